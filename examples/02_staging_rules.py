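"""Apply the published staging rules to individual patients.

Each model maps a complete record to scan/no-scan; the Wang model also
provides a continuous decision score D (printed rule: scan when D < 0).
"""
import bonedca as b
from bonedca import models as M

patient = {
    "psa_ng_ml": 12.0,
    "t_stage": "T2a",
    "gleason_primary": 3.0,
    "gleason_secondary": 4.0,
    "pct_pos_cores": 55.0,
    "n_stage_positive": 0.0,
}

print("patient: PSA 12, T2a, Gleason 3+4, 55% positive cores, node-negative")
print(f"  EAU 2020 scan rule:      {bool(M.classify_eau(patient))}")
print(f"  EAU high-risk only:      {bool(M.classify_eau_high_risk(patient))}")
print(f"  AUA 2018:                {bool(M.classify_aua(patient))}")
print(f"  NCCN 2019:               {bool(M.classify_nccn(patient))}")
print(f"  Cambridge (Gnana) group: {M.gnanapragasam_group(patient)}")
print(f"  ISUP grade group:        {M.isup_grade_group(patient):.0f}")
print(f"  Briganti group:          {M.briganti_group(patient)}")
d = M.wang_score(patient["psa_ng_ml"], patient["t_stage"],
                 patient["gleason_primary"], patient["gleason_secondary"])
print(f"  Wang score D:            {d:.3f} "
      f"(risk {M.wang_probability(12.0, 'T2a', 3, 4):.1%})")
# AUA scans this patient (PSA > 10 with Gleason 3+4); EAU does not (Gleason
# 4+3 or high-risk features required); NCCN scans via the >=50%-cores clause.
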