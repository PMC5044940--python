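"""Classify a handful of hand-written substances against the CFS criteria.

Builds four hazard profiles in code, runs the rule engine, and prints
which criteria fire and on which hazard basis each substance would be
listed as a candidate for substitution.
"""

import cfs_caseload as cc

substances = [
    # a persistent substance that is also chronically toxic to daphnids:
    # two of the three PBT criteria (P + T_aqua) => criterion 2, environmental
    cc.SubstanceRecord("soilbinder", use_categories=frozenset({"HB"})),
    # classified toxic for reproduction 1B => criterion 6, human health
    cc.SubstanceRecord("reprotox-1b", use_categories=frozenset({"IN"})),
    # interim endocrine rule: carcinogen 2 together with repro 2
    cc.SubstanceRecord("interim-ed", use_categories=frozenset({"FU"})),
    # benign profile: no criterion fires
    cc.SubstanceRecord("benign", use_categories=frozenset({"FU"})),
]

profiles = [
    cc.HazardProfile("soilbinder", dt50_soil=180.0, noec_daphnia=0.004),
    cc.HazardProfile("reprotox-1b", repro_class_existing="1B"),
    cc.HazardProfile("interim-ed", carc_class="2", repro_class_existing="2"),
    cc.HazardProfile("benign", adi=0.5, dt50_soil=12.0, bcf=40.0),
]

assessments = cc.classify_all(profiles, substances)

print(f"{'substance':<14} {'criteria met':<14} {'CFS':<5} basis")
for sid, a in assessments.items():
    crits = [name for name, flag in
             (("1", a.c1), ("2", a.c2), ("4", a.c4), ("6", a.c6), ("7", a.c7))
             if flag]
    print(f"{sid:<14} {','.join(crits) or '-':<14} {str(a.is_cfs):<5} {a.basis}")

print()
print("A substance is a candidate for substitution (CFS) when at least one")
print("criterion fires; 'basis' records whether it was identified through")
print("environmental hazards (aquatic PBT route, non-active isomers),")
print("human-health hazards (low reference doses, CMR, the interim")
print("endocrine rule), or both.")
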