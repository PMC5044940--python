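"""Run the German-market-like scenario end to end.

The preset emulates the scale of the German plant-protection market:
378 approved substances, 1,378 authorised products, a 309-crop x
477-pest use vocabulary, and hazard rates calibrated so about a
quarter of substances are candidates for substitution.  Prints the
headline workload indicators and the substance-category breakdown.
"""

import cfs_caseload as cc

cfg = cc.german_like_preset()  # fixed documented seed (2013)
substances, profiles, registry = cc.generate_scenario(cfg)
assessments = cc.classify_all(profiles, substances)
rep = cc.compute_workload(registry, assessments, "any")
env = cc.compute_workload(registry, assessments, "environmental")

print(f"substances: {rep.n_substances}, CFS: {rep.n_cfs} "
      f"({cc.pct(rep.n_cfs, rep.n_substances)}%)")
print(f"products: {rep.n_products}, candidates: {rep.n_candidates} "
      f"({cc.pct(rep.n_candidates, rep.n_products)}%), "
      f"environmental basis: {env.n_candidates} "
      f"({cc.pct(env.n_candidates, rep.n_products)}%)")
print(f"uses: {rep.n_uses_total}, of candidates: {rep.n_candidate_uses} "
      f"({cc.pct(rep.n_candidate_uses, rep.n_uses_total)}%)")
print(f"candidate uses with alternatives: {rep.n_uses_with_alternatives} "
      f"({cc.pct(rep.n_uses_with_alternatives, rep.n_candidate_uses)}%)")
print(f"pairwise comparisons (any basis): {rep.enumeration_total}")
print(f"pairwise comparisons (environmental): {env.enumeration_total}")
print()
print(cc.substance_category_breakdown(substances, assessments).to_string(index=False))
print()
print("Each pairwise comparison is one candidate product compared with one")
print("CFS-free alternative product for one shared authorised use — the")
print("unit of work a comparative risk assessment would have to address.")
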