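"""Serialization and human-readable rendering of analysis outputs."""

from __future__ import annotations

import json
from typing import Mapping

import pandas as pd

from .classifier import CFSAssessment
from .registry import Registry
from .workload import (
    WorkloadReport,
    pct,
    product_category_breakdown,
    round_half_up,
    substance_category_breakdown,
)

ASSESSMENT_COLUMNS = ["substance_id", "c1", "c2", "c3", "c4", "c5", "c6", "c7",
                      "P", "B", "T_aqua", "T_human", "is_cfs", "basis"]


def assessments_frame(assessments: Mapping[str, CFSAssessment]) -> pd.DataFrame:
    """Per-substance assessment table in the documented column order."""
    rows = []
    for sid in sorted(assessments):
        a = assessments[sid]
        rows.append({
            "substance_id": a.substance_id,
            "c1": a.c1, "c2": a.c2, "c3": a.c3, "c4": a.c4,
            "c5": a.c5, "c6": a.c6, "c7": a.c7,
            "P": a.p, "B": a.b, "T_aqua": a.t_aqua, "T_human": a.t_human,
            "is_cfs": a.is_cfs, "basis": a.basis,
        })
    return pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)


def write_assessments_csv(assessments: Mapping[str, CFSAssessment], path):
    assessments_frame(assessments).to_csv(path, index=False)


def workload_json(report: WorkloadReport) -> str:
    return json.dumps(report.to_dict(), indent=2, sort_keys=True)


def _fmt_mean(x) -> str:
    return "-" if x is None else f"{x:.3f} (~{round_half_up(x)})"


def render_workload_text(report: WorkloadReport) -> str:
    """Aligned text report mirroring the published table structure."""
    r = report
    lines = [
        f"Caseload report (basis filter: {r.basis_filter})",
        "",
        "Substances",
        f"  approved active substances        {r.n_substances}",
        f"  potential CFS                     {r.n_cfs}"
        + (f" ({pct(r.n_cfs, r.n_substances)}%)" if r.n_substances else ""),
        f"  CFS found in >=1 product          {r.n_cfs_on_market}",
        "",
        "Products",
        f"  authorised products               {r.n_products}",
        f"  candidate products                {r.n_candidates}"
        + (f" ({pct(r.n_candidates, r.n_products)}%)" if r.n_products else ""),
        f"  candidates (environmental basis)  {r.n_candidates_env}",
        f"  candidates with any alternative   {r.n_candidates_with_any_alternative}",
        "",
        "Uses",
        f"  all authorised uses               {r.n_uses_total}",
        f"  uses of candidate products        {r.n_candidate_uses}"
        + (f" ({pct(r.n_candidate_uses, r.n_uses_total)}%)" if r.n_uses_total else ""),
        f"    with alternatives               {r.n_uses_with_alternatives}",
        f"    without alternatives            {r.n_uses_without_alternatives}",
        f"  crops: all {r.n_crops_total}, candidate {r.n_crops_candidate}; "
        f"pests: all {r.n_pests_total}, candidate {r.n_pests_candidate}",
        "",
        "Availability of alternatives (uses of candidate products)",
    ]
    for label, count in r.availability_histogram.items():
        name = "no alternatives available" if label == "0" else f"{label} alternatives"
        lines.append(f"  {name:<28}{count}")
    lines += [
        "",
        "Means (unrounded, half-up in parentheses)",
        f"  uses per product                  {_fmt_mean(r.mean_uses_per_product)}",
        f"  uses per candidate                {_fmt_mean(r.mean_uses_per_candidate)}",
        f"  uses with alternatives/candidate  "
        f"{_fmt_mean(r.mean_uses_with_alts_per_candidate)}",
        f"  alternatives per use (all)        {_fmt_mean(r.mean_alts_per_use_all)}",
        f"  alternatives per use (with alts)  "
        f"{_fmt_mean(r.mean_alts_per_use_with_alts)}",
        "",
        "Comparison caseload",
        f"  candidate product x use pairs     {r.product_use_pairs_candidates}",
        f"  ... restricted to uses with alts  {r.product_use_pairs_with_alts}",
        f"  three-factor estimate             {r.three_factor_estimate:.3f}",
        f"  enumerated pairwise comparisons   {r.enumeration_total}",
    ]
    return "\n".join(lines) + "\n"


def render_breakdowns_text(substances, assessments,
                           registry: Registry) -> str:
    sub = substance_category_breakdown(substances, assessments)
    prod = product_category_breakdown(registry, assessments)
    return (
        "CFS by substance use category\n"
        + sub.to_string(index=False)
        + "\n\nCandidate products by product category (non-exclusive)\n"
        + prod.to_string(index=False)
        + "\n"
    )
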