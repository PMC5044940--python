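"""Caseload indicators for comparative assessment of candidate products.

A *candidate product* contains at least one CFS; an *alternative
product* for a use contains no CFS at all and is authorised for the
same use.  The metrics here quantify the resulting regulatory
workload: how many products and uses are affected, how many
alternatives exist per use, and how many pairwise candidate-vs-
alternative comparisons could arise.

Two estimates of the pairwise-comparison count are computed and agree
exactly by construction: a full enumeration of (candidate, use,
alternative) triples, and the three-factor product

    n_candidates x mean uses-with-alternatives per candidate
                 x mean alternatives per such use,

where both means are unrounded and the second is weighted over
candidate x use pairs.  Means are rounded half-up only for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .classifier import CFSAssessment
from .errors import CaseloadError, UnassessedSubstanceError, UndefinedPercentageError
from .registry import Registry, SubstanceRecord, UseKey

logger = logging.getLogger(__name__)

#: Availability bins: inclusive integer edges, upper None = unbounded.
HISTOGRAM_BINS: Tuple[Tuple[int, Optional[int], str], ...] = (
    (0, 0, "0"),
    (1, 1, "1"),
    (2, 2, "2"),
    (3, 5, "3-5"),
    (6, 10, "6-10"),
    (11, 20, "11-20"),
    (21, 50, "21-50"),
    (51, 100, "51-100"),
    (101, None, ">100"),
)

BASIS_FILTERS = ("any", "environmental")


def pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (exact integer arithmetic)."""
    if denominator == 0:
        raise UndefinedPercentageError(
            f"percentage of {numerator} undefined for zero denominator")
    f = Fraction(100 * numerator, denominator) + Fraction(1, 2)
    return f.numerator // f.denominator


def round_half_up(x: float, ndigits: int = 0):
    """Decimal round-half-up for display values."""
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(v) if ndigits == 0 else float(v)


def _bin_label(count: int) -> str:
    if count < 0:
        raise CaseloadError(f"negative alternative count {count}")
    for lo, hi, label in HISTOGRAM_BINS:
        if count >= lo and (hi is None or count <= hi):
            return label
    raise AssertionError("bins cover all non-negative integers")


def availability_histogram(alt_counts: Mapping[UseKey, int]) -> Dict[str, int]:
    """Bin uses by the number of available alternative products.

    Returns an ordered mapping of bin label to count; the "0" bin is
    the "no alternatives available" row.
    """
    out = {label: 0 for _, _, label in HISTOGRAM_BINS}
    for use, count in alt_counts.items():
        out[_bin_label(int(count))] += 1
    return out


def _check_filter(basis_filter: str):
    if basis_filter not in BASIS_FILTERS:
        raise CaseloadError(
            f"basis_filter must be one of {BASIS_FILTERS}, got {basis_filter!r}")


def _assessment_of(assessments: Mapping[str, CFSAssessment],
                   sid: str) -> CFSAssessment:
    try:
        return assessments[sid]
    except KeyError:
        raise UnassessedSubstanceError(
            f"substance {sid!r} has no CFS assessment") from None


def _is_candidate(product, assessments, basis_filter: str) -> bool:
    for sid in product.substance_ids:
        a = _assessment_of(assessments, sid)
        if basis_filter == "any":
            if a.is_cfs:
                return True
        else:
            if a.basis in ("env_only", "both"):
                return True
    return False


def identify_candidates(reg: Registry,
                        assessments: Mapping[str, CFSAssessment],
                        basis_filter: str = "any") -> Set[str]:
    """Products containing >= 1 CFS (filter "any") or >= 1 CFS identified
    by environmental hazard criteria (filter "environmental")."""
    _check_filter(basis_filter)
    return {pid for pid, p in reg.products.items()
            if _is_candidate(p, assessments, basis_filter)}


def _cfs_free(product, assessments) -> bool:
    return all(not _assessment_of(assessments, sid).is_cfs
               for sid in product.substance_ids)


def alternatives_for_use(reg: Registry, use: UseKey,
                         assessments: Mapping[str, CFSAssessment]) -> Set[str]:
    """Products authorised for ``use`` that contain no CFS whatsoever.

    Alternatives are CFS-free under the *any* definition regardless of
    the basis filter applied to candidates, so the returned set is
    always disjoint from every candidate set.  An unknown use yields an
    empty set (logged), not an error.
    """
    pids = reg.use_index.get(use)
    if pids is None:
        logger.info("use %r not present in registry index", use)
        return set()
    return {pid for pid in pids if _cfs_free(reg.products[pid], assessments)}


def enumerate_comparisons(reg: Registry,
                          assessments: Mapping[str, CFSAssessment],
                          basis_filter: str = "any",
                          ) -> List[Tuple[str, UseKey, str]]:
    """All (candidate, use, alternative) triples, sorted, no duplicates.

    One triple per candidate product x authorised use of that candidate
    x CFS-free product authorised for the same use.  Candidate-vs-
    candidate comparisons are excluded by construction.
    """
    candidates = identify_candidates(reg, assessments, basis_filter)
    alt_cache: Dict[UseKey, Set[str]] = {}
    triples: List[Tuple[str, UseKey, str]] = []
    for cand in candidates:
        for use in reg.uses_of(cand):
            if use not in alt_cache:
                alt_cache[use] = alternatives_for_use(reg, use, assessments)
            for alt in alt_cache[use]:
                triples.append((cand, use, alt))
    triples.sort()
    return triples


@dataclass
class WorkloadReport:
    """Every count, mean and histogram of the caseload analysis.

    Counts are exact integers; means are unrounded floats (``None``
    when their denominator is zero).  ``basis_filter`` records which
    candidate definition the filter-dependent fields used; the
    ``*_env`` fields are always computed under the environmental
    filter for side-by-side reporting.
    """

    basis_filter: str
    n_substances: int
    n_cfs: int
    n_cfs_on_market: int
    n_products: int
    n_candidates: int
    n_candidates_env: int
    n_uses_total: int
    n_candidate_uses: int
    n_candidate_uses_env: int
    n_uses_with_alternatives: int
    n_uses_without_alternatives: int
    n_crops_total: int
    n_crops_candidate: int
    n_pests_total: int
    n_pests_candidate: int
    availability_histogram: Dict[str, int]
    mean_uses_per_product: Optional[float]
    mean_uses_per_candidate: Optional[float]
    mean_uses_with_alts_per_candidate: Optional[float]
    mean_alts_per_use_all: Optional[float]
    mean_alts_per_use_with_alts: Optional[float]
    product_use_pairs_candidates: int
    product_use_pairs_with_alts: int
    three_factor_estimate: float
    enumeration_total: int
    n_candidates_with_any_alternative: int

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def compute_workload(reg: Registry,
                     assessments: Mapping[str, CFSAssessment],
                     basis_filter: str = "any") -> WorkloadReport:
    """Link assessments to the registry and fill a :class:`WorkloadReport`.

    With zero candidates the report contains zero counts and absent
    means — an empty caseload is a result, not an error.
    """
    _check_filter(basis_filter)
    candidates = sorted(identify_candidates(reg, assessments, basis_filter))
    candidates_env = identify_candidates(reg, assessments, "environmental")
    cand_set = set(candidates)

    cfs_ids = {sid for sid, a in assessments.items() if a.is_cfs}
    on_market: Set[str] = set()
    for p in reg.products.values():
        on_market |= {sid for sid in p.substance_ids if sid in cfs_ids}

    all_uses = reg.all_uses()
    cand_uses: Set[UseKey] = set()
    for pid in candidates:
        cand_uses |= reg.uses_of(pid)
    cand_uses_env: Set[UseKey] = set()
    for pid in candidates_env:
        cand_uses_env |= reg.uses_of(pid)

    # alternatives per candidate use (alternatives are always fully CFS-free)
    alt_counts: Dict[UseKey, int] = {
        use: len(alternatives_for_use(reg, use, assessments))
        for use in cand_uses
    }

    n_uses_with_alts = sum(1 for c in alt_counts.values() if c > 0)
    hist = availability_histogram(alt_counts)

    pairs_all_products = sum(len(reg.uses_of(pid)) for pid in reg.products)
    pairs_cand = sum(len(reg.uses_of(pid)) for pid in candidates)
    pairs_cand_with_alts = sum(
        1 for pid in candidates for use in reg.uses_of(pid)
        if alt_counts[use] > 0)
    total_triples = sum(alt_counts[use]
                        for pid in candidates for use in reg.uses_of(pid))
    n_cand_any_alt = sum(
        1 for pid in candidates
        if any(alt_counts[use] > 0 for use in reg.uses_of(pid)))

    n_products = len(reg.products)
    n_cand = len(candidates)

    mean_uses_per_product = pairs_all_products / n_products if n_products else None
    mean_uses_per_candidate = pairs_cand / n_cand if n_cand else None
    mean_uses_with_alts = pairs_cand_with_alts / n_cand if n_cand else None
    mean_alts_all = total_triples / pairs_cand if pairs_cand else None
    mean_alts_with = (total_triples / pairs_cand_with_alts
                      if pairs_cand_with_alts else None)

    if n_cand and mean_uses_with_alts and mean_alts_with:
        three_factor = n_cand * mean_uses_with_alts * mean_alts_with
    else:
        three_factor = 0.0

    enumeration_total = len(enumerate_comparisons(reg, assessments, basis_filter))

    return WorkloadReport(
        basis_filter=basis_filter,
        n_substances=len(assessments),
        n_cfs=len(cfs_ids),
        n_cfs_on_market=len(on_market),
        n_products=n_products,
        n_candidates=n_cand,
        n_candidates_env=len(candidates_env),
        n_uses_total=len(all_uses),
        n_candidate_uses=len(cand_uses),
        n_candidate_uses_env=len(cand_uses_env),
        n_uses_with_alternatives=n_uses_with_alts,
        n_uses_without_alternatives=len(cand_uses) - n_uses_with_alts,
        n_crops_total=len({u.crop for u in all_uses}),
        n_crops_candidate=len({u.crop for u in cand_uses}),
        n_pests_total=len({u.pest for u in all_uses}),
        n_pests_candidate=len({u.pest for u in cand_uses}),
        availability_histogram=hist,
        mean_uses_per_product=mean_uses_per_product,
        mean_uses_per_candidate=mean_uses_per_candidate,
        mean_uses_with_alts_per_candidate=mean_uses_with_alts,
        mean_alts_per_use_all=mean_alts_all,
        mean_alts_per_use_with_alts=mean_alts_with,
        product_use_pairs_candidates=pairs_cand,
        product_use_pairs_with_alts=pairs_cand_with_alts,
        three_factor_estimate=three_factor,
        enumeration_total=enumeration_total,
        n_candidates_with_any_alternative=n_cand_any_alt,
    )


# ---------------------------------------------------------------------------
# breakdown tables


def substance_category_breakdown(substances: Iterable[SubstanceRecord],
                                 assessments: Mapping[str, CFSAssessment],
                                 ) -> pd.DataFrame:
    """Per-use-category CFS shares among active substances.

    Substances with exactly one category are counted in that category's
    row; substances with two or more in a single "Multi" row; substances
    with none in "Not assigned".  Rows partition the substance set and
    an "All" row closes the table.
    """
    substances = list(substances)
    if not substances:
        return pd.DataFrame(columns=["category", "n_substances", "n_cfs", "pct_cfs"])

    def row_key(rec: SubstanceRecord) -> str:
        if len(rec.use_categories) == 0:
            return "Not assigned"
        if len(rec.use_categories) >= 2:
            return "Multi"
        return next(iter(rec.use_categories))

    counts: Dict[str, List[int]] = {}
    for rec in substances:
        key = row_key(rec)
        n, k = counts.get(key, (0, 0))
        a = _assessment_of(assessments, rec.substance_id)
        counts[key] = (n + 1, k + int(a.is_cfs))

    order = ["AC", "FU", "HB", "IN", "PG", "RE", "RO", "OTHER",
             "Multi", "Not assigned"]
    rows = []
    for key in [k for k in order if k in counts]:
        n, k = counts[key]
        rows.append({"category": key, "n_substances": n, "n_cfs": k,
                     "pct_cfs": pct(k, n)})
    n_all = len(substances)
    k_all = sum(int(_assessment_of(assessments, r.substance_id).is_cfs)
                for r in substances)
    rows.append({"category": "All", "n_substances": n_all, "n_cfs": k_all,
                 "pct_cfs": pct(k_all, n_all)})
    return pd.DataFrame(rows, columns=["category", "n_substances", "n_cfs", "pct_cfs"])


def product_category_breakdown(reg: Registry,
                               assessments: Mapping[str, CFSAssessment],
                               ) -> pd.DataFrame:
    """Candidate shares per product category (non-exclusive counting).

    A product carrying several categories is counted in every one of
    them, so category rows can sum to more than the "All" row, which
    counts distinct products.
    """
    cand_any = identify_candidates(reg, assessments, "any")
    cand_env = identify_candidates(reg, assessments, "environmental")

    cats: Dict[str, List[str]] = {}
    for pid, p in reg.products.items():
        for cat in (p.product_categories or {"OTHER"}):
            cats.setdefault(cat, []).append(pid)

    rows = []
    for cat in sorted(cats):
        pids = cats[cat]
        n = len(pids)
        rows.append({
            "category": cat,
            "n_products": n,
            "pct_candidates": pct(sum(1 for p in pids if p in cand_any), n),
            "pct_candidates_env": pct(sum(1 for p in pids if p in cand_env), n),
        })
    n_all = len(reg.products)
    if n_all:
        rows.append({
            "category": "All",
            "n_products": n_all,
            "pct_candidates": pct(len(cand_any), n_all),
            "pct_candidates_env": pct(len(cand_env), n_all),
        })
    return pd.DataFrame(
        rows, columns=["category", "n_products", "pct_candidates",
                       "pct_candidates_env"])
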