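"""Caseload metrics: candidates, alternatives, histograms, comparisons."""


import pytest
from hypothesis import given, strategies as st

import cfs_caseload as cc
from cfs_caseload.errors import (
    CaseloadError,
    UnassessedSubstanceError,
    UndefinedPercentageError,
)


class TestPct:
    @pytest.mark.parametrize("num,den,expected", [
        (351, 1378, 25),
        (237, 1378, 17),
        (1863, 3606, 52),
        (1501, 3606, 42),
        (345, 351, 98),
        (1, 200, 1),      # exact .5 rounds up
        (0, 7, 0),
        (7, 7, 100),
    ])
    def test_half_up_integer_percent(self, num, den, expected):
        assert cc.pct(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(UndefinedPercentageError):
            cc.pct(1, 0)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_within_half_a_point_and_ties_round_up(self, num, den):
        got = cc.pct(num, den)
        assert abs(got - 100 * num / den) <= 0.5 + 1e-9
        if (200 * num) % (2 * den) == den:  # exact .5
            assert got > 100 * num / den


def _counts_to_mapping(pairs):
    """[(alt_count, n_uses), ...] -> synthetic UseKey -> count mapping."""
    out = {}
    i = 0
    for count, n in pairs:
        for _ in range(n):
            out[cc.UseKey(f"crop {i}", "pest")] = count
            i += 1
    return out


class TestAvailabilityHistogram:
    def test_reported_availability_distribution(self):
        # one representative count per occupied bin
        mapping = _counts_to_mapping([
            (1, 220), (2, 126), (4, 172), (8, 82), (15, 112), (30, 42),
            (70, 12), (150, 1), (0, 1096),
        ])
        hist = cc.availability_histogram(mapping)
        assert hist == {"0": 1096, "1": 220, "2": 126, "3-5": 172,
                        "6-10": 82, "11-20": 112, "21-50": 42,
                        "51-100": 12, ">100": 1}
        assert sum(v for k, v in hist.items() if k != "0") == 767

    @pytest.mark.parametrize("count,label", [
        (0, "0"), (1, "1"), (2, "2"), (3, "3-5"), (5, "3-5"), (6, "6-10"),
        (10, "6-10"), (11, "11-20"), (20, "11-20"), (21, "21-50"),
        (50, "21-50"), (51, "51-100"), (100, "51-100"), (101, ">100"),
        (100000, ">100"),
    ])
    def test_boundary_assignment(self, count, label):
        hist = cc.availability_histogram({cc.UseKey("c", "p"): count})
        assert hist[label] == 1 and sum(hist.values()) == 1

    def test_empty_input(self):
        hist = cc.availability_histogram({})
        assert set(hist) == {b[2] for b in cc.HISTOGRAM_BINS}
        assert all(v == 0 for v in hist.values())

    def test_negative_count_rejected(self):
        with pytest.raises(CaseloadError):
            cc.availability_histogram({cc.UseKey("c", "p"): -1})

    @given(st.lists(st.integers(0, 500), max_size=60))
    def test_conservation(self, counts):
        mapping = {cc.UseKey(f"c{i}", "p"): c for i, c in enumerate(counts)}
        hist = cc.availability_histogram(mapping)
        assert sum(hist.values()) == len(mapping)
        assert sum(v for k, v in hist.items() if k != "0") == sum(
            1 for c in counts if c > 0)


class TestCandidatesAndAlternatives:
    def test_one_cfs_substance_makes_a_candidate(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a", "b", "c"}))},
            authorisations={})
        assessments = {"a": assess("a", c6=True), "b": assess("b"),
                       "c": assess("c")}
        assert cc.identify_candidates(reg, assessments) == {"p"}

    def test_cfs_free_products_are_not_candidates(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a"}))},
            authorisations={})
        assert cc.identify_candidates(reg, {"a": assess("a")}) == set()

    def test_environmental_filter_is_a_subset(self, preset_runs):
        for run in preset_runs[:5]:
            any_set = cc.identify_candidates(run["registry"],
                                             run["assessments"], "any")
            env_set = cc.identify_candidates(run["registry"],
                                             run["assessments"],
                                             "environmental")
            assert env_set <= any_set

    def test_unassessed_substance_is_named(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"mystery"}))},
            authorisations={})
        with pytest.raises(UnassessedSubstanceError, match="mystery"):
            cc.identify_candidates(reg, {})

    def test_alternatives_exclude_all_cfs_carriers(self, toy_candidate_registry):
        reg, assessments, u1, u2 = toy_candidate_registry
        assert cc.alternatives_for_use(reg, u1, assessments) == {
            "A1", "A2", "A3"}
        assert cc.alternatives_for_use(reg, u2, assessments) == set()

    def test_unknown_use_is_empty_not_error(self, toy_candidate_registry):
        reg, assessments, _, _ = toy_candidate_registry
        ghost = cc.normalize_use("ghost", "use")
        assert cc.alternatives_for_use(reg, ghost, assessments) == set()

    def test_candidates_never_appear_as_alternatives(self, preset_runs):
        run = preset_runs[0]
        reg, assessments = run["registry"], run["assessments"]
        candidates = cc.identify_candidates(reg, assessments)
        some_uses = sorted(reg.all_uses())[:200]
        for use in some_uses:
            assert not (cc.alternatives_for_use(reg, use, assessments)
                        & candidates)


class TestEnumerateComparisons:
    def test_toy_three_triples(self, toy_candidate_registry):
        reg, assessments, u1, _ = toy_candidate_registry
        triples = cc.enumerate_comparisons(reg, assessments)
        assert triples == [("C1", u1, "A1"), ("C1", u1, "A2"), ("C1", u1, "A3")]

    def test_no_alternatives_no_triples(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a"}))},
            authorisations={"p": frozenset({cc.normalize_use("c", "x")})})
        assert cc.enumerate_comparisons(reg, {"a": assess("a", c6=True)}) == []

    def test_size_matches_brute_force_double_loop(self, preset_runs):
        run = preset_runs[0]
        reg, assessments = run["registry"], run["assessments"]
        triples = cc.enumerate_comparisons(reg, assessments)
        assert len(triples) == len(set(triples))
        candidates = cc.identify_candidates(reg, assessments)
        expected = 0
        for cand in candidates:
            for use in reg.uses_of(cand):
                expected += len(cc.alternatives_for_use(reg, use, assessments))
        assert len(triples) == expected


def naive_workload(reg, assessments, basis_filter):
    """Nested-loop recomputation of the headline counts, for small inputs."""
    cfs = {s for s, a in assessments.items() if a.is_cfs}
    if basis_filter == "any":
        marker = cfs
    else:
        marker = {s for s, a in assessments.items()
                  if a.basis in ("env_only", "both")}
    cands = sorted(p for p in reg.products
                   if reg.products[p].substance_ids & marker)
    cfs_free = {p for p in reg.products
                if not (reg.products[p].substance_ids & cfs)}
    cand_uses = set()
    for p in cands:
        cand_uses |= reg.uses_of(p)
    alts = {}
    for u in cand_uses:
        alts[u] = {p for p in reg.products
                   if u in reg.uses_of(p) and p in cfs_free}
    pairs = [(p, u) for p in cands for u in reg.uses_of(p)]
    triples = [(p, u, a) for p, u in pairs for a in alts[u]]
    return {
        "n_candidates": len(cands),
        "n_candidate_uses": len(cand_uses),
        "n_uses_with_alternatives": sum(1 for u in cand_uses if alts[u]),
        "product_use_pairs_candidates": len(pairs),
        "product_use_pairs_with_alts": sum(1 for p, u in pairs if alts[u]),
        "enumeration_total": len(triples),
        "n_candidates_with_any_alternative": len(
            {p for p, u in pairs if alts[u]}),
    }


class TestComputeWorkload:
    def test_toy_identity_by_hand(self, toy_candidate_registry):
        reg, assessments, _, _ = toy_candidate_registry
        rep = cc.compute_workload(reg, assessments)
        assert rep.n_candidates == 1
        assert rep.mean_uses_with_alts_per_candidate == 1
        assert rep.mean_alts_per_use_with_alts == 3
        assert rep.three_factor_estimate == 3 == rep.enumeration_total
        assert rep.n_candidates_with_any_alternative == 1

    def test_candidate_without_alternatives_still_counted(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a"}))},
            authorisations={"p": frozenset({cc.normalize_use("c", "x")})})
        rep = cc.compute_workload(reg, {"a": assess("a", c6=True)})
        assert rep.n_candidates == 1
        assert rep.n_candidates_with_any_alternative == 0

    def test_zero_candidates_gives_zeros_and_absent_means(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a"}))},
            authorisations={"p": frozenset({cc.normalize_use("c", "x")})})
        rep = cc.compute_workload(reg, {"a": assess("a")})
        assert rep.n_candidates == 0
        assert rep.three_factor_estimate == 0.0 == rep.enumeration_total
        assert rep.mean_uses_per_candidate is None
        assert rep.mean_alts_per_use_with_alts is None

    @pytest.mark.parametrize("basis_filter", ["any", "environmental"])
    def test_matches_naive_oracle_on_small_scenarios(self, basis_filter):
        for seed in range(6):
            substances, profiles, reg = cc.generate_scenario(
                cc.small_preset(seed))
            assessments = cc.classify_all(profiles, substances)
            rep = cc.compute_workload(reg, assessments, basis_filter)
            oracle = naive_workload(reg, assessments, basis_filter)
            for key, expected in oracle.items():
                assert getattr(rep, key) == expected, key

    def test_conservation_and_nesting(self, preset_runs):
        for run in preset_runs[:5]:
            rep = run["report"]
            assert (rep.n_uses_with_alternatives
                    + rep.n_uses_without_alternatives) == rep.n_candidate_uses
            assert sum(v for k, v in rep.availability_histogram.items()
                       if k != "0") == rep.n_uses_with_alternatives
            assert sum(rep.availability_histogram.values()) == rep.n_candidate_uses
            env = cc.compute_workload(run["registry"], run["assessments"],
                                      "environmental")
            assert env.n_candidates <= rep.n_candidates
            assert env.n_candidate_uses <= rep.n_candidate_uses
            assert env.enumeration_total <= rep.enumeration_total
            assert rep.n_candidates_env == env.n_candidates
            assert rep.n_candidate_uses_env == env.n_candidate_uses

    def test_three_factor_equals_enumeration(self, preset_runs):
        for run in preset_runs:
            rep = run["report"]
            assert rep.three_factor_estimate == pytest.approx(
                rep.enumeration_total, rel=1e-9)

    def test_enlarging_cfs_set_is_monotone(self, assess):
        substances, profiles, reg = cc.generate_scenario(cc.small_preset(1))
        assessments = cc.classify_all(profiles, substances)
        base = cc.compute_workload(reg, assessments)
        non_cfs = [s for s, a in assessments.items() if not a.is_cfs]
        promoted = dict(assessments)
        promoted[non_cfs[0]] = assess(non_cfs[0], c6=True)
        bigger = cc.compute_workload(reg, promoted)
        assert bigger.n_candidates >= base.n_candidates
        for use in reg.all_uses():
            assert len(cc.alternatives_for_use(reg, use, promoted)) <= len(
                cc.alternatives_for_use(reg, use, assessments))


class TestBreakdowns:
    def test_multi_category_rule(self, assess):
        substances = [
            cc.SubstanceRecord("a", use_categories=frozenset({"FU"})),
            cc.SubstanceRecord("b", use_categories=frozenset({"FU"})),
            cc.SubstanceRecord("c", use_categories=frozenset({"AC", "FU"})),
            cc.SubstanceRecord("d", use_categories=frozenset()),
        ]
        assessments = {s.substance_id: assess(s.substance_id, c6=(s.substance_id == "a"))
                       for s in substances}
        table = cc.substance_category_breakdown(substances, assessments)
        rows = dict(zip(table["category"], table["n_substances"]))
        assert rows == {"FU": 2, "Multi": 1, "Not assigned": 1, "All": 4}
        assert table.set_index("category").loc["All", "n_cfs"] == 1

    def test_rows_partition_the_substance_set(self, preset_runs):
        run = preset_runs[0]
        table = cc.substance_category_breakdown(run["substances"],
                                                run["assessments"])
        body = table[table["category"] != "All"]
        assert body["n_substances"].sum() == len(run["substances"])
        assert body["n_cfs"].sum() == sum(
            a.is_cfs for a in run["assessments"].values())

    def test_empty_input_empty_table(self):
        table = cc.substance_category_breakdown([], {})
        assert table.empty

    def test_product_rows_are_non_exclusive(self, assess):
        reg = cc.Registry(
            products={"p": cc.Product("p", "x", frozenset({"a"}),
                                      frozenset({"HB", "FU"}))},
            authorisations={})
        table = cc.product_category_breakdown(reg, {"a": assess("a", c6=True)})
        idx = table.set_index("category")
        assert idx.loc["HB", "n_products"] == 1
        assert idx.loc["FU", "n_products"] == 1
        assert idx.loc["All", "n_products"] == 1
        assert idx.loc["All", "pct_candidates"] == 100
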