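"""Burden statistics: collapsing, exact test, conditional MLE, FDR."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from dcmburden.burden import (
    ContingencyTable,
    SampleRecord,
    UntestableTableError,
    bh_adjust,
    build_table,
    carrier_flags,
    conditional_mle_or,
    exclude_low_count,
    fisher_exact,
    fisher_p,
    run_burden,
    sample_or,
)
from dcmburden.filtering import DEFAULT_GENE_RULES
from dcmburden.io import Genotypes

from oracles import cmle_or_oracle, fisher_p_oracle


def small_genotypes():
    #               s1 s2 s3 s4
    matrix = np.array(
        [
            [1, 0, 0, -1],   # v1
            [1, 0, 0, 0],    # v2
            [0, 0, 2, 0],    # v3
        ],
        dtype=np.int8,
    )
    return Genotypes(["s1", "s2", "s3", "s4"], ["v1", "v2", "v3"], matrix)


class TestCarrierCollapsing:
    def test_two_variants_count_once(self):
        flags = carrier_flags(small_genotypes(), {"v1", "v2"})
        assert flags == {"s1": True, "s2": False, "s3": False, "s4": False}

    def test_homozygous_alt_is_carrier(self):
        flags = carrier_flags(small_genotypes(), {"v3"})
        assert flags["s3"] is True

    def test_missing_genotype_is_non_carrier(self):
        flags = carrier_flags(small_genotypes(), {"v1"})
        assert flags["s4"] is False

    def test_no_qualifying_variants(self):
        flags = carrier_flags(small_genotypes(), set())
        assert not any(flags.values())

    def test_sample_absent_from_genotypes_errors(self):
        flags = carrier_flags(small_genotypes(), {"v1"})
        samples = [SampleRecord("s1", "female"), SampleRecord("ghost", "male")]
        with pytest.raises(KeyError, match="ghost"):
            build_table(flags, samples)


class TestBuildTable:
    def test_counts_by_sex(self):
        flags = {"f1": True, "f2": False, "m1": True, "m2": False, "m3": False}
        samples = [
            SampleRecord("f1", "female"),
            SampleRecord("f2", "female"),
            SampleRecord("m1", "male"),
            SampleRecord("m2", "male"),
            SampleRecord("m3", "male"),
        ]
        assert build_table(flags, samples) == ContingencyTable(1, 1, 1, 2)

    def test_no_carriers(self):
        samples = [SampleRecord("f1", "female"), SampleRecord("m1", "male")]
        t = build_table({"f1": False, "m1": False}, samples)
        assert (t.a, t.b, t.c, t.d) == (0, 1, 0, 1)

    def test_cohort_tables(self, table1, filter_cfg):
        """The deterministic cohort yields its designed sex x carrier tables."""
        cohort, _ = table1
        results = {r.gene: r for r in run_burden(cohort, DEFAULT_GENE_RULES, filter_cfg)}
        assert results["DSP"].table == ContingencyTable(20, 254, 14, 542)
        assert results["TTN"].table == ContingencyTable(37, 237, 105, 451)


class TestFisherExact:
    def test_against_r_fisher_test(self):
        """Frozen cross-check values computed with R's fisher.test."""
        p, or_cmle, ci = fisher_exact(ContingencyTable(20, 254, 14, 542))
        assert p == pytest.approx(0.0022932, rel=1e-4)
        assert or_cmle == pytest.approx(3.0438, rel=1e-4)
        assert ci[0] == pytest.approx(1.4358, rel=2e-3)
        assert ci[1] == pytest.approx(6.6292, rel=2e-3)

        p, or_cmle, ci = fisher_exact(ContingencyTable(6, 268, 2, 554))
        assert p == pytest.approx(0.0182156, rel=1e-4)
        assert or_cmle == pytest.approx(6.1870, rel=1e-4)
        assert ci[0] == pytest.approx(1.0971, rel=2e-3)
        assert ci[1] == pytest.approx(63.126, rel=2e-3)

    def test_agrees_with_scipy_p(self):
        from scipy.stats import fisher_exact as scipy_fisher

        for t in [(5, 10, 3, 20), (1, 99, 7, 93), (12, 8, 4, 16)]:
            expected = scipy_fisher([[t[0], t[1]], [t[2], t[3]]])[1]
            assert fisher_p(ContingencyTable(*t)) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("k,n", [(1, 10), (5, 20), (7, 15)])
    def test_symmetric_table_is_null(self, k, n):
        p, or_cmle, _ = fisher_exact(ContingencyTable(k, n - k, k, n - k))
        assert p == pytest.approx(1.0)
        assert or_cmle == pytest.approx(1.0, abs=1e-9)

    def test_one_sided_alternatives(self):
        t = ContingencyTable(20, 254, 14, 542)
        # frozen from R fisher.test(alternative="greater"/"less")
        assert fisher_p(t, "greater") == pytest.approx(0.001418224, rel=1e-5)
        assert fisher_p(t, "less") == pytest.approx(0.9996, rel=1e-3)
        with pytest.raises(ValueError):
            fisher_p(t, "sideways")

    def test_zero_cell_gives_one_sided_bounds(self):
        p, or_cmle, ci = fisher_exact(ContingencyTable(0, 10, 5, 5))
        assert or_cmle == 0.0 and ci[0] == 0.0 and ci[1] > 0
        p, or_cmle, ci = fisher_exact(ContingencyTable(5, 5, 0, 10))
        assert math.isinf(or_cmle) and math.isinf(ci[1]) and ci[0] > 0

    def test_empty_margin_rejected(self):
        with pytest.raises(UntestableTableError):
            fisher_exact(ContingencyTable(0, 0, 5, 5))
        with pytest.raises(UntestableTableError):
            fisher_exact(ContingencyTable(0, 10, 0, 10))

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=150, deadline=None)
    def test_sex_swap_antisymmetry(self, a, b, c, d):
        """Swapping the rows inverts both OR estimators and keeps p."""
        t = ContingencyTable(a, b, c, d)
        assume(t.n_female > 0 and t.n_male > 0 and t.n_carriers > 0 and t.b + t.d > 0)
        p1, or1, _ = fisher_exact(t)
        p2, or2, _ = fisher_exact(t.swapped())
        assert p1 == pytest.approx(p2, rel=1e-9)
        if 0 < or1 < math.inf:
            assert or2 == pytest.approx(1.0 / or1, rel=1e-6)
        if t.b * t.c > 0 and t.a * t.d > 0:
            assert sample_or(t.swapped()) == pytest.approx(1.0 / sample_or(t), rel=1e-12)

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracles(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assume(t.n_female > 0 and t.n_male > 0 and t.n_carriers > 0 and t.b + t.d > 0)
        assert fisher_p(t) == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-9)
        expected = cmle_or_oracle(a, b, c, d)
        got = conditional_mle_or(t.n_female, t.n_male, t.n_carriers, a)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    @given(
        a=st.integers(50, 300), b=st.integers(50, 300),
        c=st.integers(50, 300), d=st.integers(50, 300),
    )
    @settings(max_examples=30, deadline=None)
    def test_cmle_close_to_sample_or_for_large_cells(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        _, or_cmle, _ = fisher_exact(t)
        assert abs(or_cmle - sample_or(t)) / sample_or(t) < 0.01


class TestSampleOr:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((20, 254, 14, 542), 20 * 542 / (254 * 14)),
            ((2, 272, 4, 552), 2 * 552 / (272 * 4)),
        ],
    )
    def test_direct_arithmetic(self, table, expected):
        assert sample_or(ContingencyTable(*table)) == pytest.approx(expected, rel=1e-12)

    def test_zero_cells_give_infinity(self):
        assert math.isinf(sample_or(ContingencyTable(0, 10, 0, 10)))


class TestExclusionRule:
    @pytest.mark.parametrize("a, c, tested", [(2, 2, False), (2, 3, True), (0, 0, False), (5, 0, True)])
    def test_minimum_carrier_boundary(self, a, c, tested):
        tables = {"G": ContingencyTable(a, 100, c, 100)}
        kept, dropped = exclude_low_count(tables, min_carriers=5)
        assert ("G" in kept) is tested
        if not tested:
            assert "fewer than 5 carriers" in dropped["G"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            exclude_low_count({}, min_carriers=0)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust({"g": 0.03}) == {"g": pytest.approx(0.03)}

    def test_step_up_hand_example(self):
        adj = bh_adjust({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04})
        assert all(v == pytest.approx(0.04) for v in adj.values())

    def test_minimum_scaled_by_family_size(self):
        ps = {"g1": 0.001, **{f"x{i}": 0.5 for i in range(7)}}
        assert bh_adjust(ps)["g1"] == pytest.approx(8 * 0.001)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, ps):
        pvals = {f"g{i}": p for i, p in enumerate(ps)}
        adj = bh_adjust(pvals)
        order = sorted(pvals, key=pvals.get)
        adj_sorted = [adj[g] for g in order]
        assert all(x <= y + 1e-12 for x, y in zip(adj_sorted, adj_sorted[1:]))
        assert all(pvals[g] <= adj[g] + 1e-12 <= 1 + 1e-12 for g in pvals)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust({"g": 0.0})


class TestRunBurden:
    def test_cohort_end_to_end(self, table1, filter_cfg):
        cohort, manifest = table1
        results = run_burden(cohort, DEFAULT_GENE_RULES, filter_cfg)
        tested = [r.gene for r in results if r.tested]
        excluded = {r.gene for r in results if not r.tested}
        assert len(tested) == 8
        assert excluded == {"BAG3", "TNNC1", "TNNT2", "PLN"}
        for r in results:
            if r.tested:
                assert r.ci95[0] <= r.or_cmle <= r.ci95[1]
                assert r.p <= r.p_fdr <= 1.0

    def test_trivial_subset_filter_is_identity(self, table1, filter_cfg):
        cohort, _ = table1
        base = run_burden(cohort, DEFAULT_GENE_RULES, filter_cfg)
        same = run_burden(cohort, DEFAULT_GENE_RULES, filter_cfg, subset_filter=lambda s: True)
        for r1, r2 in zip(base, same):
            assert r1.table == r2.table and r1.p == r2.p

    def test_european_subset_keeps_dsp_enrichment(self, table1, filter_cfg):
        cohort, _ = table1
        results = {
            r.gene: r
            for r in run_burden(
                cohort, DEFAULT_GENE_RULES, filter_cfg,
                subset_filter=lambda s: s.ancestry == "European",
            )
        }
        dsp = results["DSP"]
        assert dsp.table.a == 20 and dsp.table.c == 14  # carriers are European
        assert dsp.or_cmle > 2.5

    def test_single_sex_cohort_rejected(self, table1, filter_cfg):
        cohort, _ = table1
        with pytest.raises(UntestableTableError, match="both sexes"):
            run_burden(cohort, DEFAULT_GENE_RULES, filter_cfg,
                       subset_filter=lambda s: s.sex == "male")
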