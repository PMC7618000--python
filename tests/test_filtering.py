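"""Variant qualification: consequence classes, QC filters, rarity, TTN exon."""


import pytest
from hypothesis import given, settings, strategies as st

from dcmburden.filtering import (
    ConsequenceClass,
    DEFAULT_GENE_RULES,
    FilterConfig,
    GeneRule,
    MISSENSE_TERMS,
    PLOF_TERMS,
    REASON_QUALIFIES,
    VariantRecord,
    classify_consequence,
    hwe_exact_test,
    passes_rarity_filter,
    passes_ttn_exon_filter,
    passes_variant_qc,
    qualification_report,
    qualifying_variants,
)

from oracles import hwe_p_oracle


def make_variant(gene="DSP", terms=("missense_variant",), afs=None, psi=None,
                 call_rate=1.0, qd=15.0, counts=(829, 1, 0), pos=100):
    return VariantRecord(
        chrom="6", pos=pos, ref="G", alt="A", gene=gene,
        consequence_terms=frozenset(terms),
        pop_afs=afs if afs is not None else {"nfe": 0.0},
        ttn_psi=psi, call_rate=call_rate, qual_by_depth=qd, genotype_counts=counts,
    )


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "terms, expected",
        [
            ({"stop_gained"}, ConsequenceClass.PLOF),
            ({"frameshift_variant"}, ConsequenceClass.PLOF),
            ({"splice_acceptor_variant"}, ConsequenceClass.PLOF),
            ({"splice_donor_variant", "intron_variant"}, ConsequenceClass.PLOF),
            ({"missense_variant"}, ConsequenceClass.MISSENSE),
            ({"inframe_deletion"}, ConsequenceClass.MISSENSE),
            ({"inframe_insertion"}, ConsequenceClass.MISSENSE),
            # loss of function takes precedence over missense
            ({"stop_gained", "missense_variant"}, ConsequenceClass.PLOF),
            ({"synonymous_variant"}, ConsequenceClass.NONE),
            ({"upstream_gene_variant", "weird_term"}, ConsequenceClass.NONE),
        ],
    )
    def test_examples(self, terms, expected):
        assert classify_consequence(terms) is expected

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            classify_consequence(set())

    @given(
        terms=st.sets(
            st.sampled_from(
                sorted(PLOF_TERMS | MISSENSE_TERMS)
                + ["synonymous_variant", "intron_variant", "5_prime_UTR_variant"]
            ),
            min_size=1,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_pav_is_union_of_plof_and_missense(self, terms):
        """PAV qualification is exactly pLoF-or-missense qualification."""
        cls = classify_consequence(terms)
        plof_ok = ConsequenceClass.PLOF.admits(cls)
        ms_ok = ConsequenceClass.MISSENSE.admits(cls)
        assert ConsequenceClass.PAV.admits(cls) == (plof_ok or ms_ok)
        assert not (plof_ok and ms_ok)  # a variant has one class


class TestHardyWeinberg:
    @pytest.mark.parametrize("counts", [(830, 0, 0), (0, 0, 830), (1, 0, 0)])
    def test_monomorphic_sites(self, counts):
        assert hwe_exact_test(counts) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(500, 10, 20), (100, 50, 10), (5, 3, 2), (830, 3, 0), (700, 0, 12), (50, 50, 50)],
    )
    def test_matches_exact_enumeration(self, counts):
        assert hwe_exact_test(counts) == pytest.approx(hwe_p_oracle(*counts), abs=1e-12)

    def test_allele_label_symmetry(self):
        assert hwe_exact_test((400, 30, 12)) == pytest.approx(
            hwe_exact_test((12, 30, 400)), abs=1e-14
        )

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=300, deadline=None)
    def test_exact_enumeration_property(self, counts):
        p = hwe_exact_test(counts)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_p_oracle(*counts), abs=1e-12)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            hwe_exact_test((0, 0, 0))
        with pytest.raises(ValueError):
            hwe_exact_test((-1, 2, 3))


class TestVariantQC:
    @pytest.mark.parametrize(
        "call_rate, qd, counts, expected",
        [
            (0.95, 10.0, (800, 30, 0), True),
            (0.90, 6.0, (800, 30, 0), True),   # thresholds pass at equality
            (0.85, 10.0, (800, 30, 0), False),  # call rate below 90%
            (0.95, 5.9, (800, 30, 0), False),   # QualByDepth below 6
            (0.95, 10.0, (700, 0, 130), False),  # gross heterozygote deficit
        ],
    )
    def test_threshold_behaviour(self, call_rate, qd, counts, expected):
        v = make_variant(call_rate=call_rate, qd=qd, counts=counts)
        assert passes_variant_qc(v, FilterConfig()) is expected

    def test_missing_qc_strict_raises(self):
        v = make_variant(call_rate=None)
        with pytest.raises(ValueError, match="missing QC"):
            passes_variant_qc(v, FilterConfig(strict=True))

    def test_missing_qc_lenient_passes(self):
        v = make_variant(call_rate=None)
        assert passes_variant_qc(v, FilterConfig(strict=False)) is True


class TestRarityFilter:
    @pytest.mark.parametrize(
        "afs, expected",
        [
            ({"nfe": 5e-5, "afr": 0.0}, True),
            ({"nfe": 2e-4}, False),     # exceeds 0.01% in one population
            ({"nfe": 1e-4}, False),     # strict inequality at the threshold
            ({"nfe": 5e-5, "afr": 3e-4}, False),  # popmax binds
            ({}, True),                 # absent from the reference
        ],
    )
    def test_popmax_rule(self, afs, expected):
        assert passes_rarity_filter(afs, 1e-4) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            passes_rarity_filter({"nfe": 0.0}, 0.0)


class TestTtnExonFilter:
    @pytest.mark.parametrize(
        "psi, expected",
        [(0.99, True), (0.90, True), (0.10, False), (None, False)],
    )
    def test_constitutive_exon_rule(self, psi, expected):
        v = make_variant(gene="TTN", terms=("stop_gained",), psi=psi)
        assert passes_ttn_exon_filter(v, FilterConfig()) is expected


class TestQualifyingVariants:
    def test_mechanism_matched_classes(self, filter_cfg):
        variants = [
            make_variant(gene="DSP", terms=("missense_variant",), pos=100),
            make_variant(gene="TTN", terms=("missense_variant",), pos=200),  # wrong class
            make_variant(gene="TTN", terms=("stop_gained",), psi=0.99, pos=300),
            make_variant(gene="MYH7", terms=("stop_gained",), pos=400),  # ms gene, pLoF variant
        ]
        qual = qualifying_variants(variants, DEFAULT_GENE_RULES, filter_cfg)
        assert variants[0].key in qual["DSP"]
        assert qual["TTN"] == {variants[2].key}
        assert qual["MYH7"] == set()

    def test_empty_input_yields_entry_per_rule_gene(self, filter_cfg):
        qual = qualifying_variants([], DEFAULT_GENE_RULES, filter_cfg)
        assert set(qual) == {r.gene for r in DEFAULT_GENE_RULES}
        assert all(v == set() for v in qual.values())

    def test_unruled_gene_ignored(self, filter_cfg):
        v = make_variant(gene="MYBPC3")
        qual = qualifying_variants([v], DEFAULT_GENE_RULES, filter_cfg)
        assert all(v.key not in s for s in qual.values())

    def test_duplicate_rules_rejected(self, filter_cfg):
        rules = [DEFAULT_GENE_RULES[0], DEFAULT_GENE_RULES[0]]
        with pytest.raises(ValueError, match="distinct"):
            qualifying_variants([], rules, filter_cfg)

    @pytest.mark.parametrize("maf_pair", [(1e-4, 5e-5), (1e-4, 1e-5)])
    def test_tightening_filters_never_adds_variants(self, filter_cfg, maf_pair):
        """Monotonicity: stricter MAF or PSI thresholds shrink the sets."""
        loose_maf, tight_maf = maf_pair
        variants = [
            make_variant(gene="DSP", afs={"nfe": af}, pos=100 + i)
            for i, af in enumerate([0.0, 2e-5, 4e-5, 8e-5, 2e-4])
        ] + [
            make_variant(gene="TTN", terms=("stop_gained",), psi=psi, pos=600 + i)
            for i, psi in enumerate([0.85, 0.92, 0.97, 1.0])
        ]
        loose = qualifying_variants(
            variants, DEFAULT_GENE_RULES,
            FilterConfig(maf_threshold=loose_maf, ttn_psi_threshold=0.90),
        )
        tight = qualifying_variants(
            variants, DEFAULT_GENE_RULES,
            FilterConfig(maf_threshold=tight_maf, ttn_psi_threshold=0.95),
        )
        for gene in loose:
            assert tight[gene] <= loose[gene]

    def test_fixture_qualifying_counts_match_manifest(self, table1, filter_cfg):
        cohort, manifest = table1
        qual = qualifying_variants(cohort.variants, DEFAULT_GENE_RULES, filter_cfg)
        female = {s.sample_id for s in cohort.samples if s.sex == "female"}
        for gene, expected in manifest["expected_carriers"].items():
            carriers = {
                sid
                for sid, flag in zip(
                    cohort.genotypes.sample_ids, cohort.genotypes.any_alt(qual[gene])
                )
                if flag
            }
            assert len(carriers & female) == expected["female_carriers"], gene
            assert len(carriers - female) == expected["male_carriers"], gene

    def test_verdict_report_covers_all_variants(self, table1, filter_cfg):
        cohort, manifest = table1
        report = qualification_report(cohort.variants, DEFAULT_GENE_RULES, filter_cfg)
        assert set(report) == {v.key for v in cohort.variants}
        n_qual = sum(1 for _, r in report.values() if r == REASON_QUALIFIES)
        expected = sum(
            e["female_carriers"] + e["male_carriers"]
            for e in manifest["expected_carriers"].values()
        )
        # one extra variant: the designated double-carrier's second variant
        assert n_qual == expected + 1
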