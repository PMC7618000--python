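"""Qualifying-variant selection for gene-based rare-variant burden analysis.

Turns annotated candidate variants into per-gene sets of *qualifying*
variants: variants that pass site-level QC (call rate, QualByDepth,
Hardy-Weinberg equilibrium), are rare in every reference population
(popmax MAF below threshold), belong to the consequence class consistent
with the gene's disease mechanism, and — for titin — alter a
constitutively expressed cardiac exon (high percent-spliced-in).

Sample-level QC (excess heterozygosity, sex checks, relatedness pruning)
is deliberately NOT performed here: the sample sheet is assumed to be
pre-cleaned upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger("dcmburden")

__all__ = [
    "ConsequenceClass",
    "VariantRecord",
    "GeneRule",
    "FilterConfig",
    "DEFAULT_GENE_RULES",
    "PLOF_TERMS",
    "MISSENSE_TERMS",
    "classify_consequence",
    "hwe_exact_test",
    "passes_variant_qc",
    "passes_rarity_filter",
    "passes_ttn_exon_filter",
    "qualifying_variants",
    "qualification_report",
    "REASON_QUALIFIES",
    "REASON_CALL_RATE",
    "REASON_QUAL_BY_DEPTH",
    "REASON_HWE",
    "REASON_MAF",
    "REASON_CLASS",
    "REASON_TTN_PSI",
    "REASON_NO_RULE",
]

# ---------------------------------------------------------------------------
# Consequence vocabulary (sequence-ontology terms as emitted by VEP on the
# MANE transcript)
# ---------------------------------------------------------------------------

#: Terms mapped to predicted loss of function: nonsense, frameshift and
#: essential splice-site variants.
PLOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: Terms mapped to the missense class: missense and in-frame indels.
MISSENSE_TERMS = frozenset(
    {
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
    }
)


class ConsequenceClass(str, Enum):
    """Variant consequence class used for mechanism-aware collapsing.

    ``PAV`` (protein-altering variant) is exactly the union of ``PLOF``
    and ``MISSENSE``; it is a valid *qualifying* class for a gene but is
    never returned by :func:`classify_consequence`, which reports the
    most specific class of a single variant.
    """

    PLOF = "pLoF"
    MISSENSE = "missense"
    PAV = "PAV"
    NONE = "none"

    def admits(self, observed: "ConsequenceClass") -> bool:
        """Whether a variant of class ``observed`` qualifies under ``self``."""
        if observed in (ConsequenceClass.NONE, ConsequenceClass.PAV):
            return False
        if self is ConsequenceClass.PAV:
            return observed in (ConsequenceClass.PLOF, ConsequenceClass.MISSENSE)
        return observed is self


def classify_consequence(terms: Iterable[str]) -> ConsequenceClass:
    """Classify a variant from its set of consequence terms.

    Loss-of-function terms take precedence over missense terms (a variant
    annotated both frameshift and missense is pLoF).  Term sets with no
    protein-altering term map to ``NONE``; an unrecognised vocabulary is
    not an error.
    """
    terms = set(terms)
    if not terms:
        raise ValueError("empty consequence term set")
    if terms & PLOF_TERMS:
        return ConsequenceClass.PLOF
    if terms & MISSENSE_TERMS:
        return ConsequenceClass.MISSENSE
    return ConsequenceClass.NONE


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic annotated candidate variant.

    ``pop_afs`` maps a reference-population label (e.g. ``nfe``, ``afr``)
    to its allele frequency; populations absent from the map contribute a
    frequency of zero.  ``genotype_counts`` are cohort genotype counts
    ``(n_homref, n_het, n_homalt)`` used for the Hardy-Weinberg test.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence_terms: frozenset = field(default_factory=frozenset)
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    ttn_psi: Optional[float] = None
    call_rate: Optional[float] = None
    qual_by_depth: Optional[float] = None
    genotype_counts: Optional[tuple] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("multi-allelic record; split to bi-allelic first")
        for pop, af in self.pop_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency out of [0,1] for {pop}: {af}")
        if self.ttn_psi is not None and not 0.0 <= self.ttn_psi <= 1.0:
            raise ValueError(f"ttn_psi out of [0,1]: {self.ttn_psi}")
        if self.genotype_counts is not None and any(
            n < 0 for n in self.genotype_counts
        ):
            raise ValueError("negative genotype count")

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def consequence_class(self) -> ConsequenceClass:
        return classify_consequence(self.consequence_terms)


@dataclass(frozen=True)
class GeneRule:
    """A gene and the variant class consistent with its disease mechanism."""

    gene: str
    qualifying_class: ConsequenceClass
    requires_constitutive_exon: bool = False

    def __post_init__(self):
        if self.qualifying_class is ConsequenceClass.NONE:
            raise ValueError("qualifying class must not be 'none'")


#: The twelve definitive DCM genes with their mechanism-consistent classes.
#: TTN and FLNC collapse truncating (pLoF) variants only, DES and MYH7
#: missense only, and DSP/LMNA/RBM20/SCN5A any protein-altering variant.
#: TTN additionally requires the variant to hit a constitutively expressed
#: cardiac exon.  The four genes excluded from testing in the source cohort
#: (BAG3, TNNC1, TNNT2, PLN) are assigned classes from the disease-mechanism
#: literature.
DEFAULT_GENE_RULES: tuple = (
    GeneRule("TTN", ConsequenceClass.PLOF, requires_constitutive_exon=True),
    GeneRule("FLNC", ConsequenceClass.PLOF),
    GeneRule("DES", ConsequenceClass.MISSENSE),
    GeneRule("MYH7", ConsequenceClass.MISSENSE),
    GeneRule("DSP", ConsequenceClass.PAV),
    GeneRule("LMNA", ConsequenceClass.PAV),
    GeneRule("RBM20", ConsequenceClass.PAV),
    GeneRule("SCN5A", ConsequenceClass.PAV),
    GeneRule("BAG3", ConsequenceClass.PAV),
    GeneRule("TNNC1", ConsequenceClass.MISSENSE),
    GeneRule("TNNT2", ConsequenceClass.MISSENSE),
    GeneRule("PLN", ConsequenceClass.PAV),
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site-level QC and rarity filtering.

    Defaults follow the cohort analysis: sites with call rate < 90%,
    QualByDepth < 6 or an exact Hardy-Weinberg p-value < 1e-6 are
    excluded, and qualifying variants must have MAF < 0.01% in every
    reference population.  The rarity comparison is strict (< threshold);
    the QC comparisons pass at equality.
    """

    maf_threshold: float = 1e-4
    min_call_rate: float = 0.90
    min_qual_by_depth: float = 6.0
    hwe_p_floor: float = 1e-6
    ttn_psi_threshold: float = 0.90
    strict: bool = True

    def __post_init__(self):
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError("maf_threshold must be in (0,1)")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0,1]")
        if self.min_qual_by_depth < 0:
            raise ValueError("min_qual_by_depth must be >= 0")
        if not 0.0 < self.hwe_p_floor < 1.0:
            raise ValueError("hwe_p_floor must be in (0,1)")
        if not 0.0 <= self.ttn_psi_threshold <= 1.0:
            raise ValueError("ttn_psi_threshold must be in [0,1]")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

# Relative guard when comparing outcome probabilities for the "as or less
# probable" sum; absorbs last-ulp noise between analytically equal weights.
_PROB_TIE_GUARD = 1e-9


def hwe_exact_test(genotype_counts: Sequence[int]) -> float:
    """Two-sided exact (Levene-Haldane) Hardy-Weinberg p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    the observed one.  Monomorphic sites return 1.

    Parameters
    ----------
    genotype_counts : (n_homref, n_het, n_homalt)
    """
    n_homref, n_het, n_homalt = (int(n) for n in genotype_counts)
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("negative genotype count")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_alt = n_het + 2 * n_homalt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # support: heterozygote counts with the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logw = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_major + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_minor + 1)
    )
    logw -= _logsumexp(logw)
    log_obs = logw[np.searchsorted(hets, n_het)]
    p = float(np.exp(logw[logw <= log_obs + _PROB_TIE_GUARD]).sum())
    return min(p, 1.0)


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def _logsumexp(x: np.ndarray) -> float:
    from scipy.special import logsumexp

    return float(logsumexp(x))


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def passes_variant_qc(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Site-level QC: call rate, QualByDepth and exact HWE.

    With ``cfg.strict`` (the default) missing QC fields raise; otherwise
    the variant is treated as passing and a warning is logged.
    """
    missing = [
        name
        for name, val in (
            ("call_rate", v.call_rate),
            ("qual_by_depth", v.qual_by_depth),
            ("genotype_counts", v.genotype_counts),
        )
        if val is None or (isinstance(val, float) and math.isnan(val))
    ]
    if missing:
        if cfg.strict:
            raise ValueError(
                f"variant {v.key} missing QC fields {missing} (strict mode)"
            )
        log.warning("variant %s missing QC fields %s; treated as passing", v.key, missing)
        return True
    if v.call_rate < cfg.min_call_rate:
        return False
    if v.qual_by_depth < cfg.min_qual_by_depth:
        return False
    return hwe_exact_test(v.genotype_counts) >= cfg.hwe_p_floor


def passes_rarity_filter(pop_afs: Mapping[str, float], threshold: float) -> bool:
    """True iff the variant is rare in *every* reference population.

    Implements a popmax rule over the populations supplied: the maximum
    allele frequency must be strictly below ``threshold``.  A variant
    absent from the reference (empty map) is rare.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    return max(pop_afs.values(), default=0.0) < threshold


def passes_ttn_exon_filter(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Restrict titin variants to constitutively expressed cardiac exons.

    Uses the exon inclusion proportion (percent spliced-in); a TTN variant
    with no PSI annotation is conservatively excluded.
    """
    if v.ttn_psi is None or (isinstance(v.ttn_psi, float) and math.isnan(v.ttn_psi)):
        log.warning("TTN variant %s has no PSI annotation; excluded", v.key)
        return False
    return v.ttn_psi >= cfg.ttn_psi_threshold


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------

REASON_QUALIFIES = "qualifies"
REASON_CALL_RATE = "qc_call_rate"
REASON_QUAL_BY_DEPTH = "qc_qual_by_depth"
REASON_HWE = "qc_hwe"
REASON_MAF = "maf"
REASON_CLASS = "class"
REASON_TTN_PSI = "ttn_psi"
REASON_NO_RULE = "no_rule"


def _qualify_one(v: VariantRecord, rule: GeneRule, cfg: FilterConfig) -> str:
    """Verdict for one variant against its gene rule; first failing reason."""
    missing_qc = (
        v.call_rate is None
        or v.qual_by_depth is None
        or v.genotype_counts is None
        or (isinstance(v.call_rate, float) and math.isnan(v.call_rate))
        or (isinstance(v.qual_by_depth, float) and math.isnan(v.qual_by_depth))
    )
    if missing_qc:
        if cfg.strict:
            raise ValueError(f"variant {v.key} missing QC fields (strict mode)")
        log.warning("variant %s missing QC fields; QC treated as passing", v.key)
    else:
        if v.call_rate < cfg.min_call_rate:
            return REASON_CALL_RATE
        if v.qual_by_depth < cfg.min_qual_by_depth:
            return REASON_QUAL_BY_DEPTH
        if hwe_exact_test(v.genotype_counts) < cfg.hwe_p_floor:
            return REASON_HWE
    if not passes_rarity_filter(v.pop_afs, cfg.maf_threshold):
        return REASON_MAF
    if not rule.qualifying_class.admits(v.consequence_class):
        return REASON_CLASS
    if rule.requires_constitutive_exon and not passes_ttn_exon_filter(v, cfg):
        return REASON_TTN_PSI
    return REASON_QUALIFIES


def qualification_report(
    variants: Sequence[VariantRecord],
    rules: Sequence[GeneRule],
    cfg: FilterConfig,
) -> dict:
    """Per-variant verdicts: variant key -> (gene, reason).

    The reason is :data:`REASON_QUALIFIES` for qualifying variants,
    otherwise the first failing filter in the order QC (call rate,
    QualByDepth, HWE), rarity, consequence class, TTN exon inclusion;
    variants in genes without a rule get :data:`REASON_NO_RULE`.
    """
    by_gene = {r.gene: r for r in rules}
    if len(by_gene) != len(rules):
        raise ValueError("gene rules must cover distinct genes")
    report = {}
    for v in variants:
        rule = by_gene.get(v.gene)
        report[v.key] = (v.gene, REASON_NO_RULE if rule is None else _qualify_one(v, rule, cfg))
    return report


def qualifying_variants(
    variants: Sequence[VariantRecord],
    rules: Sequence[GeneRule],
    cfg: FilterConfig,
) -> dict:
    """Map every rule gene to its set of qualifying variant keys.

    A variant qualifies for gene *g* iff it is annotated to *g*, passes
    QC and the rarity filter, its consequence class is admitted by the
    gene's qualifying class, and (for TTN) the constitutive-exon filter
    passes.  Every rule gene appears in the result, possibly with an
    empty set.  Variants annotated to genes without a rule are ignored
    and counted in a log summary.
    """
    report = qualification_report(variants, rules, cfg)
    out = {r.gene: set() for r in rules}
    n_unruled = 0
    reasons: dict = {}
    for key, (gene, reason) in report.items():
        reasons[reason] = reasons.get(reason, 0) + 1
        if reason == REASON_QUALIFIES:
            out[gene].add(key)
        elif reason == REASON_NO_RULE:
            n_unruled += 1
    if n_unruled:
        log.info("%d variants annotated to genes without a rule were ignored", n_unruled)
    log.info("variant qualification summary: %s", dict(sorted(reasons.items())))
    return out
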