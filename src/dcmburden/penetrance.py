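"""Cross-sectional, sex-stratified penetrance estimation.

The penetrance of qualifying variants in a gene — P(disease | carrier) —
is estimated by Bayes' rule from the aggregated variant frequency in
diagnosed cases, the frequency in an unselected reference population,
and a disease-prevalence prior:

    penetrance = prevalence * f_case / f_pop,   clamped to [0, 1].

Frequencies are computed on carrier counts per individual by default; at
the rarity threshold used for qualifying variants (MAF < 0.01%) the
factor of two between carrier and allele frequencies cancels in the
ratio, and an allele-count mode is available.  Uncertainty is propagated
by Monte Carlo: case and population frequencies are drawn from Jeffreys
Beta posteriors, the clamped product is formed per draw, and the 2.5/97.5
percentiles reported.  The prevalence is treated as fixed unless a 95%
CI is supplied, in which case it is drawn log-normally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger("dcmburden")

__all__ = [
    "FrequencyObservation",
    "PenetranceEstimate",
    "estimate_penetrance",
    "sex_stratified_penetrance",
    "DEFAULT_PREVALENCE",
    "DEFAULT_DRAWS",
    "DEFAULT_SEED",
]

#: Ship-with default DCM prevalence.  This is a placeholder for a
#: cohort-appropriate value and should be set explicitly for any real
#: analysis; a warning is logged whenever it is used implicitly.
DEFAULT_PREVALENCE = 1.0 / 250.0
DEFAULT_DRAWS = 100_000
DEFAULT_SEED = 20250423

STRATA = ("all", "female", "male")


@dataclass(frozen=True)
class FrequencyObservation:
    """Carrier (or allele) count over a sample of individuals (or alleles)."""

    carriers: int
    n: int
    stratum: str = "all"

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("sample size must be positive")
        if not 0 <= self.carriers <= self.n:
            raise ValueError(f"carriers must be in [0, n], got {self.carriers}/{self.n}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")

    @property
    def frequency(self) -> float:
        return self.carriers / self.n


@dataclass
class PenetranceEstimate:
    """Point estimate and Monte-Carlo 95% CI of P(disease | carrier)."""

    gene: str
    stratum: str
    point: float
    ci95: tuple
    prevalence_used: float
    n_draws: int
    seed: int
    n_clamped: int = 0

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.point <= hi <= 1.0):
            raise ValueError(f"CI must bracket the point in [0,1]: {self.ci95}, {self.point}")


def _posterior_draws(obs: FrequencyObservation, n_draws: int, rng: np.random.Generator,
                     allele_counts: bool) -> np.ndarray:
    """Jeffreys Beta(c + 1/2, n - c + 1/2) posterior draws of the frequency."""
    n = 2 * obs.n if allele_counts else obs.n
    return rng.beta(obs.carriers + 0.5, n - obs.carriers + 0.5, size=n_draws)


def estimate_penetrance(
    case_obs: FrequencyObservation,
    pop_obs: FrequencyObservation,
    prevalence: float,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
    gene: str = "",
    prevalence_ci: Optional[tuple] = None,
    allele_counts: bool = False,
) -> PenetranceEstimate:
    """Estimate P(disease | qualifying variant) for one gene and stratum.

    Parameters
    ----------
    case_obs, pop_obs
        Carrier counts among diagnosed cases and in the reference
        population for the same stratum.
    prevalence
        Disease prevalence in the stratum, treated as known unless
        ``prevalence_ci`` (a 95% CI) is given, in which case it is drawn
        log-normally around ``prevalence``.
    allele_counts
        Interpret counts as allele counts over ``2n`` chromosomes.

    The point estimate is ``clamp(prevalence * f_case / f_pop, 0, 1)``;
    the CI comes from ``n_draws`` Monte-Carlo draws of both frequencies
    from Jeffreys Beta posteriors (clamping applied per draw).
    Bit-reproducible given ``seed``.
    """
    if pop_obs.carriers == 0:
        raise ValueError("population carrier count is zero: penetrance ratio undefined")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    if case_obs.stratum != pop_obs.stratum:
        raise ValueError(
            f"stratum mismatch: case {case_obs.stratum!r} vs population {pop_obs.stratum!r}"
        )
    denom_case = 2 * case_obs.n if allele_counts else case_obs.n
    denom_pop = 2 * pop_obs.n if allele_counts else pop_obs.n
    f_case = case_obs.carriers / denom_case
    f_pop = pop_obs.carriers / denom_pop
    point = min(1.0, prevalence * f_case / f_pop)

    rng = np.random.default_rng(seed)
    draws_case = _posterior_draws(case_obs, n_draws, rng, allele_counts)
    draws_pop = _posterior_draws(pop_obs, n_draws, rng, allele_counts)
    if prevalence_ci is not None:
        lo, hi = prevalence_ci
        if not 0.0 < lo <= prevalence <= hi < 1.0:
            raise ValueError("prevalence CI must bracket the prevalence within (0,1)")
        sigma = (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)
        prev_draws = np.exp(rng.normal(math.log(prevalence), sigma, size=n_draws))
    else:
        prev_draws = prevalence
    raw = prev_draws * draws_case / draws_pop
    n_clamped = int((raw > 1.0).sum())
    if n_clamped:
        log.info("%d/%d penetrance draws clamped at 1", n_clamped, n_draws)
    draws = np.minimum(raw, 1.0)
    lo, hi = (float(q) for q in np.percentile(draws, [2.5, 97.5]))
    # a boundary point (e.g. zero case carriers) must stay inside its CI
    ci = (min(lo, point), max(hi, point))
    return PenetranceEstimate(
        gene=gene,
        stratum=case_obs.stratum,
        point=point,
        ci95=ci,
        prevalence_used=prevalence,
        n_draws=n_draws,
        seed=seed,
        n_clamped=n_clamped,
    )


def sex_stratified_penetrance(
    gene: str,
    case_counts: Mapping[str, tuple],
    pop_counts: Mapping[str, tuple],
    prevalence: Mapping[str, float],
    n_draws: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
    allele_counts: bool = False,
) -> list:
    """One penetrance estimate per stratum, each with its own inputs.

    ``case_counts`` and ``pop_counts`` map stratum (``all``/``female``/
    ``male``) to ``(carriers, n)``; strata present in both maps are
    estimated.  Each stratum uses its own prevalence and an independent,
    deterministically derived random stream.
    """
    shared = [s for s in STRATA if s in case_counts and s in pop_counts]
    if not shared:
        raise ValueError("no stratum present in both case and population counts")
    estimates = []
    for i, stratum in enumerate(shared):
        if stratum not in prevalence:
            raise ValueError(f"no prevalence supplied for stratum {stratum!r}")
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        estimates.append(
            estimate_penetrance(
                FrequencyObservation(*case_counts[stratum], stratum=stratum),
                FrequencyObservation(*pop_counts[stratum], stratum=stratum),
                prevalence[stratum],
                n_draws=n_draws,
                seed=sub_seed,
                gene=gene,
                allele_counts=allele_counts,
            )
        )
    return estimates
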