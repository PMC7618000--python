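"""Independent oracles used to verify the exact statistics.

Everything here recomputes quantities by a different route than the
package: exact integer/rational arithmetic for the conditional
(hypergeometric and Levene-Haldane) enumerations, golden-section search
directly on the conditional likelihood for the odds-ratio MLE, and a
different random generator plus inverse-CDF sampling for the penetrance
Monte Carlo.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_p_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact-rational Levene-Haldane two-sided p (probability-mass sum)."""
    n = n_homref + n_het + n_homalt
    n_alt = n_het + 2 * n_homalt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = (
            math.factorial(n)
            // (math.factorial(hom_major) * math.factorial(h) * math.factorial(hom_minor))
        ) * 2**h
    w_obs = weights[n_het]
    total = sum(weights.values())
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


def hwe_p_oracle_group(n: int, n_minor: int) -> dict:
    """Levene-Haldane p for every heterozygote count at fixed allele
    counts (exact integer weights); keys are heterozygote counts."""
    if n_minor == 0:
        return {0: 1.0}
    hets = list(range(n_minor % 2, n_minor + 1, 2))
    ws = []
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        ws.append(
            (math.factorial(n)
             // (math.factorial(hom_major) * math.factorial(h) * math.factorial(hom_minor)))
            << h
        )
    total = sum(ws)
    order = sorted(range(len(hets)), key=lambda i: ws[i])
    acc = 0
    by_weight: dict = {}
    for i in order:
        acc += ws[i]
        by_weight[ws[i]] = acc
    return {hets[i]: by_weight[ws[i]] / total for i in range(len(hets))}


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    weights = {x: math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), sum(weights.values())))


def fisher_p_oracle_group(r1: int, r2: int, k: int) -> dict:
    """Two-sided p for every observed cell given fixed margins (exact ints)."""
    lo, hi = max(0, k - r2), min(k, r1)
    xs = list(range(lo, hi + 1))
    ws = [math.comb(r1, x) * math.comb(r2, k - x) for x in xs]
    total = sum(ws)
    order = sorted(range(len(xs)), key=lambda i: ws[i])
    prefix, acc = {}, 0
    for i in order:
        acc += ws[i]
        prefix[i] = acc
    # ties: every x shares the cumulative sum of its weight class
    by_weight: dict = {}
    for i in order:
        by_weight[ws[i]] = prefix[i]
    # integer weights are exact; a single float division loses < 1e-15
    return {xs[i]: by_weight[ws[i]] / total for i in range(len(xs))}


def cmle_or_oracle(a: int, b: int, c: int, d: int, iters: int = 200) -> float:
    """Conditional-MLE odds ratio by golden-section search on the
    non-central hypergeometric log-likelihood (concave in log psi)."""
    r1, r2, k = a + b, c + d, a + c
    lo_s, hi_s = max(0, k - r2), min(k, r1)
    if a == lo_s:
        return 0.0
    if a == hi_s:
        return math.inf
    xs = np.arange(lo_s, hi_s + 1)
    logw = np.array(
        [math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
         + math.lgamma(r2 + 1) - math.lgamma(k - x + 1) - math.lgamma(r2 - k + x + 1)
         for x in xs]
    )

    def ll(t: float) -> float:
        z = logw + xs * t
        m = z.max()
        return a * t - (m + math.log(np.exp(z - m).sum()))

    lo, hi = -60.0, 60.0
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = ll(x1), ll(x2)
    for _ in range(iters):
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = ll(x2)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = ll(x1)
    return math.exp(0.5 * (lo + hi))


def cmle_or_oracle_group(r1: int, r2: int, k: int, iters: int = 90) -> dict:
    """Golden-section conditional MLE for every interior cell, vectorised."""
    lo_s, hi_s = max(0, k - r2), min(k, r1)
    xs = np.arange(lo_s, hi_s + 1)
    logw = np.array(
        [math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
         + math.lgamma(r2 + 1) - math.lgamma(k - x + 1) - math.lgamma(r2 - k + x + 1)
         for x in xs]
    )
    out = {lo_s: 0.0, hi_s: math.inf}
    interior = np.arange(lo_s + 1, hi_s)
    if interior.size == 0:
        return out

    def ll(t: np.ndarray) -> np.ndarray:
        z = logw[None, :] + xs[None, :] * t[:, None]
        m = z.max(axis=1)
        return interior * t - (m + np.log(np.exp(z - m[:, None]).sum(axis=1)))

    # golden-section search with function-value reuse (one eval per step)
    lo = np.full(interior.shape, -60.0)
    hi = np.full(interior.shape, 60.0)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = ll(x1), ll(x2)
    for _ in range(iters):
        move = f1 < f2  # the maximum lies right of x1
        lo = np.where(move, x1, lo)
        hi = np.where(move, hi, x2)
        x1n = np.where(move, x2, hi - invphi * (hi - lo))
        x2n = np.where(move, lo + invphi * (hi - lo), x1)
        fresh = ll(np.where(move, x2n, x1n))
        f1n = np.where(move, f2, fresh)
        f2n = np.where(move, fresh, f1)
        x1, x2, f1, f2 = x1n, x2n, f1n, f2n
    for x, t in zip(interior, 0.5 * (lo + hi)):
        out[int(x)] = math.exp(t)
    return out


def penetrance_ci_oracle(case_carriers, case_n, pop_carriers, pop_n,
                         prevalence, n_draws, seed):
    """Monte-Carlo 95% CI via a different generator (Philox) and
    inverse-CDF Beta sampling instead of direct beta draws."""
    from scipy.stats import beta

    rng = np.random.Generator(np.random.Philox(seed))
    f_case = beta.ppf(rng.random(n_draws), case_carriers + 0.5, case_n - case_carriers + 0.5)
    f_pop = beta.ppf(rng.random(n_draws), pop_carriers + 0.5, pop_n - pop_carriers + 0.5)
    draws = np.minimum(prevalence * f_case / f_pop, 1.0)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)
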