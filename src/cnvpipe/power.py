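"""Case-control power for a rare CNV locus.

Models a locus as a carrier proportion ``q`` in controls whose odds are
multiplied by the odds ratio in cases, giving a case carrier proportion
``p1 = OR*q / (1 - q + OR*q)``.  Power is the probability that a two-group
comparison of carrier counts rejects at level alpha.

Three power routes are provided:

* ``method="exact"`` (default): deterministic enumeration of Fisher's exact
  test over the joint binomial distribution of carrier counts — the
  reference at rare frequencies, where large-sample approximations are off
  by far more than the quantities of interest;
* ``method="chi2"``: the classic non-central chi-square (two-proportion)
  approximation — instant, adequate for common variants, used for curve
  tracing;
* :func:`simulate_power`: seeded Monte-Carlo of the same Fisher test, the
  independent cross-check of the enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    control_freq: float
    odds_ratio: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    sided: str = "two-sided"  # "two-sided" | "one-sided"

    def __post_init__(self) -> None:
        if not 0 < self.control_freq < 1:
            raise ValueError("control_freq must be in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.sided not in ("two-sided", "one-sided"):
            raise ValueError(f"sided must be two-/one-sided, got {self.sided!r}")


def case_frequency(control_freq: float, odds_ratio: float) -> float:
    """Carrier proportion in cases when control odds are scaled by the OR."""
    q = control_freq
    return odds_ratio * q / (1 - q + odds_ratio * q)


def _fisher_p(a: int, n1: int, c: int, n0: int, sided: str) -> float:
    alt = "two-sided" if sided == "two-sided" else "greater"
    return stats.fisher_exact([[a, n1 - a], [c, n0 - c]], alternative=alt)[1]


def _chi2_power(query: PowerQuery) -> float:
    p1 = case_frequency(query.control_freq, query.odds_ratio)
    p0 = query.control_freq
    denom = p1 * (1 - p1) / query.n_cases + p0 * (1 - p0) / query.n_controls
    lam = (p1 - p0) ** 2 / denom
    if query.sided == "two-sided":
        crit = stats.chi2.ppf(1 - query.alpha, 1)
        return float(stats.ncx2.sf(crit, 1, lam))
    # one-sided: normal test toward enrichment
    zcrit = stats.norm.ppf(1 - query.alpha)
    return float(stats.norm.sf(zcrit - math.sqrt(lam)))


def _exact_power(query: PowerQuery, tail: float = 1e-10) -> float:
    """Sum P(a)P(c) over carrier-count pairs where Fisher rejects.

    Binomial tails below ``tail`` total mass are truncated; for each case
    count the significant control counts form a lower set (one-sided) or
    at most two tail sets, but we simply test each pair — counts are small
    at the rare frequencies this is meant for.
    """
    p1 = case_frequency(query.control_freq, query.odds_ratio)
    p0 = query.control_freq
    amax = int(stats.binom.ppf(1 - tail, query.n_cases, p1))
    cmax = int(stats.binom.ppf(1 - tail, query.n_controls, p0))
    pa = stats.binom.pmf(np.arange(amax + 1), query.n_cases, p1)
    pc = stats.binom.pmf(np.arange(cmax + 1), query.n_controls, p0)
    total = 0.0
    for a in range(amax + 1):
        if pa[a] < tail / (amax + 1):
            continue
        for c in range(cmax + 1):
            joint = pa[a] * pc[c]
            if joint < 1e-14:
                continue
            if _fisher_p(a, query.n_cases, c, query.n_controls, query.sided) < query.alpha:
                total += joint
    return float(min(total, 1.0))


def analytic_power(query: PowerQuery, method: str = "exact") -> float:
    """Deterministic power of the carrier-count comparison.

    ``method="exact"`` enumerates Fisher's exact test over the binomial
    sampling distribution; ``method="chi2"`` uses the non-central chi-square
    two-proportion approximation.  Degenerate queries (expected carriers
    ~ 0 everywhere) warn and return ~alpha-level power.
    """
    p1 = case_frequency(query.control_freq, query.odds_ratio)
    if p1 * query.n_cases < 1e-8 and query.control_freq * query.n_controls < 1e-8:
        warnings.warn("expected carrier counts ~ 0; power degenerates to the test size")
        return query.alpha
    if method == "exact":
        return _exact_power(query)
    if method == "chi2":
        return _chi2_power(query)
    raise ValueError(f"unknown method {method!r}")


def simulate_power(
    query: PowerQuery, n_rep: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo power: binomial carrier draws scored by Fisher's test."""
    rng = np.random.default_rng(seed)
    p1 = case_frequency(query.control_freq, query.odds_ratio)
    a = rng.binomial(query.n_cases, p1, n_rep)
    c = rng.binomial(query.n_controls, query.control_freq, n_rep)
    cache: dict[tuple[int, int], bool] = {}
    hits = 0
    for ai, ci in zip(a.tolist(), c.tolist()):
        key = (ai, ci)
        if key not in cache:
            cache[key] = (
                _fisher_p(ai, query.n_cases, ci, query.n_controls, query.sided)
                < query.alpha
            )
        hits += cache[key]
    return hits / n_rep


def or_for_power(
    control_freq: float,
    n_cases: int,
    n_controls: int,
    target_power: float = 0.8,
    alpha: float = 0.05,
    sided: str = "two-sided",
    method: str = "chi2",
    tol: float = 1e-4,
    or_max: float = 1e6,
) -> float:
    """Smallest OR giving ``target_power`` at this control frequency.

    Bisection on log OR; power is monotone increasing in OR.  Returns
    ``inf`` (with a warning) when even ``or_max`` cannot reach the target.
    The chi-square method is the default for curve tracing (the exact
    enumeration is available but much slower inside a root search).
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")

    def power_at(orr: float) -> float:
        return analytic_power(
            PowerQuery(control_freq, orr, n_cases, n_controls, alpha, sided), method
        )

    lo, hi = 1.0, 2.0
    while power_at(hi) < target_power:
        hi *= 4
        if hi > or_max:
            warnings.warn(
                f"no OR below {or_max:g} reaches power {target_power} at q={control_freq:g}"
            )
            return float("inf")
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        p = power_at(mid)
        if abs(p - target_power) < tol:
            return mid
        if p < target_power:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def power_curve(
    freqs,
    n_cases: int,
    n_controls: int,
    target_power: float = 0.8,
    alpha: float = 0.05,
    sided: str = "two-sided",
    method: str = "chi2",
):
    """The (frequency, minimal OR) 80%-power frontier of a study design."""
    return [
        (float(q), or_for_power(q, n_cases, n_controls, target_power, alpha, sided, method))
        for q in freqs
    ]
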