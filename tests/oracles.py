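"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive — direct enumeration and direct
formulas — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Fisher's exact test by exact rational hypergeometric enumeration
# ---------------------------------------------------------------------------

def _hypergeom_pmf_exact(x: int, row1: int, row2: int, col1: int) -> Fraction:
    """P(X = x) for the 2x2 table distribution with fixed margins, exact."""
    return Fraction(
        math.comb(row1, x) * math.comb(row2, col1 - x),
        math.comb(row1 + row2, col1),
    )


def fisher_enumeration(a: int, b: int, c: int, d: int, sided: str = "two-sided") -> float:
    """Fisher exact p by summing exact rational point probabilities.

    Two-sided: mass of all tables with point probability <= the observed
    table's (exact rational comparison, no float ties).  One-sided: upper
    tail of the case-carrier count.
    """
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = _hypergeom_pmf_exact(a, row1, row2, col1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = _hypergeom_pmf_exact(x, row1, row2, col1)
        if sided == "two-sided":
            if px <= p_obs:
                total += px
        else:  # upper tail: carrier count in cases >= observed
            if x >= a:
                total += px
    return float(total)


# ---------------------------------------------------------------------------
# CMH statistic by direct formula
# ---------------------------------------------------------------------------

def cmh_direct(tables) -> tuple[float, float]:
    """CMH chi-square (no continuity correction) from the textbook formula.

    stat = (sum_k (a_k - E a_k))^2 / sum_k Var a_k with hypergeometric
    moments per stratum.  Returns (statistic, p) with p from the chi2(1)
    survival function.
    """
    from scipy.stats import chi2

    num = 0.0
    var = 0.0
    for (a, b, c, d) in tables:
        n = a + b + c + d
        if n <= 1:
            continue
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        num += a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if var == 0:
        return float("nan"), float("nan")
    stat = num * num / var
    return stat, float(chi2.sf(stat, 1))


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected Pearson chi-square statistic for one 2x2."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------
# Pooled OR / Woolf CI by direct arithmetic
# ---------------------------------------------------------------------------

def pooled_or_ci_direct(a: int, b: int, c: int, d: int):
    orr = (a * d) / (b * c) if c > 0 and b > 0 else None
    cells = [a, b, c, d]
    if min(cells) == 0:
        cells = [x + 0.5 for x in cells]
    aa, bb, cc, dd = cells
    lor = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = 1.96
    return orr, (math.exp(lor - z * se), math.exp(lor + z * se))


# ---------------------------------------------------------------------------
# Brute-force call joining (pairwise merge to fixpoint, arbitrary order)
# ---------------------------------------------------------------------------

def join_bruteforce(segments, frac: float = 0.5):
    """Merge (start, end, n_probes) triples on one chromosome/type.

    Repeatedly merges *any* mergeable pair until none remains, regardless of
    coordinate order — the reference for the scan algorithm's fixpoint.
    """
    segs = [tuple(s) for s in segments]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(segs)), 2):
            s1, e1, p1 = segs[i]
            s2, e2, p2 = segs[j]
            if s1 > s2:
                (s1, e1, p1), (s2, e2, p2) = (s2, e2, p2), (s1, e1, p1)
            gap = s2 - e1 - 1
            len1, len2 = e1 - s1 + 1, e2 - s2 + 1
            if gap < frac * (len1 + len2):
                merged = (min(s1, s2), max(e1, e2), p1 + p2)
                segs = [s for k, s in enumerate(segs) if k not in (i, j)]
                segs.append(merged)
                changed = True
                break
    return sorted(segs)


def filter_bruteforce(segments, lcr, cfg):
    """Reference filter: (start, end, n_probes) + LCR (start, end) list.

    Returns (kept, removed-with-reason), reasons in the fixed order
    length -> probes -> LCR -> density.
    """
    kept, removed = [], []
    for (s, e, p) in segments:
        length = e - s + 1
        covered = np.zeros(length, dtype=bool)
        for (ls, le) in lcr:
            lo, hi = max(s, ls), min(e, le)
            if lo <= hi:
                covered[lo - s : hi - s + 1] = True
        if length < cfg.min_length_bp:
            removed.append(((s, e, p), "min_length"))
        elif p < cfg.min_probes:
            removed.append(((s, e, p), "min_probes"))
        elif covered.sum() / length > cfg.max_lcr_overlap_fraction:
            removed.append(((s, e, p), "lcr_overlap"))
        elif p / length < cfg.min_probe_density:
            removed.append(((s, e, p), "probe_density"))
        else:
            kept.append((s, e, p))
    return kept, removed


# ---------------------------------------------------------------------------
# Exhaustive permutation burden
# ---------------------------------------------------------------------------

def burden_exhaustive(counts, n_cases: int) -> tuple[float, float]:
    """Exact one-sided permutation p for the rate-difference excess.

    Enumerates every choice of which samples are labeled cases (single
    stratum).  Returns (observed excess, exact p) where the observed labels
    are the first ``n_cases`` entries of ``counts``.
    """
    counts = list(counts)
    n = len(counts)
    n_controls = n - n_cases
    total = sum(counts)

    def excess(case_idx):
        cs = sum(counts[i] for i in case_idx)
        return 100.0 * (cs / n_cases - (total - cs) / n_controls)

    obs = excess(range(n_cases))
    hits = 0
    m = 0
    for combo in itertools.combinations(range(n), n_cases):
        m += 1
        if excess(combo) >= obs - 1e-12:
            hits += 1
    return obs, hits / m
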