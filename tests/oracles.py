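"""Independent oracles used by the tests.

Everything here is computed from first principles (combinatorics, closed
forms, direct enumeration) and never calls the implementation under test.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import binom


def fisher_one_tailed_enum(sb: int, fb: int, sa: int, fa: int) -> float:
    """Exact one-tailed Fisher p (decrease in success) by direct enumeration
    of the conditional hypergeometric distribution."""
    nb, na = sb + fb, sa + fa
    k_succ, n_total = sb + sa, nb + na
    total = comb(n_total, nb)
    p = 0.0
    for x in range(max(0, k_succ - na), min(k_succ, nb) + 1):
        if x >= sb:
            p += comb(k_succ, x) * comb(n_total - k_succ, nb - x) / total
    return p


def exact_selection_power(
    p_before: float, p_after: float, n: int, n_targets: int = 4, alpha: float = 0.05
) -> float:
    """Exact probability that the representative target (argmin of the
    success-rate delta over ``n_targets`` iid targets, ties broken by index)
    is flagged by the one-tailed Fisher test at level alpha.

    Sums P(target j selected and rejected) over the 21x21 binomial outcome
    grid using iid order statistics.
    """
    outcomes = []
    for sb in range(n + 1):
        pb = binom.pmf(sb, n, p_before)
        for sa in range(n + 1):
            pr = pb * binom.pmf(sa, n, p_after)
            d = (sa - sb) / n
            rej = fisher_one_tailed_enum(sb, n - sb, sa, n - sa) < alpha
            outcomes.append((d, rej, pr))
    deltas = np.array([o[0] for o in outcomes])
    rejs = np.array([o[1] for o in outcomes])
    prs = np.array([o[2] for o in outcomes])

    total = 0.0
    for d, rej, pr in zip(deltas, rejs, prs):
        if not rej:
            continue
        p_gt = prs[deltas > d].sum()  # earlier targets must be strictly worse-ranked
        p_ge = prs[deltas >= d].sum()  # later targets lose ties to lower index
        for j in range(1, n_targets + 1):
            total += pr * p_gt ** (j - 1) * p_ge ** (n_targets - j)
    return float(total)


def min_jerk_position(t_ms: np.ndarray, onset_ms: float, duration_ms: float, amplitude: float) -> np.ndarray:
    """Closed-form minimum-jerk displacement profile (the generator's model,
    restated independently for trace-level checks)."""
    tau = np.clip((t_ms - onset_ms) / duration_ms, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def min_jerk_speed(t_ms: np.ndarray, onset_ms: float, duration_ms: float, amplitude: float) -> np.ndarray:
    """Analytic speed (deg/s) of the minimum-jerk profile."""
    tau = (t_ms - onset_ms) / duration_ms
    v = np.where(
        (tau >= 0) & (tau <= 1),
        30 * tau**2 * (1 - tau) ** 2 * amplitude / (duration_ms / 1000.0),
        0.0,
    )
    return v


def welch_formula(m1, s1, n1, m2, s2, n2):
    """Welch t, Satterthwaite df, and the two-sided p straight from the
    textbook formulas (p via the regularized incomplete beta through scipy's
    t distribution)."""
    from scipy.stats import t as t_dist

    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    return t, df, 2.0 * t_dist.sf(abs(t), df)
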