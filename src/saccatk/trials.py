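"""Trial classification and behavioral statistics for visually guided saccade
tasks (step / overlap / round) and reversible-inactivation sessions.

Success definition: after the go signal (fixation offset; coincident with
target onset in the step task) the first saccade must start within 1000 ms,
be non-anticipatory (reaction time >= 100 ms), reach the target window within
200 ms of leaving fixation, and land inside the window directly (no corrective
step before window entry). The target window is a circle of radius
eccentricity * sin(22.5 deg), half the distance between adjacent 45-deg-spaced
targets, so neighboring windows never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .eyekin import SaccadeEvent

__all__ = [
    "Outcome",
    "TargetLayout",
    "TrialEvents",
    "TrialRecord",
    "window_radius",
    "classify_trial",
    "success_rate",
    "select_representative_target",
    "session_comparison",
    "fisher_exact_one_tailed",
    "compare_reaction_times",
    "iqr_bootstrap_ci",
    "rank_two_way_anova",
]


class Outcome(str, Enum):
    SUCCESS = "success"
    ANTICIPATORY_EXCLUDED = "anticipatory_excluded"
    FIXATION_BREAK_EXCLUDED = "fixation_break_excluded"
    ERROR_OFFTARGET = "error_offtarget"
    ERROR_TIMING = "error_timing"
    ERROR_MULTISTEP = "error_multistep"


EXCLUDED = {Outcome.ANTICIPATORY_EXCLUDED, Outcome.FIXATION_BREAK_EXCLUDED}


def window_radius(eccentricity_deg: float) -> float:
    """Target-window radius: eccentricity * sin(22.5 deg).

    This is half the chord between adjacent targets separated by 45 deg at the
    same eccentricity, so adjacent windows are tangent and never overlap.
    """
    if eccentricity_deg <= 0:
        raise ValueError("eccentricity must be positive")
    return eccentricity_deg * math.sin(math.radians(22.5))


@dataclass
class TargetLayout:
    """Iso-eccentric target array with circular acceptance windows."""

    eccentricity_deg: float
    directions_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0)
    window_radius_deg: float | None = None

    def __post_init__(self) -> None:
        if self.window_radius_deg is None:
            self.window_radius_deg = window_radius(self.eccentricity_deg)

    def target_position(self, direction_deg: float) -> np.ndarray:
        a = math.radians(direction_deg)
        return self.eccentricity_deg * np.array([math.cos(a), math.sin(a)])


@dataclass
class TrialEvents:
    """Timing and geometry of one trial; times in ms on the trace clock."""

    task: str
    fix_on_ms: float
    fix_off_ms: float  # the go signal
    target_on_ms: float
    target_direction_deg: float
    target_eccentricity_deg: float
    trial_id: int = 0


@dataclass
class TrialRecord:
    """Classified trial: events, saccades, outcome, first-saccade endpoint errors."""

    events: TrialEvents
    saccades: list[SaccadeEvent]
    outcome: Outcome
    reaction_time_ms: float | None = None
    direction_error_deg: float | None = None
    eccentricity_error_deg: float | None = None


def _wrap_deg(a: float) -> float:
    w = (a + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def classify_trial(
    events: TrialEvents,
    saccades: list[SaccadeEvent],
    layout: TargetLayout,
    fixation_radius_deg: float = 2.0,
    rt_min_ms: float = 100.0,
    rt_max_ms: float = 1000.0,
    entry_limit_ms: float = 200.0,
) -> TrialRecord:
    """Assign exactly one outcome label to a trial.

    Exclusions (fixation break before the go signal; anticipatory first
    saccade, RT < 100 ms) are checked first and never count in success-rate
    denominators. The 200 ms window-entry clock starts at the detected onset
    of the primary saccade.
    """
    if events.fix_off_ms is None:
        raise ValueError("trial is missing its go event (fixation offset)")
    go = events.fix_off_ms
    target = layout.target_position(events.target_direction_deg)
    rec = TrialRecord(events=events, saccades=saccades, outcome=Outcome.ERROR_TIMING)

    for sac in saccades:
        if events.fix_on_ms <= sac.onset_ms < go and np.hypot(*sac.end) > fixation_radius_deg:
            rec.outcome = Outcome.FIXATION_BREAK_EXCLUDED
            return rec

    post = [s for s in saccades if s.onset_ms >= go]
    if not post:
        return rec  # never left fixation: timing error
    first = post[0]
    rt = first.onset_ms - go
    rec.reaction_time_ms = rt
    end = np.asarray(first.end)
    ecc = float(np.hypot(*end))
    if ecc > 0:
        rec.direction_error_deg = _wrap_deg(
            math.degrees(math.atan2(end[1], end[0])) - events.target_direction_deg
        )
        rec.eccentricity_error_deg = ecc - events.target_eccentricity_deg

    if rt < rt_min_ms:
        rec.outcome = Outcome.ANTICIPATORY_EXCLUDED
        return rec
    if rt >= rt_max_ms:
        rec.outcome = Outcome.ERROR_TIMING
        return rec

    in_window = float(np.hypot(*(end - target))) <= layout.window_radius_deg
    if in_window:
        if first.offset_ms - first.onset_ms <= entry_limit_ms:
            rec.outcome = Outcome.SUCCESS
        else:
            rec.outcome = Outcome.ERROR_TIMING
        return rec
    # primary saccade missed: corrective step reaching the window => multistep
    for sac in post[1:]:
        if float(np.hypot(*(np.asarray(sac.end) - target))) <= layout.window_radius_deg:
            rec.outcome = Outcome.ERROR_MULTISTEP
            return rec
    rec.outcome = Outcome.ERROR_OFFTARGET
    return rec


def success_rate(records: list[TrialRecord]) -> tuple[float, int, int]:
    """(rate, n_success, n_counted); excluded trials leave the denominator."""
    counted = [r for r in records if r.outcome not in EXCLUDED]
    if not counted:
        raise ValueError("no non-excluded trials")
    n_succ = sum(r.outcome is Outcome.SUCCESS for r in counted)
    return n_succ / len(counted), n_succ, len(counted)


def select_representative_target(
    rate_before: dict[float, float],
    rate_after: dict[float, float],
    hemifield_directions: list[float],
) -> float:
    """Target with the largest inactivation-induced drop in success rate.

    Returns the direction (deg) minimizing rate_after - rate_before over the
    hemifield; ties break toward the lowest direction angle.
    """
    if not hemifield_directions:
        raise ValueError("hemifield has no targets")
    best = None
    best_delta = np.inf
    for d in sorted(hemifield_directions):
        delta = rate_after[d] - rate_before[d]
        if delta < best_delta:
            best, best_delta = d, delta
    return best


def session_comparison(
    counts_before: dict[float, tuple[int, int]],
    counts_after: dict[float, tuple[int, int]],
    hemifield_directions: list[float],
    alpha: float = 0.05,
) -> dict:
    """Inactivation analysis for one hemifield.

    counts_* map target direction -> (n_success, n_counted). Selects the
    representative target (largest success-rate drop), runs the one-tailed
    Fisher exact test for a decrease in success, and reports significance at
    ``alpha``.
    """
    rb = {d: counts_before[d][0] / counts_before[d][1] for d in hemifield_directions}
    ra = {d: counts_after[d][0] / counts_after[d][1] for d in hemifield_directions}
    rep = select_representative_target(rb, ra, hemifield_directions)
    sb, nb = counts_before[rep]
    sa, na = counts_after[rep]
    p = fisher_exact_one_tailed(sb, nb - sb, sa, na - sa)
    return {
        "representative_target_deg": rep,
        "success_before": (sb, nb),
        "success_after": (sa, na),
        "fisher_one_tailed_p": p,
        "significant": p < alpha,
    }


def fisher_exact_one_tailed(
    succ_before: int, fail_before: int, succ_after: int, fail_after: int
) -> float:
    """One-tailed Fisher exact p for a DECREASE in success after injection.

    Exact hypergeometric tail: conditioning on the margins, p is the
    probability that the before-row success count is at least as large as
    observed (equivalently, the after row at least as unsuccessful).
    """
    counts = (succ_before, fail_before, succ_after, fail_after)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n_before = succ_before + fail_before
    n_total = sum(counts)
    k_succ = succ_before + succ_after
    if n_total == 0:
        raise ValueError("empty table")
    return float(stats.hypergeom.sf(succ_before - 1, n_total, k_succ, n_before))


def compare_reaction_times(rt_before: np.ndarray, rt_after: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    rt_before = np.asarray(rt_before, dtype=float)
    rt_after = np.asarray(rt_after, dtype=float)
    if len(rt_before) == 0 or len(rt_after) == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(rt_before), np.sort(rt_after)) and len(rt_before) == len(rt_after):
        # degenerate identical samples: the test is exactly symmetric
        res = stats.mannwhitneyu(rt_before, rt_after, alternative="two-sided", method="asymptotic")
        return float(min(res.pvalue, 1.0))
    res = stats.mannwhitneyu(rt_before, rt_after, alternative="two-sided")
    return float(res.pvalue)


def iqr_bootstrap_ci(
    sample: np.ndarray, n_boot: int = 2000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Interquartile range with a percentile-bootstrap confidence interval."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 4:
        raise ValueError("need at least 4 observations")
    q75, q25 = np.percentile(sample, [75, 25])
    iqr = float(q75 - q25)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, len(sample), size=(n_boot, len(sample)))
    boots = np.percentile(sample[idx], 75, axis=1) - np.percentile(sample[idx], 25, axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return iqr, (float(lo), float(hi))


def rank_two_way_anova(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> dict:
    """Two-way fixed-effects ANOVA on rank-transformed data, plus post hoc
    pairwise Mann-Whitney tests with Bonferroni correction.

    Returns {'anova': DataFrame with F and p per effect,
             'posthoc': {(cell_i, cell_j): adjusted p}}.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    df = pd.DataFrame({"r": stats.rankdata(values), "A": factor_a, "B": factor_b})
    sizes = df.groupby(["A", "B"]).size()
    if len(sizes) < len(np.unique(factor_a)) * len(np.unique(factor_b)) or (sizes < 2).any():
        raise ValueError("every cell of the design needs at least 2 observations")
    if np.ptp(df["r"].to_numpy()) == 0:
        # fully tied data: every effect sum-of-squares is exactly zero
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=["C(A)", "C(B)", "C(A):C(B)", "Residual"],
        )
    else:
        model = ols("r ~ C(A) * C(B)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)

    cells = sorted(df.groupby(["A", "B"]).groups)
    pairs = [(cells[i], cells[j]) for i in range(len(cells)) for j in range(i + 1, len(cells))]
    posthoc = {}
    for ci_, cj in pairs:
        vi = values[(factor_a == ci_[0]) & (factor_b == ci_[1])]
        vj = values[(factor_a == cj[0]) & (factor_b == cj[1])]
        p = stats.mannwhitneyu(vi, vj, alternative="two-sided").pvalue
        posthoc[(ci_, cj)] = float(min(p * len(pairs), 1.0))
    return {"anova": anova, "posthoc": posthoc}
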