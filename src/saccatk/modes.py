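"""Saccade-endpoint multimodality: Silverman's critical-bandwidth test with
the iterative mode-count search, single-point-mode outlier retest, and
on-/off-target labeling.

The test statistic is the critical bandwidth h_crit(k): the smallest Gaussian
kernel bandwidth at which the KDE of the sample has at most k modes (mode
count is non-increasing in bandwidth for the Gaussian kernel, so h_crit is
well defined and found by bisection). Significance comes from the smoothed
bootstrap: resamples are drawn from the KDE at h_crit(k), rescaled to the
sample variance, and the p value is the fraction of resamples whose KDE at
h_crit(k) still shows more than k modes. The mode search starts at k = 1 and
stops at the first k whose test is NOT rejected (p >= alpha). If the
resulting density has a mode supported by a single observation, that point is
removed as an outlier and the whole procedure reruns on the reduced sample.

Direction errors are treated as linear data after wrapping into
(-180, 180] relative to the target direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EndpointErrors",
    "ModeTestResult",
    "decompose_errors",
    "count_kde_modes",
    "critical_bandwidth",
    "silverman_p",
    "estimate_mode_structure",
    "label_on_off_target",
]

_GRID_SIZE = 2048


# ---------------------------------------------------------------------------
# endpoint decomposition


@dataclass
class EndpointErrors:
    """Per-saccade endpoint errors in target-relative polar coordinates."""

    direction_error_deg: np.ndarray
    eccentricity_error_deg: np.ndarray
    undefined: np.ndarray  # endpoint at fixation: direction error undefined


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    w = np.mod(a + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def decompose_errors(
    endpoints: np.ndarray, target_direction_deg: float, target_eccentricity_deg: float
) -> EndpointErrors:
    """Split endpoint positions (n, 2) in degrees into direction and
    eccentricity errors relative to the target."""
    endpoints = np.atleast_2d(np.asarray(endpoints, dtype=float))
    if target_eccentricity_deg <= 0:
        raise ValueError("target eccentricity must be positive")
    ecc = np.hypot(endpoints[:, 0], endpoints[:, 1])
    undefined = ecc == 0.0
    direction = np.degrees(np.arctan2(endpoints[:, 1], endpoints[:, 0]))
    dir_err = _wrap_deg(direction - target_direction_deg)
    dir_err = np.where(undefined, np.nan, dir_err)
    return EndpointErrors(dir_err, ecc - target_eccentricity_deg, undefined)


# ---------------------------------------------------------------------------
# KDE mode counting and critical bandwidth


def _kde_on_grid(sample: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    # unnormalized Gaussian KDE; normalization is irrelevant for mode counting
    z = (grid[:, None] - sample[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1)


def count_kde_modes(sample: np.ndarray, h: float, grid_size: int = _GRID_SIZE) -> int:
    """Number of local maxima of the Gaussian KDE at bandwidth h.

    Evaluated on a grid spanning the data range +- 3h; plateau runs count as
    one mode.
    """
    sample = np.asarray(sample, dtype=float)
    lo, hi = sample.min() - 3 * h, sample.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    d = _kde_on_grid(sample, h, grid)
    s = np.sign(np.diff(d))
    s = s[s != 0]  # collapse plateaus
    if len(s) == 0:
        return 1
    rises_to_falls = np.sum((s[:-1] > 0) & (s[1:] < 0))
    # a density falling from the left edge or rising into the right edge
    # contributes boundary modes only if it starts falling / ends rising
    n_modes = int(rises_to_falls)
    if s[0] < 0:
        n_modes += 1  # mode at/before the left grid edge
    if s[-1] > 0:
        n_modes += 1  # mode at/after the right grid edge
    return max(n_modes, 1)


def critical_bandwidth(sample: np.ndarray, k: int, rel_tol: float = 1e-4) -> float:
    """Smallest bandwidth at which the KDE has at most k modes (bisection)."""
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    spread = sample.std()
    if spread == 0:
        raise ValueError("degenerate sample: all points identical")

    hi = spread
    while count_kde_modes(sample, hi) > k:
        hi *= 2.0
    lo = spread / 64.0
    while count_kde_modes(sample, lo) <= k:
        lo /= 2.0
        if lo < 1e-12 * spread:
            return lo  # duplicated points: <= k modes at any bandwidth
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if count_kde_modes(sample, mid) <= k:
            hi = mid
        else:
            lo = mid
    return hi


def silverman_p(
    sample: np.ndarray,
    k: int,
    n_boot: int = 500,
    seed: int | tuple[int, ...] = 0,
    h_crit: float | None = None,
) -> float:
    """Smoothed-bootstrap p value of H0: the density has at most k modes."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    if h_crit is None:
        h_crit = critical_bandwidth(sample, k)
    var = sample.var()
    shrink = 1.0 / np.sqrt(1.0 + h_crit**2 / var) if var > 0 else 1.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = 0
    for _ in range(n_boot):
        pick = sample[rng.integers(0, n, size=n)]
        y = pick + h_crit * rng.standard_normal(n)
        # variance-rescaled smoothed bootstrap (classical convention)
        y = y.mean() + shrink * (y - y.mean())
        if count_kde_modes(y, h_crit) > k:
            exceed += 1
    return exceed / n_boot


# ---------------------------------------------------------------------------
# iterative mode-structure estimation


@dataclass
class ModeTestResult:
    """Outcome of the iterative multimodality procedure on one error axis."""

    k_star: int
    h_crit: dict[int, float]
    p_values: dict[int, float]
    mode_locations: np.ndarray
    antimode_boundaries: np.ndarray
    assignments: np.ndarray  # mode index per input point; -1 for removed outliers
    outlier_indices: np.ndarray
    degenerate: bool = False
    on_target: np.ndarray | None = None


def _modes_and_antimodes(sample: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = sample.min() - 3 * h, sample.max() + 3 * h
    grid = np.linspace(lo, hi, _GRID_SIZE)
    d = _kde_on_grid(sample, h, grid)
    modes, antis = [], []
    s = np.sign(np.diff(d))
    nz = np.nonzero(s)[0]
    comp = s[nz]
    # positions where the compressed sign flips; plateau midpoint as location
    for i in range(len(comp) - 1):
        if comp[i] > 0 and comp[i + 1] < 0:
            modes.append(grid[(nz[i] + 1 + nz[i + 1]) // 2])
        elif comp[i] < 0 and comp[i + 1] > 0:
            antis.append(grid[(nz[i] + 1 + nz[i + 1]) // 2])
    if len(comp) and comp[0] < 0:
        modes.insert(0, grid[0])
    if len(comp) and comp[-1] > 0:
        modes.append(grid[-1])
    if not modes:
        modes = [grid[int(np.argmax(d))]]
    return np.asarray(modes, dtype=float), np.asarray(antis, dtype=float)


def estimate_mode_structure(
    sample: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
    max_k: int = 10,
) -> ModeTestResult:
    """Iterative Silverman procedure with single-point-mode outlier retest.

    Returns the selected mode count k* (first k with p >= alpha), the KDE
    mode/antimode structure at h_crit(k*), per-point mode assignments, and
    the indices (into the original sample) of removed outliers.
    """
    sample = np.asarray(sample, dtype=float)
    n0 = len(sample)
    if n0 < 3:
        raise ValueError("need at least 3 points")
    active = np.arange(n0)
    outliers: list[int] = []
    ss = np.random.SeedSequence(seed)
    round_idx = 0

    while True:
        x = sample[active]
        if len(x) < 3:
            result = ModeTestResult(
                k_star=1,
                h_crit={},
                p_values={},
                mode_locations=np.array([np.median(x)]) if len(x) else np.array([]),
                antimode_boundaries=np.array([]),
                assignments=np.full(n0, -1, dtype=int),
                outlier_indices=np.array(outliers, dtype=int),
                degenerate=True,
            )
            result.assignments[active] = 0
            return result

        h_path: dict[int, float] = {}
        p_path: dict[int, float] = {}
        k_star = max_k
        for k in range(1, max_k + 1):
            h = critical_bandwidth(x, k)
            p = silverman_p(x, k, n_boot=n_boot, seed=(seed, round_idx, k), h_crit=h)
            h_path[k], p_path[k] = h, p
            if p >= alpha:
                k_star = k
                break

        h_star = h_path[k_star]
        modes, antis = _modes_and_antimodes(x, h_star)
        bounds = np.concatenate(([-np.inf], antis, [np.inf]))
        assign_local = np.searchsorted(antis, x)  # mode index per active point

        counts = np.bincount(assign_local, minlength=len(modes))
        singleton_modes = np.nonzero(counts == 1)[0]
        if len(singleton_modes) > 0 and len(x) > 3:
            # remove the single-point mode farthest from the sample median
            med = np.median(x)
            worst = max(singleton_modes, key=lambda m: abs(modes[m] - med) if m < len(modes) else 0)
            local_idx = int(np.nonzero(assign_local == worst)[0][0])
            outliers.append(int(active[local_idx]))
            active = np.delete(active, local_idx)
            round_idx += 1
            continue

        assignments = np.full(n0, -1, dtype=int)
        assignments[active] = assign_local
        return ModeTestResult(
            k_star=k_star,
            h_crit=h_path,
            p_values=p_path,
            mode_locations=modes,
            antimode_boundaries=antis,
            assignments=assignments,
            outlier_indices=np.array(sorted(outliers), dtype=int),
        )


def label_on_off_target(result: ModeTestResult) -> np.ndarray:
    """Boolean on-target label per original point.

    In error coordinates the target sits at 0: members of the mode nearest 0
    are on-target; with a unimodal result every retained point is on-target.
    Removed outliers and members of other modes are off-target. Ties between
    equidistant modes break toward the larger-mass mode.
    """
    n = len(result.assignments)
    on = np.zeros(n, dtype=bool)
    retained = result.assignments >= 0
    if result.k_star == 1 or len(result.mode_locations) == 1:
        on[retained] = True
    else:
        dist = np.abs(result.mode_locations)
        mass = np.bincount(
            result.assignments[retained], minlength=len(result.mode_locations)
        )
        # lexicographic: distance to 0, then larger mass wins
        order = sorted(range(len(dist)), key=lambda m: (dist[m], -mass[m]))
        best = order[0]
        on[retained & (result.assignments == best)] = True
    result.on_target = on
    return on
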