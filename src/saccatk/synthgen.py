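"""Ground-truthed synthetic data: eye traces, spike trains, endpoint mixtures,
and paired before/after inactivation sessions.

Every generator is driven by a single integer seed that fans out to
independent per-trial substreams (``numpy.random.SeedSequence``), so output is
bit-reproducible and adding trials never reshuffles earlier ones.

Saccades follow a minimum-jerk position profile: with normalized time
tau = (t - t0)/D the displacement is A*(10 tau^3 - 15 tau^4 + 6 tau^5), whose
speed is (A/D)*30*tau^2*(1-tau)^2 with closed-form peak 1.875*A/D at
tau = 1/2. Durations come from a linear main sequence D = d0 + d1*A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .eyekin import EyeTrace, SaccadeEvent

__all__ = [
    "PlannedTrial",
    "TracePlan",
    "NeuronPlan",
    "MixtureSpec",
    "gen_eye_trace",
    "gen_spike_trains",
    "gen_endpoints",
    "gen_inactivation_session",
    "minimum_jerk_peak_velocity",
    "speed_threshold_crossing",
]


# ---------------------------------------------------------------------------
# minimum-jerk profile helpers


def _min_jerk_pos(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_peak_velocity(amplitude_deg: float, duration_ms: float) -> float:
    """Closed-form peak speed (deg/s) of a minimum-jerk saccade."""
    return 1.875 * amplitude_deg / (duration_ms / 1000.0)


def speed_threshold_crossing(
    amplitude_deg: float, duration_ms: float, threshold_deg_s: float, rising: bool = True
) -> float:
    """Time (ms after motion onset) when the true min-jerk speed crosses a threshold.

    rising=True gives the first (accelerating) crossing, rising=False the last.
    """
    vmax = minimum_jerk_peak_velocity(amplitude_deg, duration_ms)
    if threshold_deg_s >= vmax:
        raise ValueError("threshold above the profile's peak speed")

    def f(tau: float) -> float:
        return (amplitude_deg / (duration_ms / 1000.0)) * 30 * tau**2 * (1 - tau) ** 2 - threshold_deg_s

    tau = brentq(f, 1e-12, 0.5) if rising else brentq(f, 0.5, 1 - 1e-12)
    return tau * duration_ms


# ---------------------------------------------------------------------------
# eye traces


@dataclass
class PlannedTrial:
    """One planned trial of a visually guided saccade task."""

    fixation_ms: float  # fixation duration before the go signal
    target_direction_deg: float
    target_eccentricity_deg: float
    post_ms: float = 400.0  # hold on target before the return saccade


@dataclass
class TracePlan:
    """Plan for a synthetic eye-position recording.

    Main-sequence defaults (duration 21 ms + 2.2 ms/deg) are literature-typical
    for macaque saccades; peak velocity is implied by the minimum-jerk profile.
    """

    sampling_rate: float = 1000.0
    trials: list[PlannedTrial] = field(default_factory=list)
    duration_intercept_ms: float = 21.0
    duration_slope_ms_per_deg: float = 2.2
    latency_mean_ms: float = 180.0
    latency_sd_ms: float = 30.0
    endpoint_noise_sd_deg: float = 0.0
    position_noise_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate not in (250, 1000):
            raise ValueError(f"sampling_rate must be 250 or 1000 Hz, got {self.sampling_rate}")
        for tr in self.trials:
            if self.saccade_duration_ms(tr.target_eccentricity_deg) <= 0:
                raise ValueError("planned saccade duration must be positive")

    def saccade_duration_ms(self, amplitude_deg: float) -> float:
        return self.duration_intercept_ms + self.duration_slope_ms_per_deg * amplitude_deg


def gen_eye_trace(plan: TracePlan) -> tuple[EyeTrace, list[SaccadeEvent]]:
    """Generate one continuous eye trace realizing the plan.

    Each trial contributes fixation at the center, an outbound saccade to the
    (noise-perturbed) target after a Gaussian latency, a hold period, and a
    return saccade to the center. Both saccades enter the ground-truth list
    (onset/offset are motion start/end; ``reaction_time_ms`` is set on the
    outbound saccade relative to the trial's go signal).
    """
    dt = 1000.0 / plan.sampling_rate
    ss = np.random.SeedSequence(plan.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(max(len(plan.trials), 1))]

    segments_t: list[np.ndarray] = []
    segments_x: list[np.ndarray] = []
    segments_y: list[np.ndarray] = []
    truth: list[SaccadeEvent] = []
    t0 = 0.0

    def emit_hold(t_start: float, t_end: float, pos: tuple[float, float]) -> float:
        n = int(round((t_end - t_start) / dt))
        if n > 0:
            tt = t_start + dt * np.arange(n)
            segments_t.append(tt)
            segments_x.append(np.full(n, pos[0]))
            segments_y.append(np.full(n, pos[1]))
        return t_start + n * dt

    def emit_saccade(t_start: float, p0: np.ndarray, p1: np.ndarray, dur: float) -> float:
        n = int(round(dur / dt))
        tt = t_start + dt * np.arange(n)
        tau = (tt - t_start) / dur
        prof = _min_jerk_pos(tau)
        segments_t.append(tt)
        segments_x.append(p0[0] + (p1[0] - p0[0]) * prof)
        segments_y.append(p0[1] + (p1[1] - p0[1]) * prof)
        return t_start + n * dt

    for i, tr in enumerate(plan.trials):
        rng = streams[i]
        go = t0 + tr.fixation_ms
        latency = max(rng.normal(plan.latency_mean_ms, plan.latency_sd_ms), 60.0)
        # snap the saccade onset to the sample grid so the profile is sampled
        # exactly from its start
        sac_on = t0 + round((tr.fixation_ms + latency) / dt) * dt
        target = tr.target_eccentricity_deg * np.array(
            [np.cos(np.radians(tr.target_direction_deg)), np.sin(np.radians(tr.target_direction_deg))]
        )
        endpoint = target + rng.normal(0.0, plan.endpoint_noise_sd_deg, size=2)
        amp_out = float(np.hypot(*endpoint))
        dur_out = plan.saccade_duration_ms(amp_out)

        t = emit_hold(t0, sac_on, (0.0, 0.0))
        truth.append(
            SaccadeEvent(
                onset_ms=t,
                offset_ms=t + dur_out,
                start=(0.0, 0.0),
                end=(float(endpoint[0]), float(endpoint[1])),
                reaction_time_ms=t - go,
            )
        )
        t = emit_saccade(t, np.zeros(2), endpoint, dur_out)
        t = emit_hold(t, t + tr.post_ms, (float(endpoint[0]), float(endpoint[1])))
        dur_back = plan.saccade_duration_ms(amp_out)
        truth.append(
            SaccadeEvent(
                onset_ms=t,
                offset_ms=t + dur_back,
                start=(float(endpoint[0]), float(endpoint[1])),
                end=(0.0, 0.0),
            )
        )
        t = emit_saccade(t, endpoint, np.zeros(2), dur_back)
        t0 = emit_hold(t, t + 300.0, (0.0, 0.0))

    if not segments_t:
        raise ValueError("plan has no trials")
    time = np.concatenate(segments_t)
    x = np.concatenate(segments_x)
    y = np.concatenate(segments_y)
    if plan.position_noise_sd_deg > 0:
        # dedicated substream: noise never perturbs the per-trial streams
        noise_rng = np.random.default_rng(np.random.SeedSequence((plan.seed, 0xE0E)))
        x = x + noise_rng.normal(0.0, plan.position_noise_sd_deg, size=len(x))
        y = y + noise_rng.normal(0.0, plan.position_noise_sd_deg, size=len(y))
    return EyeTrace(time=time, x=x, y=y, sampling_rate=plan.sampling_rate), truth


# ---------------------------------------------------------------------------
# spike trains


@dataclass
class NeuronPlan:
    """Rate model for one synthetic neuron in an overlap-task session.

    Trial clock: target onset at 0 ms; fixation offset at ``delay_ms``;
    saccade onset a Gaussian reaction time later. The instantaneous rate is
    baseline + phasic alpha bump (decay ``phasic_decay_ms``, scaled so its
    mean over the 50 ms after ``visual_latency_ms`` equals
    ``phasic_magnitude``) + sustained delay rate (from the bump onset until
    fixation offset) + a perisaccadic boost within +-50 ms of saccade onset.
    Response components on out-of-RF trials are multiplied by
    ``out_rf_factor``.
    """

    baseline_rate: float = 16.9
    visual_latency_ms: float = 141.0
    phasic_magnitude: float = 22.1
    phasic_decay_ms: float = 12.0
    sustained_rate: float = 15.0
    perisaccadic_rate: float = 10.0
    out_rf_factor: float = 0.0
    n_trials: int = 30
    delay_ms: float = 400.0
    rt_mean_ms: float = 180.0
    rt_sd_ms: float = 25.0
    trial_start_ms: float = -500.0
    trial_stop_pad_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.baseline_rate, self.phasic_magnitude, self.sustained_rate, self.perisaccadic_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.visual_latency_ms <= 0:
            raise ValueError("visual latency must be positive")
        if self.out_rf_factor < 0:
            raise ValueError("out_rf_factor must be non-negative")


@dataclass
class SpikeTrial:
    """Spike times of one trial, on the trial clock (target onset = 0 ms)."""

    spikes_ms: np.ndarray
    target_on_ms: float
    fix_off_ms: float
    saccade_on_ms: float
    in_rf: bool
    target_direction_deg: float = 0.0
    target_eccentricity_deg: float = 10.0


@dataclass
class SpikeDataset:
    trials: list[SpikeTrial]
    true_latency_ms: float | None = None

    def subset(self, in_rf: bool) -> "SpikeDataset":
        return SpikeDataset([t for t in self.trials if t.in_rf == in_rf], self.true_latency_ms)

    def __len__(self) -> int:
        return len(self.trials)


def _alpha_scale(decay_ms: float, window_ms: float = 50.0) -> float:
    """Mean of (s/tau)exp(-s/tau) over [0, window]; the bump is magnitude/this."""
    u = window_ms / decay_ms
    integral = decay_ms * (1.0 - np.exp(-u) * (1.0 + u))
    return integral / window_ms


def _rate_fn(plan: NeuronPlan, fix_off: float, sac_on: float, factor: float):
    c = plan.phasic_magnitude * factor / _alpha_scale(plan.phasic_decay_ms)
    lat, tau = plan.visual_latency_ms, plan.phasic_decay_ms
    sus = plan.sustained_rate * factor
    peri = plan.perisaccadic_rate * factor

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full_like(t, plan.baseline_rate, dtype=float)
        s = t - lat
        m = s > 0
        r[m] += c * (s[m] / tau) * np.exp(-s[m] / tau)
        r[(t > lat) & (t <= fix_off)] += sus
        r[np.abs(t - sac_on) <= 50.0] += peri
        return r

    return rate


def gen_spike_trains(plan: NeuronPlan) -> SpikeDataset:
    """Inhomogeneous-Poisson spike trains by thinning, in- and out-of-RF trials."""
    ss = np.random.SeedSequence(plan.seed)
    trials: list[SpikeTrial] = []
    if plan.n_trials == 0:
        return SpikeDataset([], plan.visual_latency_ms)
    streams = ss.spawn(2 * plan.n_trials)
    for i in range(2 * plan.n_trials):
        in_rf = i < plan.n_trials
        rng = np.random.default_rng(streams[i])
        rt = max(rng.normal(plan.rt_mean_ms, plan.rt_sd_ms), 80.0)
        fix_off = plan.delay_ms
        sac_on = fix_off + rt
        t_stop = sac_on + plan.trial_stop_pad_ms
        factor = 1.0 if in_rf else plan.out_rf_factor
        rate = _rate_fn(plan, fix_off, sac_on, factor)
        c = plan.phasic_magnitude * factor / _alpha_scale(plan.phasic_decay_ms)
        rmax = plan.baseline_rate + c * np.exp(-1.0) + plan.sustained_rate * factor + plan.perisaccadic_rate * factor
        rmax = max(rmax, 1e-9)
        span_s = (t_stop - plan.trial_start_ms) / 1000.0
        n_cand = rng.poisson(rmax * span_s)
        cand = np.sort(rng.uniform(plan.trial_start_ms, t_stop, size=n_cand))
        keep = rng.uniform(0.0, 1.0, size=n_cand) < rate(cand) / rmax
        trials.append(
            SpikeTrial(
                spikes_ms=cand[keep],
                target_on_ms=0.0,
                fix_off_ms=fix_off,
                saccade_on_ms=sac_on,
                in_rf=in_rf,
            )
        )
    return SpikeDataset(trials, plan.visual_latency_ms)


# ---------------------------------------------------------------------------
# endpoint mixtures


@dataclass
class MixtureSpec:
    """Gaussian mixture in (direction error, eccentricity error) coordinates."""

    weights: np.ndarray
    means: np.ndarray  # (k, 2)
    sds: np.ndarray  # (k,) isotropic or (k, 2)
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1 (within 1e-12)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def gen_endpoints(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw n labeled samples; returns (samples (n,2), component labels (n,))."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    k = len(spec.weights)
    labels = rng.choice(k, size=spec.n, p=spec.weights)
    sds = np.broadcast_to(spec.sds.reshape(k, -1), (k, 2))
    samples = spec.means[labels] + rng.standard_normal((spec.n, 2)) * sds[labels]
    return samples, labels


# ---------------------------------------------------------------------------
# inactivation sessions


def gen_inactivation_session(
    p_before: dict[float, float],
    p_after: dict[float, float],
    n_per_target: int,
    seed: int = 0,
) -> tuple[dict[float, np.ndarray], dict[float, np.ndarray]]:
    """Bernoulli success outcomes per target direction, before and after injection.

    Keys of the two dicts are target directions in degrees and must match.
    Returns ({direction: bool array of n outcomes}, ...) for before and after.
    """
    if set(p_before) != set(p_after):
        raise ValueError("before/after target lists must match")
    if n_per_target < 1:
        raise ValueError("n_per_target must be >= 1")
    for p in list(p_before.values()) + list(p_after.values()):
        if not 0.0 <= p <= 1.0:
            raise ValueError("success probabilities must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    dirs = sorted(p_before)
    streams = ss.spawn(2 * len(dirs))
    before = {}
    after = {}
    for i, d in enumerate(dirs):
        before[d] = np.random.default_rng(streams[2 * i]).random(n_per_target) < p_before[d]
        after[d] = np.random.default_rng(streams[2 * i + 1]).random(n_per_target) < p_after[d]
    return before, after
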