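"""Forward simulation of somato-dendritic calcium-imaging sessions.

The generator emulates the signal structure the analysis assumes: sparse
somatic transients (Poisson, with a burst-frequency label and log-normal
amplitude), somatofugal propagation with amplitude-dependent per-segment
survival gated fully-on above a critical burst frequency (~50 Hz), rare
tuft-initiated global events visible in every compartment, a unit-peak
difference-of-exponentials indicator kernel, i.i.d. Gaussian dF/F0 noise,
treadmill speed with prescribed locomotion bouts, and an 8-direction
drifting-grating schedule with a cosine-shaped orientation tuning profile.
The hidden ground truth (event times, propagation flags, kernel parameters,
seed) is returned alongside the traces for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .core import DEFAULT_CHAIN, Event, EventSeries, SpeedTrace, StimSchedule, Trace


# ---------------------------------------------------------------------------
# Indicator kernel


def kernel_peak_time(rise: float, decay: float) -> float:
    """Time of the maximum of the difference-of-exponentials kernel."""
    return rise * decay / (decay - rise) * math.log(decay / rise)


def kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials: (e^(-t/decay) - e^(-t/rise)) / K.

    Zero for t < 0.  Defaults elsewhere use rise 0.18 s / decay 1.0 s for a
    GCaMP6s-like indicator; 0.05 s / 0.3 s approximates GCaMP6f.
    """
    t = np.asarray(t, dtype=float)
    tp = kernel_peak_time(rise, decay)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    out = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    return out / peak


# ---------------------------------------------------------------------------
# Attenuation models


@dataclass
class LogisticAttenuation:
    """Per-segment somatofugal survival probability.

    Survival is logistic in normalized event amplitude (small events
    attenuate more) and jumps to 1 for burst frequencies at or above the
    critical frequency for dendritic electrogenesis.

    ``midpoints`` gives the half-survival amplitude per segment; a longer
    chain reuses the last midpoint.
    """

    midpoints: tuple[float, ...] = (0.10, 0.06, 0.18)
    steepness: float = 15.0
    critical_frequency: float = 50.0

    def __call__(self, norm_amplitude: float, burst_frequency: float,
                 segment: int) -> float:
        if burst_frequency >= self.critical_frequency:
            return 1.0
        mid = self.midpoints[min(segment, len(self.midpoints) - 1)]
        return 1.0 / (1.0 + math.exp(-self.steepness * (norm_amplitude - mid)))


@dataclass
class FlatAttenuation:
    """Amplitude-independent survival (for rate-recovery tests)."""

    survival: float = 1.0

    def __call__(self, norm_amplitude: float, burst_frequency: float,
                 segment: int) -> float:
        return self.survival


@dataclass
class StepAttenuation:
    """All events below an amplitude threshold attenuate; none above."""

    threshold: float = 0.3

    def __call__(self, norm_amplitude: float, burst_frequency: float,
                 segment: int) -> float:
        return 0.0 if norm_amplitude < self.threshold else 1.0


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass
class SynthConfig:
    """Study conditions for the forward simulator.

    Rates are events/min; kernel constants are seconds; ``noise_sd`` is in
    dF/F0 units; ``baseline_f0`` is raw fluorescence (a.u.).  Somatic events
    closer than ``min_event_interval`` are thinned, matching the indicator's
    inability to resolve intra-burst spikes: one generated event is one
    merged ground-truth transient.
    """

    n_neurons: int = 1
    duration: float = 600.0
    fs: float = 5.0
    soma_event_rate: float = 6.0
    burst_frequency_distribution: dict[float, float] = field(
        default_factory=lambda: {10.0: 0.45, 25.0: 0.30, 50.0: 0.15, 100.0: 0.10}
    )
    attenuation_curve: object = field(default_factory=LogisticAttenuation)
    tuft_initiated_rate: float = 0.3
    kernel_rise: float = 0.18
    kernel_decay: float = 1.0
    noise_sd: float = 0.02
    baseline_f0: float = 100.0
    seed: int = 0
    chain: tuple[str, ...] = DEFAULT_CHAIN
    min_event_interval: float = 2.5
    amp_log_mu: float = math.log(0.5)
    amp_log_sigma: float = 0.5
    segment_gain: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"SynthConfig.{f.name} must be finite, got {v}")
        if self.duration <= 0:
            raise ValueError("SynthConfig.duration must be positive")
        if self.fs <= 0:
            raise ValueError("SynthConfig.fs must be positive")
        for name in ("soma_event_rate", "tuft_initiated_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"SynthConfig.{name} must be non-negative")
        if not self.kernel_rise < self.kernel_decay:
            raise ValueError("SynthConfig.kernel_rise must be below kernel_decay")
        probs = list(self.burst_frequency_distribution.values())
        if probs and not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError(
                "SynthConfig.burst_frequency_distribution probabilities must sum to 1"
            )


@dataclass
class GroundTruthEvent:
    time: float
    burst_frequency: float
    amplitude: float
    norm_amplitude: float
    origin: str                      # "soma" or "tuft"
    reached: dict[str, bool]         # propagation flag per compartment


@dataclass
class SynthGroundTruth:
    """The generator's hidden truth for one neuron."""

    neuron_id: int
    events: list[GroundTruthEvent]
    seed: int
    kernel_rise: float
    kernel_decay: float

    def times_in(self, compartment: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.reached[compartment]])

    def count_in(self, compartment: str) -> int:
        return sum(e.reached[compartment] for e in self.events)


# ---------------------------------------------------------------------------
# Generation


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration: float, min_interval: float = 0.0) -> np.ndarray:
    if rate_per_min <= 0:
        return np.array([])
    n = rng.poisson(rate_per_min / 60.0 * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    if min_interval <= 0:
        return times
    kept, last = [], -math.inf
    for t in times:
        if t - last >= min_interval:
            kept.append(t)
            last = t
    return np.asarray(kept)


def _render(times: np.ndarray, amps: np.ndarray, config: SynthConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Baseline + amplitude-scaled kernel train + i.i.d. Gaussian noise."""
    n = int(round(config.duration * config.fs))
    dff = np.zeros(n)
    support = int(math.ceil(8.0 * config.kernel_decay * config.fs))
    for t, a in zip(times, amps):
        i0 = int(math.ceil(t * config.fs))
        i1 = min(n, i0 + support)
        if i0 >= n:
            continue
        tt = np.arange(i0, i1) / config.fs - t
        dff[i0:i1] += a * kernel(tt, config.kernel_rise, config.kernel_decay)
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    return config.baseline_f0 * (1.0 + dff + noise)


def generate_neuron(config: SynthConfig,
                    neuron_id: int = 0) -> tuple[dict[str, Trace], SynthGroundTruth]:
    """Simulate one neuron's raw fluorescence in every chain compartment.

    Somatic events propagate somatofugally: an event appears in compartment
    k+1 iff it reached compartment k and a Bernoulli draw with probability
    ``attenuation_curve(norm_amplitude, burst_frequency, segment=k)``
    succeeds.  Distal amplitudes are the somatic amplitude times
    ``segment_gain`` per segment crossed.  Tuft-initiated events are global
    (present in every compartment).  Identical (config, neuron_id) gives
    bit-identical output.
    """
    rng = np.random.default_rng([config.seed, neuron_id])
    chain = config.chain
    curve = config.attenuation_curve

    soma_times = _poisson_times(rng, config.soma_event_rate, config.duration,
                                config.min_event_interval)
    n_ev = soma_times.size
    freqs = np.array(sorted(config.burst_frequency_distribution))
    if n_ev and freqs.size:
        probs = np.array([config.burst_frequency_distribution[f] for f in freqs])
        burst = rng.choice(freqs, size=n_ev, p=probs)
    else:
        burst = np.zeros(n_ev)
    amps = rng.lognormal(config.amp_log_mu, config.amp_log_sigma, n_ev)
    norm = amps / amps.max() if n_ev else amps

    events: list[GroundTruthEvent] = []
    for k in range(n_ev):
        reached = {chain[0]: True}
        alive = True
        for seg in range(len(chain) - 1):
            if alive:
                alive = rng.random() < curve(float(norm[k]), float(burst[k]), seg)
            reached[chain[seg + 1]] = alive
        events.append(GroundTruthEvent(
            time=float(soma_times[k]), burst_frequency=float(burst[k]),
            amplitude=float(amps[k]), norm_amplitude=float(norm[k]),
            origin="soma", reached=reached))

    tuft_times = _poisson_times(rng, config.tuft_initiated_rate, config.duration,
                                config.min_event_interval)
    tuft_amps = rng.lognormal(config.amp_log_mu, config.amp_log_sigma, tuft_times.size)
    for t, a in zip(tuft_times, tuft_amps):
        events.append(GroundTruthEvent(
            time=float(t), burst_frequency=math.inf, amplitude=float(a),
            norm_amplitude=float("nan"), origin="tuft",
            reached={c: True for c in chain}))
    events.sort(key=lambda e: e.time)

    traces: dict[str, Trace] = {}
    for depth, comp in enumerate(chain):
        times = np.array([e.time for e in events if e.reached[comp]])
        gain = config.segment_gain ** depth
        amps_c = np.array([e.amplitude * (gain if e.origin == "soma" else 1.0)
                           for e in events if e.reached[comp]])
        values = _render(times, amps_c, config, rng)
        traces[comp] = Trace(values=values, fs=config.fs,
                             trace_id=f"n{neuron_id}_{comp}",
                             neuron_id=str(neuron_id), compartment=comp,
                             kind="raw")
    truth = SynthGroundTruth(neuron_id=neuron_id, events=events,
                             seed=config.seed, kernel_rise=config.kernel_rise,
                             kernel_decay=config.kernel_decay)
    return traces, truth


def generate_session(config: SynthConfig) -> list[tuple[dict[str, Trace], SynthGroundTruth]]:
    """Simulate ``config.n_neurons`` neurons."""
    return [generate_neuron(config, i) for i in range(config.n_neurons)]


def truth_event_series(truth: SynthGroundTruth, compartment: str) -> EventSeries:
    """Ground-truth transients of one compartment as an EventSeries.

    Amplitudes are the true (pre-noise) event amplitudes; normalized
    amplitudes are relative to the compartment's own maximum, matching the
    per-compartment normalization used on detected events.
    """
    evs = [e for e in truth.events if e.reached[compartment]]
    if not evs:
        return EventSeries(events=[], trace_id=f"truth_{compartment}")
    max_amp = max(e.amplitude for e in evs)
    events = [Event(peak_time=e.time, peak_index=i, amplitude=e.amplitude,
                    norm_amplitude=e.amplitude / max_amp)
              for i, e in enumerate(evs)]
    return EventSeries(events=events, trace_id=f"truth_{compartment}")


# ---------------------------------------------------------------------------
# Speed and stimulus schedules


def generate_speed(duration: float, fs: float,
                   bout_spec: list[tuple[float, float, float]],
                   seed: int | None = None,
                   jitter_sd: float = 0.0) -> SpeedTrace:
    """Treadmill speed: prescribed bouts of (start_s, stop_s, speed_cm_s).

    Speed equals the bout speed (plus optional non-negative Gaussian jitter)
    inside each half-open bout interval and zero outside.  Bouts must lie in
    [0, duration] and not overlap.
    """
    prev_stop = -math.inf
    for start, stop, _ in sorted(bout_spec):
        if start < 0 or stop > duration or stop <= start:
            raise ValueError("bouts must lie within [0, duration]")
        if start < prev_stop:
            raise ValueError("bouts must not overlap")
        prev_stop = stop
    n = int(round(duration * fs))
    speed = np.zeros(n)
    rng = np.random.default_rng(seed)
    for start, stop, v in bout_spec:
        lo, hi = int(round(start * fs)), int(round(stop * fs))
        seg = np.full(hi - lo, float(v))
        if jitter_sd > 0:
            seg = np.maximum(seg + rng.normal(0.0, jitter_sd, seg.size), 0.0)
        speed[lo:hi] = seg
    return SpeedTrace(speed=speed, fs=fs)


def generate_stim_schedule(n_repeats: int = 12, stim_duration: float = 3.0,
                           gray_duration: float = 4.0, t_start: float = 5.0,
                           seed: int | None = None) -> StimSchedule:
    """Drifting gratings: 8 equally spaced directions, randomized order.

    Each of ``n_repeats`` blocks presents all 8 directions once in a fresh
    random order; 3 s stimulus, 4 s gray.
    """
    rng = np.random.default_rng(seed)
    directions = []
    for _ in range(n_repeats):
        directions.extend(rng.permutation(np.arange(8) * 45.0))
    n = len(directions)
    onsets = t_start + np.arange(n) * (stim_duration + gray_duration)
    return StimSchedule(onsets=onsets, directions=np.array(directions),
                        stim_duration=stim_duration, gray_duration=gray_duration)


def generate_tuned_responses(schedule: StimSchedule, preferred: float,
                             osi_target: float, gain: float = 1.0) -> np.ndarray:
    """Per-trial multiplicative response gains realizing a target OSI.

    The noiseless tuning curve is g(theta) = g_orth + (g_pref - g_orth) *
    cos^2(theta - preferred) in orientation space, with g_pref = ``gain`` and
    g_orth = gain * (1 - OSI) / (1 + OSI), so the trial-averaged curve has
    exactly the requested OSI and preferred orientation (mod 180 deg).
    """
    if not 0.0 <= osi_target <= 1.0:
        raise ValueError("osi_target must lie in [0, 1]")
    g_orth = gain * (1.0 - osi_target) / (1.0 + osi_target)
    delta = np.deg2rad(schedule.orientations - (preferred % 180.0))
    return g_orth + (gain - g_orth) * np.cos(delta) ** 2


def generate_tuned_trace(schedule: StimSchedule, preferred: float,
                         osi_target: float, config: SynthConfig,
                         seed: int | None = None,
                         response_latency: float = 0.3,
                         amp_jitter: float = 0.15) -> Trace:
    """Raw trace of an orientation-tuned neuron: one transient per trial.

    Trial amplitudes follow :func:`generate_tuned_responses` with
    multiplicative log-normal-like jitter of fractional SD ``amp_jitter``.
    """
    rng = np.random.default_rng(seed)
    gains = generate_tuned_responses(schedule, preferred, osi_target)
    amps = gains * np.maximum(1.0 + amp_jitter * rng.standard_normal(gains.size), 0.05)
    times = schedule.onsets + response_latency
    values = _render(times, amps, config, rng)
    return Trace(values=values, fs=config.fs, trace_id="tuned",
                 compartment="soma", kind="raw")


# ---------------------------------------------------------------------------
# Bare event-series pairs (adversarial matching inputs)


def _series_from_times(times: np.ndarray, trace_id: str = "") -> EventSeries:
    times = np.sort(np.asarray(times, dtype=float))
    if times.size:
        times = times[np.concatenate([[True], np.diff(times) > 1e-9])]
    events = [Event(peak_time=float(t), peak_index=i, amplitude=1.0,
                    norm_amplitude=1.0) for i, t in enumerate(times)]
    return EventSeries(events=events, trace_id=trace_id, noise_sd=1.0)


def generate_event_pair(duration: float = 600.0, rate_per_min: float = 3.0,
                        jitter: tuple[float, float] = (-3.0, 3.0),
                        extra_distal_per_min: float = 0.0,
                        seed: int | None = None) -> tuple[EventSeries, EventSeries]:
    """Poisson proximal series plus a jittered distal copy.

    Distal times are the proximal times shifted by i.i.d. uniform jitter on
    ``jitter`` (a wide range creates out-of-window candidates on purpose),
    plus optional unrelated Poisson distal events.
    """
    rng = np.random.default_rng(seed)
    prox = _poisson_times(rng, rate_per_min, duration)
    dist = prox + rng.uniform(jitter[0], jitter[1], prox.size)
    extra = _poisson_times(rng, extra_distal_per_min, duration)
    dist = np.concatenate([dist, extra])
    dist = dist[(dist >= 0) & (dist <= duration)]
    return _series_from_times(prox, "prox"), _series_from_times(dist, "dist")
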