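"""Calcium-transient detection on dF/F0 traces.

Noise is estimated as the standard deviation of the high-pass-filtered trace
(0.6 Hz, 9th order, zero-phase); peaks are strict local maxima of dF/F0 whose
height exceeds ``multiplier x noise_sd`` (default multiplier 2.8).  An event's
amplitude is the peak value minus the minimum of dF/F0 over a 2 s backward
window ending at (and including) the peak sample, which accounts for events
riding on the decay of earlier transients.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import Event, EventSeries, Trace, TraceKind

#: High-pass filter order for noise estimation.
NOISE_FILTER_ORDER = 9
#: High-pass cutoff, Hz.
NOISE_CUTOFF_HZ = 0.6
#: Detection threshold in units of noise SD.
DEFAULT_MULTIPLIER = 2.8
#: Backward window for the local pre-peak minimum, seconds.
AMPLITUDE_WINDOW_S = 2.0

_MIN_SAMPLES = 3 * (NOISE_FILTER_ORDER + 1)


def estimate_noise_sd(dff: Trace) -> float:
    """SD of the 0.6 Hz zero-phase high-pass-filtered dF/F0 trace.

    A 9th-order Butterworth applied forward-backward (second-order sections
    for numerical stability).
    """
    if dff.kind is not TraceKind.DFF:
        raise ValueError("estimate_noise_sd expects a dF/F0 trace")
    if dff.n_samples < _MIN_SAMPLES:
        raise ValueError(
            f"trace of {dff.n_samples} samples is shorter than 3 filter "
            f"lengths ({_MIN_SAMPLES} samples)"
        )
    sos = signal.butter(NOISE_FILTER_ORDER, NOISE_CUTOFF_HZ, btype="highpass",
                        fs=dff.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, dff.values)
    return float(np.std(filtered))


def _find_peaks(values: np.ndarray, height: float) -> np.ndarray:
    """Strict local maxima above ``height``; plateaus take their left-most sample."""
    peaks, props = signal.find_peaks(values, height=height, plateau_size=(1, None))
    return props["left_edges"]


def detect_events(dff: Trace, noise_sd: float,
                  multiplier: float = DEFAULT_MULTIPLIER) -> EventSeries:
    """Detect transient peaks above ``multiplier * noise_sd``.

    ``norm_amplitude`` is amplitude divided by the maximum amplitude among the
    detected events of this trace; to normalize against a whole session
    spanning several traces of the same compartment, use
    :func:`normalize_session`.
    """
    if dff.kind is not TraceKind.DFF:
        raise ValueError("detect_events expects a dF/F0 trace")
    if not np.isfinite(noise_sd) or noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    threshold = multiplier * noise_sd
    idx = _find_peaks(dff.values, threshold)

    window = max(1, int(round(AMPLITUDE_WINDOW_S * dff.fs)))
    amplitudes = np.empty(idx.size)
    for k, i in enumerate(idx):
        lo = max(0, i - window)          # window truncates at trace start
        amplitudes[k] = dff.values[i] - dff.values[lo:i + 1].min()
    max_amp = amplitudes.max() if idx.size else 1.0
    norm = amplitudes / max_amp if max_amp > 0 else np.zeros_like(amplitudes)

    events = [
        Event(peak_time=dff.t0 + i / dff.fs, peak_index=int(i),
              amplitude=float(a), norm_amplitude=float(na))
        for i, a, na in zip(idx, amplitudes, norm)
    ]
    return EventSeries(events=events, trace_id=dff.trace_id,
                       noise_sd=noise_sd, threshold_multiplier=multiplier)


def normalize_session(series_list: list[EventSeries]) -> list[EventSeries]:
    """Re-normalize amplitudes to the maximum across several event series.

    Session maxima are taken per compartment over the entire session,
    including all behavioral and stimulus conditions, so call this once per
    compartment with every condition's series.
    """
    all_amps = np.concatenate([s.amplitudes for s in series_list if len(s)])
    if all_amps.size == 0:
        return series_list
    max_amp = float(all_amps.max())
    out = []
    for s in series_list:
        events = [
            Event(e.peak_time, e.peak_index, e.amplitude,
                  e.amplitude / max_amp if max_amp > 0 else 0.0)
            for e in s.events
        ]
        out.append(EventSeries(events, s.trace_id, s.noise_sd,
                               s.threshold_multiplier))
    return out


def threshold_sweep(dff: Trace, noise_sd: float,
                    multipliers: list[float]) -> dict[float, EventSeries]:
    """Detection at several threshold multipliers (robustness check, +/-30%)."""
    if not multipliers:
        raise ValueError("multiplier list must be non-empty")
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be positive")
    return {m: detect_events(dff, noise_sd, m) for m in multipliers}
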