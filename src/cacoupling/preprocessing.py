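"""Raw fluorescence to dF/F0, and resampling to analysis rates.

The in vivo baseline F0 is the 5th percentile of the low-pass-filtered raw
trace (1 Hz cutoff, zero-phase, 60th-order FIR), computed per trial and
averaged across trials so the same scalar baseline divides darkness and
visual-stimulation data alike.  The ex vivo variant uses a mean over an
explicit baseline window and a background term: (F - F0) / (F0 - F_bg).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import Trace, TraceKind, TrialStructure

#: FIR low-pass order used for baseline smoothing (filter has order+1 taps).
BASELINE_FIR_ORDER = 60
#: Low-pass cutoff for baseline smoothing, Hz.
BASELINE_CUTOFF_HZ = 1.0
#: Percentile of the smoothed trace taken as the baseline.
BASELINE_PERCENTILE = 5.0


def lowpass_fir(values: np.ndarray, fs: float,
                cutoff_hz: float = BASELINE_CUTOFF_HZ,
                order: int = BASELINE_FIR_ORDER) -> np.ndarray:
    """Zero-phase windowed-sinc (Hamming) FIR low-pass.

    Applied forward-backward with reflection padding of one filter length.
    The cutoff is specified at the trace's own sampling rate.
    """
    if values.size <= order:
        raise ValueError(
            f"trace segment of {values.size} samples is too short for a "
            f"{order}th-order filter (need more than {order} samples)"
        )
    nyq = fs / 2.0
    cutoff = min(cutoff_hz, 0.99 * nyq)  # keep well-posed at very low rates
    taps = signal.firwin(order + 1, cutoff, fs=fs, window="hamming")
    padlen = min(order + 1, values.size - 1)
    return signal.filtfilt(taps, [1.0], values, padlen=padlen)


def trial_baselines(raw: Trace, trials: TrialStructure) -> np.ndarray:
    """Per-trial baseline F0(t): 5th percentile of the smoothed raw trace."""
    f0s = []
    for start, stop in trials.bounds:
        smoothed = lowpass_fir(raw.values[start:stop], raw.fs)
        f0s.append(np.percentile(smoothed, BASELINE_PERCENTILE))
    return np.asarray(f0s)


def compute_dff(raw: Trace, trials: TrialStructure | None = None) -> Trace:
    """Convert a raw fluorescence trace to dF/F0.

    Within each trial the trial's own baseline F0(t) is subtracted; the
    divisor is the single scalar F0 = mean of the per-trial baselines, so one
    baseline is shared across all conditions of a session.  Percentiles use
    the linear-interpolation convention.

    Raises
    ------
    ValueError
        If the trace is not raw, a trial extends beyond the trace, the trace
        is shorter than the filter order, or F0 <= 0 (division undefined).
    """
    if raw.kind is not TraceKind.RAW:
        raise ValueError("compute_dff expects a raw trace")
    if trials is None:
        trials = TrialStructure.whole(raw.n_samples)
    trials.validate_against(raw)

    f0s = trial_baselines(raw, trials)
    f0 = float(np.mean(f0s))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.4g} <= 0; dF/F0 is undefined")

    dff = np.zeros_like(raw.values)
    covered = np.zeros(raw.n_samples, dtype=bool)
    for (start, stop), f0_t in zip(trials.bounds, f0s):
        dff[start:stop] = (raw.values[start:stop] - f0_t) / f0
        covered[start:stop] = True
    # Samples outside any trial (inter-trial gaps) use the scalar baseline.
    dff[~covered] = (raw.values[~covered] - f0) / f0
    return raw.with_values(dff, kind=TraceKind.DFF)


def compute_dff_exvivo(raw: Trace, baseline_window: tuple[float, float],
                       f_background: float = 0.0) -> Trace:
    """Ex vivo dF/F0: (F - F0) / (F0 - F_background).

    F0 is the mean of the raw trace over ``baseline_window`` (seconds,
    half-open, relative to ``t0``).  Background-corrected division guards
    against the very low resting fluorescence of distal dendrites ex vivo.
    """
    if raw.kind is not TraceKind.RAW:
        raise ValueError("compute_dff_exvivo expects a raw trace")
    start_s, stop_s = baseline_window
    start = int(round((start_s - raw.t0) * raw.fs))
    stop = int(round((stop_s - raw.t0) * raw.fs))
    if start < 0 or stop > raw.n_samples or stop <= start:
        raise ValueError("baseline window must lie within the trace")
    f0 = float(np.mean(raw.values[start:stop]))
    denom = f0 - f_background
    if denom <= 0:
        raise ValueError(
            f"F0 ({f0:.4g}) must exceed F_background ({f_background:.4g}); "
            "baseline fluorescence too low for dF/F0"
        )
    return raw.with_values((raw.values - f0) / denom, kind=TraceKind.DFF)


def resample(trace: Trace, target_fs: float) -> Trace:
    """Downsample by non-overlapping bin averaging (no upsampling).

    Bin k averages the input samples whose index i satisfies
    ``floor(i * target_fs / fs) == k``; a trailing partial bin is kept, so
    total duration is preserved to within one output sample.
    """
    if target_fs > trace.fs:
        raise ValueError("resample only downsamples: target_fs must be <= fs")
    if target_fs == trace.fs:
        return trace.with_values(trace.values.copy())
    n = trace.n_samples
    bins = np.floor(np.arange(n) * (target_fs / trace.fs)).astype(np.int64)
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=trace.values)
    out = sums / counts
    new = trace.with_values(out)
    new.fs = target_fs
    return new
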