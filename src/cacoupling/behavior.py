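"""Behavior-state segmentation from treadmill speed.

Locomotion requires three criteria simultaneously: instantaneous speed
>= 0.1 cm/s, 0.25 Hz low-pass-filtered speed >= 0.1 cm/s, and mean speed
>= 0.1 cm/s over a 2 s window centred on the sample.  Inter-locomotion gaps
shorter than 500 ms are merged into locomotion.  Stationary samples less than
3 s after, or 0.2 s before, a locomotion bout are excluded from analysis.
Behavioral transitions (for onset/offset-aligned analyses) cover 2 s before
to 1 s after each bout onset and 1 s before to 20 s after each offset,
truncated if another bout begins sooner.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import BehaviorLabels, BehaviorState, SpeedTrace

SPEED_THRESHOLD = 0.1      # cm/s
LOWPASS_CUTOFF_HZ = 0.25
MEAN_WINDOW_S = 2.0
MERGE_GAP_S = 0.5
EXCLUDE_AFTER_S = 3.0
EXCLUDE_BEFORE_S = 0.2
TRANS_PRE_ONSET_S = 2.0
TRANS_POST_ONSET_S = 1.0
TRANS_PRE_OFFSET_S = 1.0
TRANS_POST_OFFSET_S = 20.0


def lowpass_speed(speed: np.ndarray, fs: float) -> np.ndarray:
    """0.25 Hz zero-phase 2nd-order Butterworth low-pass."""
    sos = signal.butter(2, LOWPASS_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, speed)


def centered_mean(values: np.ndarray, fs: float,
                  window_s: float = MEAN_WINDOW_S) -> np.ndarray:
    """Mean over a centred window, truncated at trace boundaries."""
    half = int(round(window_s * fs / 2))
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def locomotion_mask(speed: SpeedTrace,
                    merge_gap_s: float = MERGE_GAP_S) -> np.ndarray:
    """Samples meeting all three locomotion criteria, with short gaps merged.

    Gap merging is applied after the three criteria: any below-threshold run
    between two locomotion runs shorter than ``merge_gap_s`` is relabelled
    as locomotion.
    """
    inst = speed.speed
    low = lowpass_speed(inst, speed.fs)
    cmean = centered_mean(inst, speed.fs)
    mask = (inst >= SPEED_THRESHOLD) & (low >= SPEED_THRESHOLD) & (cmean >= SPEED_THRESHOLD)

    runs = _runs(mask)
    for (_, stop_a), (start_b, _) in zip(runs, runs[1:]):
        if (start_b - stop_a) / speed.fs < merge_gap_s:
            mask[stop_a:start_b] = True
    return mask


def classify_behavior(speed: SpeedTrace,
                      merge_gap_s: float = MERGE_GAP_S) -> BehaviorLabels:
    """Label every sample stationary / locomotion / excluded.

    Samples with instantaneous speed above threshold that fail the smoothed
    or windowed criteria belong to neither state and are excluded, as are
    stationary samples in the peri-locomotion exclusion zones (< 3 s after or
    < 0.2 s before a bout).
    """
    if np.any(speed.speed < 0):
        raise ValueError("speeds must be non-negative")
    if speed.duration < MEAN_WINDOW_S:
        raise ValueError("speed trace shorter than the 2 s criterion window")

    fs = speed.fs
    loco = locomotion_mask(speed, merge_gap_s)
    n = loco.size
    states = np.full(n, int(BehaviorState.EXCLUDED), dtype=np.int8)
    stationary = (speed.speed < SPEED_THRESHOLD) & ~loco
    states[stationary] = int(BehaviorState.STATIONARY)
    states[loco] = int(BehaviorState.LOCOMOTION)

    bouts_idx = _runs(loco)
    after = int(round(EXCLUDE_AFTER_S * fs))
    before = int(round(EXCLUDE_BEFORE_S * fs))
    for start, stop in bouts_idx:
        zone = slice(stop, min(n, stop + after))
        sel = states[zone] == int(BehaviorState.STATIONARY)
        states[zone][sel] = int(BehaviorState.EXCLUDED)
        zone = slice(max(0, start - before), start)
        sel = states[zone] == int(BehaviorState.STATIONARY)
        states[zone][sel] = int(BehaviorState.EXCLUDED)

    bouts = [(start / fs, stop / fs) for start, stop in bouts_idx]
    return BehaviorLabels(states=states, fs=fs, bouts=bouts)


def transition_windows(labels: BehaviorLabels) -> BehaviorLabels:
    """Mark behavioral-transition windows around bout onsets and offsets.

    Windows: [onset - 2 s, onset + 1 s) and [offset - 1 s, offset + 20 s),
    the latter truncated at the next bout's onset.  Transition labels
    override stationary/excluded samples and the 1 s locomotion margins at
    bout edges, but never the protected locomotion interior.
    """
    fs = labels.fs
    n = labels.states.size
    states = labels.states.copy()
    trans = np.zeros(n, dtype=bool)

    onsets = [int(round(b[0] * fs)) for b in labels.bouts]
    offsets = [int(round(b[1] * fs)) for b in labels.bouts]
    for k, (on, off) in enumerate(zip(onsets, offsets)):
        pre = slice(max(0, on - int(round(TRANS_PRE_ONSET_S * fs))),
                    min(n, on + int(round(TRANS_POST_ONSET_S * fs))))
        trans[pre] = True
        post_stop = off + int(round(TRANS_POST_OFFSET_S * fs))
        if k + 1 < len(onsets):
            post_stop = min(post_stop, onsets[k + 1])
        post = slice(max(0, off - int(round(TRANS_PRE_OFFSET_S * fs))),
                     min(n, post_stop))
        trans[post] = True

    # Locomotion interiors beyond the 1 s edge margins stay locomotion.
    protected = np.zeros(n, dtype=bool)
    for on, off in zip(onsets, offsets):
        lo = on + int(round(TRANS_POST_ONSET_S * fs))
        hi = off - int(round(TRANS_PRE_OFFSET_S * fs))
        if hi > lo:
            protected[lo:hi] = True
    trans &= ~protected

    states[trans] = int(BehaviorState.TRANSITION)
    return BehaviorLabels(states=states, fs=fs, bouts=list(labels.bouts))
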