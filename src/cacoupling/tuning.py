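"""Orientation tuning from drifting-grating responses.

Responses are trial-averaged mean dF/F0 over each 3 s stimulus window, with
the eight drift directions collapsed to four orientations (opposite
directions averaged).  Selectivity is summarized two ways: the orientation
selectivity index OSI = (O_pref - O_orth) / (O_pref + O_orth), and the
complex resultant vector V = sum_k R_k exp(2i theta_k) / sum_k R_k whose
argument (halved) gives the preferred orientation on [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BehaviorLabels, BehaviorState, StimSchedule, Trace, TraceKind


@dataclass
class TuningResult:
    orientations: np.ndarray     # degrees, sorted, on [0, 180)
    responses: np.ndarray        # mean dF/F0 per orientation (NaN if no trials)
    preferred: float             # argmax orientation, degrees
    osi: float
    resultant: complex
    resultant_preferred: float   # arg(V)/2 mod 180, degrees
    resultant_magnitude: float


def trial_average(dff: Trace, schedule: StimSchedule,
                  labels: BehaviorLabels | None = None,
                  state: BehaviorState | None = None,
                  min_state_fraction: float = 0.5) -> dict[float, float]:
    """Per-orientation mean dF/F0, averaged across trials.

    Each trial's response is the mean dF/F0 over its stimulus window; trials
    of opposite drift directions pool into one orientation.  With ``labels``
    and ``state`` given, a trial qualifies only if more than
    ``min_state_fraction`` of its stimulus-window samples carry that state.
    Orientations with zero qualifying trials map to NaN.
    """
    if dff.kind is not TraceKind.DFF:
        raise ValueError("trial_average expects a dF/F0 trace")
    per_ori: dict[float, list[float]] = {}
    for onset, ori in zip(schedule.onsets, schedule.orientations):
        lo = int(round((onset - dff.t0) * dff.fs))
        hi = int(round((onset + schedule.stim_duration - dff.t0) * dff.fs))
        if lo < 0 or hi > dff.n_samples:
            raise ValueError("trial extends beyond trace")
        if labels is not None and state is not None:
            frac = float(np.mean(labels.states[lo:hi] == int(state)))
            if frac <= min_state_fraction:
                continue
        per_ori.setdefault(float(ori), []).append(float(np.mean(dff.values[lo:hi])))
    out: dict[float, float] = {}
    for ori in sorted(set(float(o) for o in schedule.orientations)):
        vals = per_ori.get(ori, [])
        out[ori] = float(np.mean(vals)) if vals else float("nan")
    return out


def osi(responses: dict[float, float]) -> tuple[float, float]:
    """Orientation selectivity index and preferred orientation.

    Preferred is the orientation with the maximal trial-averaged response;
    orthogonal is preferred + 90 deg (mod 180).  Raises if either response is
    missing or O_pref + O_orth <= 0.
    """
    finite = {o: r for o, r in responses.items() if np.isfinite(r)}
    if not finite:
        raise ValueError("no finite responses")
    preferred = max(finite, key=finite.get)
    orth = (preferred + 90.0) % 180.0
    if orth not in finite:
        raise ValueError(f"no response measured at the orthogonal orientation {orth}")
    o_pref, o_orth = finite[preferred], finite[orth]
    denom = o_pref + o_orth
    if denom <= 0:
        raise ValueError("O_pref + O_orth <= 0: OSI undefined")
    return (o_pref - o_orth) / denom, preferred


def resultant_vector(responses: dict[float, float]) -> tuple[complex, float]:
    """Complex resultant V and the preferred angle arg(V)/2 mod 180 (deg).

    Negative mean responses are floored at zero before the weighted sum (the
    vector average is ill-behaved for negative weights).  All-zero responses
    leave V undefined and raise rather than returning an arbitrary angle.
    """
    oris = np.array([o for o, r in responses.items() if np.isfinite(r)])
    resp = np.array([responses[o] for o in oris])
    resp = np.maximum(resp, 0.0)
    total = resp.sum()
    if total <= 0:
        raise ValueError("all responses zero: resultant vector undefined")
    theta = np.deg2rad(oris)
    v = complex(np.sum(resp * np.exp(2j * theta)) / total)
    angle = np.degrees(np.angle(v)) / 2.0 % 180.0
    return v, float(angle)


def tuning_result(responses: dict[float, float]) -> TuningResult:
    """Bundle OSI, preferred orientation and resultant vector for one ROI."""
    osi_value, preferred = osi(responses)
    v, v_angle = resultant_vector(responses)
    oris = np.array(sorted(responses))
    return TuningResult(
        orientations=oris,
        responses=np.array([responses[o] for o in oris]),
        preferred=preferred,
        osi=osi_value,
        resultant=v,
        resultant_preferred=v_angle,
        resultant_magnitude=abs(v),
    )


def normalize_to_preferred(responses: dict[float, float],
                           reference: dict[float, float] | None = None) -> dict[float, float]:
    """Normalize a tuning curve to the preferred-orientation response.

    With ``reference`` given (e.g. the stationary-state curve), the divisor is
    the reference curve's preferred response, as used when comparing running
    vs stationary tuning.
    """
    ref = reference if reference is not None else responses
    finite = {o: r for o, r in ref.items() if np.isfinite(r)}
    if not finite:
        raise ValueError("no finite responses")
    peak = finite[max(finite, key=finite.get)]
    if peak == 0:
        raise ValueError("preferred response is zero: normalization undefined")
    return {o: r / peak for o, r in responses.items()}
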