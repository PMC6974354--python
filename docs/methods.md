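# Methods

This note documents the models, numerical choices and limitations behind
`cacoupling`. Defaults are stated with units; everything here is
configuration or derivation the code actually implements — no empirical
claim is made beyond what the test suite and `scripts/acceptance.py`
compute.

## Signal model and preprocessing

A raw trace F(t) is one ROI's mean pixel intensity over time, uniformly
sampled (single-plane sessions at 120 Hz are bin-averaged down to 5 Hz for
analysis; dual-plane sessions run natively at 4.8 Hz per plane). Baseline
F0 is estimated per trial as the 5th percentile (linear-interpolation
convention) of the low-pass-filtered trace — a zero-phase, 60th-order
windowed-sinc FIR (Hamming window) with 1 Hz cutoff at the trace's own
sampling rate, applied forward–backward with reflection padding of one
filter length. Each trial's own F0(t) is subtracted; the divisor is the
single scalar F0 = mean of the per-trial baselines, so darkness and
stimulation periods share one baseline. Sessions without trial structure
are treated as a single trial. The filter is applied at the native rate
rather than after downsampling; the alternative ordering changes F0 only
through filter edge effects and is not exposed.

Downsampling is non-overlapping bin averaging (a trailing partial bin is
kept), chosen over decimation to suppress aliasing without a second filter
stage.

The ex vivo variant uses ΔF/F0 = (F − F0)/(F0 − F_bg) with F0 the mean over
an explicit baseline window (1 s by default) and F_bg a background term,
because resting fluorescence in distal dendrites ex vivo is often too low
for the plain ratio; F0 ≤ F_bg is rejected rather than producing inflated
values.

## Transient detection

Noise is the standard deviation of the ΔF/F0 trace after a 0.6 Hz
zero-phase high-pass. The filter is a 9th-order Butterworth applied
forward–backward in second-order sections; a spectral test checks the
resulting SD against an ideal frequency-domain high-pass within 5%, so the
IIR/FIR ambiguity is immaterial at these rates. Peaks are strict local
maxima of ΔF/F0 whose height exceeds 2.8 × noise SD (the multiplier is a
parameter; ±30% sweeps are built in as `threshold_sweep`). Plateaus take
their left-most sample. No minimum inter-peak distance is imposed, so at
low signal-to-noise a single transient's decay can carry duplicate
above-threshold local maxima — visible in the examples, and the reason
recovery tests are run at low noise.

Event amplitude is the peak value minus the minimum of ΔF/F0 over a 2 s
backward window ending at (and including) the peak, truncated at the trace
start. Detection height and amplitude are deliberately different
quantities: the first is the trace value compared against the threshold,
the second a local rise that remains meaningful for events riding on a
previous transient's decay. Normalized amplitudes divide by the maximum
amplitude per compartment over the whole session (all conditions pooled;
`normalize_session` re-normalizes across condition-split traces).

## Coincidence matching and coupling

Two peaks are candidate coincidences when one lies within [−2 s, +1 s] of
the other (either side may serve as reference, so the achievable |Δt| bound
is 2 s). Matching is one-to-one: candidate pairs are sorted globally by
|Δt| (ties broken by signed Δt, then event order, for determinism) and
accepted greedily. The algorithm is verified against exhaustive
maximum-cardinality, minimum-cost assignment on small instances. For
specificity curves, each side is its own reference: the proximal curve
counts proximal events lacking a distal match and vice versa.

Paired amplitudes feed a Pearson correlation; when one side has no detected
peak, that side contributes max − min of its ΔF/F0 in a 3 s window centred
on the partner's peak. Fewer than 3 pairs raises an error rather than
returning r = 0. The permutation null shuffles the distal amplitude order
(default 1000 permutations, seeded; explicit permutation lists reproduce a
single-shuffle analysis).

Binned specificity uses half-open normalized-amplitude bins of width 0.05,
the final bin closed at 1.0; empty bins are missing (NaN), never zero.
Across pairs, per-bin proportions are combined as a weighted mean with
weights equal to each pair's event count in the bin; the weighted SEM is
the weight-normalized SD divided by √(number of contributing pairs) — one
of several defensible "weighted SEM" conventions, fixed and documented
here.

Frequency attenuation is the distal/proximal event-count ratio per pair;
chained per-segment losses compound as 1 − Π(1 − loss_i). Residual analysis
fits distal on proximal normalized amplitudes by iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685,
coefficient-convergence tolerance 1e−8, via statsmodels RLM), verified
against an exhaustive least-trimmed-squares oracle; residuals are vertical
distances from the fit, grouped by condition labels for cumulative
distributions.

## Behavior segmentation

Criteria are evaluated at the trace's analysis rate after any
interpolation. Locomotion requires instantaneous speed ≥ 0.1 cm/s, 0.25 Hz
low-passed speed ≥ 0.1 cm/s (2nd-order zero-phase Butterworth; only the
cutoff is prescribed, the order is a choice), and mean speed ≥ 0.1 cm/s
over a 2 s centred window truncated at trace boundaries. Gaps shorter than
500 ms between locomotion runs are merged *after* the three criteria
(applying the merge before the windowed criterion would differ only for
gaps whose windowed mean straddles threshold). Stationary is instantaneous
speed < 0.1 cm/s; stationary samples < 3 s after or < 0.2 s before a bout
are excluded, as are samples satisfying neither definition (above-threshold
speed failing the smoothed criteria). Transition windows span
[onset − 2 s, onset + 1 s) and [offset − 1 s, offset + 20 s), the latter
truncated at the next bout's onset; transitions override stationary,
excluded and the 1 s bout-edge margins, never the protected bout interior.
The rule engine is verified sample-by-sample against an independent naive
loop implementation.

## Orientation tuning

Trial responses are mean ΔF/F0 over each 3 s stimulus window; the eight
drift directions collapse to four orientations by pooling opposite
directions before any indexing (direction selectivity is out of scope). A
trial is attributed to a behavioral state when more than half its window
samples carry that state. OSI = (O_pref − O_orth)/(O_pref + O_orth) with
preferred = argmax orientation and orthogonal = preferred + 90°; a
non-positive denominator raises. The resultant vector
V = Σ R e^{2iθ} / Σ R floors negative mean responses at zero (the weighted
circular mean is ill-behaved for negative weights) and raises on an
all-zero curve instead of fabricating an angle. For a cosine-shaped tuning
curve sampled at four equally spaced orientations, arg(V)/2 recovers the
continuous preferred orientation exactly; the generator uses
g(θ) = g_orth + (g_pref − g_orth)cos²(θ − preferred) with
g_orth = g_pref(1 − OSI)/(1 + OSI), so target OSI and preferred are exact
in the noiseless curve.

## Ex vivo detection

Trials are 6 s at 20 Hz with a 1 s baseline; 10-pulse trains at 5–200 Hz.
The response is the peak ΔF/F0 within 1 s after stimulation ends, minus the
mean sham peak measured in the matched window. The null distribution is
leave-one-out over sham trials (each sham peak minus the mean of the rest),
and detection requires exceeding 2.8 × null SD; a degenerate null (SD = 0)
raises. Per-compartment max-normalization is an output option and cannot
change detection outcomes (amplitudes and null scale together). The
simulator gates the dendritic response of somatic-stimulation trials on a
configurable critical frequency (default 50 Hz) and treats
electrophysiology only as metadata (evoked action-potential counts); the
default sham count is 10 per set.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
sparse somatic transients (Poisson, default 6/min, thinned to a 2.5 s
minimum separation because the indicator cannot resolve intra-burst spikes
— one generated event is one merged transient), a categorical
burst-frequency label (default mass at 10/25/50/100 Hz with 25% at or above
the 50 Hz gate), log-normal amplitudes (median 0.5 ΔF/F0, σ_log 0.5 — the
true in vivo amplitude distribution is unknown; log-normal is a modelling
choice), per-segment survival that is logistic in normalized amplitude
(midpoints 0.10/0.06/0.18 along soma→trunk→tuft, steepness 15) and unity
above the critical frequency, rare tuft-initiated global events (default
0.3/min) present in every compartment, and fluorescence rendered as
baseline × (1 + Σ a·k(t) + noise) with a unit-peak
difference-of-exponentials kernel (rise 0.18 s / decay 1.0 s for a slow
indicator; 0.05/0.3 s approximates a fast one) and i.i.d. Gaussian ΔF/F0
noise (default 0.02).

Not emulated: photon (shot) statistics, bleaching, neuropil contamination,
motion artefacts, biophysical cable properties, pixel-level movies, and
correlation between burst frequency and amplitude. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the assumed
signal structure, not robustness to every real-data nuisance; the
out-of-scope nuisances (motion correction, ROI extraction) are upstream of
this pipeline.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen as the smallest
sizes at which the statistical checks are well-powered: 1000 adversarial
event-series pairs (Poisson 3/min, 10 min each) for the matching-window
bound, ≥ 500 ground-truth events for attenuation-curve recovery, 1000
permutations for the shuffle null, 1500 + 1500 sham trials for false-
positive calibration, and 200 simulated tuned neurons (5 repeats × 8
directions each) for orientation recovery. Every stochastic component
accepts an explicit seed (numpy `default_rng`; per-item seeds derive from a
`SeedSequence`), and identical seeds give bit-identical outputs, including
CSV artifacts of the end-to-end pipeline.

## Known limitations

- Greedy |Δt|-ordered matching is not guaranteed globally optimal on
  pathological tie structures, though it matches exhaustive assignment on
  all tested instances and cannot violate the 2 s window bound.
- With no minimum inter-peak distance, event counts at realistic noise
  overestimate ground truth (duplicate maxima on decays); frequency ratios
  are less biased because duplication affects both compartments.
- The weighted-SEM convention for binned specificity is one of several in
  use; comparisons across packages should compare means and weights, not
  SEMs.
- The 40 Hz instantaneous-speed acquisition detail is subsumed by
  evaluating all behavior criteria at the (interpolated) imaging rate.
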