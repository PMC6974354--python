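"""Coincidence matching, coupling statistics, and their independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacoupling import (
    Event,
    EventSeries,
    binned_specificity,
    chain_attenuation,
    coincidence_containment_width,
    generate_event_pair,
    match_events,
    pearson,
    residual_analysis,
    robust_fit,
    shuffle_null,
)
from cacoupling.coupling import amplitude_pairs, pair_correlation

from conftest import make_dff


def series(times, amps=None):
    times = np.asarray(times, dtype=float)
    amps = np.ones_like(times) if amps is None else np.asarray(amps, float)
    max_amp = amps.max() if times.size else 1.0
    return EventSeries([Event(float(t), i, float(a), float(a / max_amp))
                        for i, (t, a) in enumerate(zip(times, amps))])


def exhaustive_match(tp, td, before=2.0, after=1.0):
    """Oracle: maximum-cardinality, minimum-total-|dt| one-to-one assignment."""
    def in_window(t_ref, t_other):
        dt = t_other - t_ref
        return -before <= dt <= after or -before <= -dt <= after

    cands = [[j for j, t in enumerate(td) if in_window(tp[i], t)]
             for i in range(len(tp))]
    best = (0, math.inf, frozenset())

    def rec(i, used, n, cost, pairs):
        nonlocal best
        if i == len(tp):
            if n > best[0] or (n == best[0] and cost < best[1]):
                best = (n, cost, frozenset(pairs))
            return
        rec(i + 1, used, n, cost, pairs)
        for j in cands[i]:
            if j not in used:
                rec(i + 1, used | {j}, n + 1, cost + abs(td[j] - tp[i]),
                    pairs | {(i, j)})

    rec(0, frozenset(), 0, 0.0, frozenset())
    return best[0], best[1], best[2]


class TestMatchEvents:
    def test_identical_series_fully_matched_at_zero_lag(self):
        s = series([1.0, 5.0, 9.0])
        pair = match_events(s, series([1.0, 5.0, 9.0]))
        assert len(pair.matches) == 3
        assert all(m.dt == 0.0 for m in pair.matches)
        assert pair.proximal_only == [] and pair.distal_only == []

    def test_events_beyond_two_seconds_never_match(self):
        pair = match_events(series([10.0]), series([12.5]))
        assert pair.matches == []
        assert pair.proximal_only == [0] and pair.distal_only == [0]

    def test_asymmetric_window_accepts_lead_and_lag(self):
        # distal 1.9 s before the proximal reference: inside [-2, +1]
        assert len(match_events(series([10.0]), series([8.1])).matches) == 1
        # distal 1.9 s after: outside the proximal window but the distal
        # reference sees the proximal peak 1.9 s before it
        assert len(match_events(series([10.0]), series([11.9])).matches) == 1

    def test_one_to_one_each_event_used_once(self):
        pair = match_events(series([10.0, 10.5]), series([10.2]))
        assert len(pair.matches) == 1
        assert pair.matches[0].dt == pytest.approx(0.2)
        assert pair.proximal_only == [1]

    def test_matches_equal_exhaustive_assignment_on_small_instances(self):
        """Greedy nearest-|dt| equals brute-force optimal assignment."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(2, 9)
            tp = np.sort(rng.uniform(0, 200, n) * 1.0)
            tp = tp[np.concatenate([[True], np.diff(tp) > 5.0])]  # separated
            td = np.sort(tp + rng.uniform(-0.4, 0.4, tp.size))
            extras = np.sort(rng.uniform(300, 400, 2))
            td = np.sort(np.concatenate([td, extras]))
            got = match_events(series(tp), series(td))
            n_opt, cost_opt, pairs_opt = exhaustive_match(tp, td)
            assert len(got.matches) == n_opt
            got_pairs = {(m.prox_index, m.dist_index) for m in got.matches}
            assert got_pairs == set(pairs_opt)

    def test_unsorted_series_rejected(self):
        bad = EventSeries.__new__(EventSeries)
        bad.events = [Event(5.0, 0, 1.0, 1.0), Event(1.0, 1, 1.0, 1.0)]
        bad.trace_id, bad.noise_sd, bad.threshold_multiplier = "", 1.0, 2.8
        with pytest.raises(ValueError, match="sorted"):
            match_events(bad, series([1.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 500), min_size=0, max_size=30),
           st.lists(st.floats(0, 500), min_size=0, max_size=30))
    def test_window_bound_and_conservation_hold_for_any_input(self, tp, td):
        tp = np.unique(np.round(tp, 3))
        td = np.unique(np.round(td, 3))
        pair = match_events(series(tp), series(td))
        for m in pair.matches:
            assert abs(m.dt) <= 2.0 + 1e-9
        assert len(pair.matches) + len(pair.proximal_only) == tp.size
        assert len(pair.matches) + len(pair.distal_only) == td.size
        prox_used = [m.prox_index for m in pair.matches]
        dist_used = [m.dist_index for m in pair.matches]
        assert len(set(prox_used)) == len(prox_used)
        assert len(set(dist_used)) == len(dist_used)


def test_adversarial_jittered_pairs_respect_window_bound():
    max_dt = 0.0
    for k in range(50):
        prox, dist = generate_event_pair(duration=600, rate_per_min=3.0,
                                         jitter=(-3.0, 3.0), seed=k)
        pair = match_events(prox, dist)
        if pair.matches:
            max_dt = max(max_dt, max(abs(m.dt) for m in pair.matches))
    assert 0 < max_dt <= 2.0


class TestPearson:
    def test_exact_affine_relation_gives_r_one(self):
        p = series([1, 5, 9, 13], amps=[0.2, 0.4, 0.6, 0.8])
        d = series([1, 5, 9, 13], amps=[0.1, 0.2, 0.3, 0.4])
        pair = match_events(p, d)
        assert pair_correlation(pair) == pytest.approx(1.0)

    def test_hand_listed_pairs_match_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-10)

    def test_independent_amplitudes_give_near_zero_r(self):
        rng = np.random.default_rng(8)
        times = np.arange(2000) * 10.0
        p = series(times, amps=rng.lognormal(0, 0.5, 2000))
        d = series(times, amps=rng.lognormal(0, 0.5, 2000))
        assert abs(pair_correlation(match_events(p, d))) < 0.1

    def test_fewer_than_three_pairs_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            pearson([1.0, 2.0], [1.0, 2.0])


def test_unmatched_readout_is_max_minus_min_in_centered_window():
    fs = 5.0
    prox = series([10.0], amps=[1.0])
    dist = series([], amps=[])
    dist_vals = np.zeros(100)
    dist_vals[45] = -0.1  # within 10 +/- 1.5 s
    dist_vals[52] = 0.3
    dist_trace = make_dff(dist_vals, fs=fs)
    pair = match_events(prox, dist)
    xp, xd = amplitude_pairs(pair, dist_trace=dist_trace)
    assert xp.tolist() == [1.0]
    assert xd[0] == pytest.approx(0.4)  # max - min over the 3 s window


class TestShuffleNull:
    def _pair(self):
        rng = np.random.default_rng(9)
        amps = rng.lognormal(0, 0.5, 200)
        times = np.arange(200) * 10.0
        return match_events(series(times, amps), series(times, 0.5 * amps))

    def test_identity_permutation_reproduces_r(self):
        pair = self._pair()
        r = pair_correlation(pair)
        null = shuffle_null(pair, permutations=[np.arange(200)])
        assert null[0] == pytest.approx(r, abs=1e-12)

    def test_null_mean_centred_at_zero(self):
        pair = self._pair()
        null = shuffle_null(pair, n_perm=1000, seed=10)
        se = null.std(ddof=1) / math.sqrt(null.size)
        assert abs(null.mean()) <= 3 * se
        assert pair_correlation(pair) > 0.99  # the coupled r itself is high

    def test_seed_determinism(self):
        pair = self._pair()
        a = shuffle_null(pair, n_perm=50, seed=11)
        b = shuffle_null(pair, n_perm=50, seed=11)
        np.testing.assert_array_equal(a, b)


class TestBinnedSpecificity:
    def test_lossless_pairs_have_zero_specific_proportion(self):
        times = np.arange(50) * 10.0
        amps = np.linspace(0.1, 1.0, 50)
        pair = match_events(series(times, amps), series(times, amps))
        spec = binned_specificity([pair])
        filled = ~np.isnan(spec.prox_mean)
        assert np.all(spec.prox_mean[filled] == 0.0)
        assert np.all(spec.dist_mean[~np.isnan(spec.dist_mean)] == 0.0)

    def test_single_pair_weighted_mean_is_raw_proportion(self):
        prox = series([10.0, 20.0, 30.0, 40.0], amps=[0.1, 0.12, 0.9, 0.95])
        dist = series([30.0, 40.0], amps=[0.9, 0.95])
        spec = binned_specificity([match_events(prox, dist)])
        # both small-amplitude events (norm ~0.105..0.126, bin [0.10, 0.15))
        # are proximal-specific: proportion exactly 1
        b = int(0.105 / 0.05)
        assert spec.prox_mean[b] == pytest.approx(1.0)
        assert spec.prox_mean[19] == pytest.approx(0.0)  # large events matched

    def test_empty_bins_reported_missing_not_zero(self):
        pair = match_events(series([5.0], amps=[1.0]), series([5.0], amps=[1.0]))
        spec = binned_specificity([pair])
        assert np.isnan(spec.prox_mean[0])
        assert spec.prox_counts[0] == 0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            binned_specificity([match_events(series([]), series([]))])


class TestChainAttenuation:
    def test_printed_per_segment_losses_compound_to_forty_percent(self):
        assert chain_attenuation([0.14, 0.08, 0.24]) == pytest.approx(0.3987, abs=5e-5)

    def test_zero_losses(self):
        assert chain_attenuation([0.0, 0.0]) == 0.0

    def test_total_loss(self):
        assert chain_attenuation([1.0]) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            chain_attenuation([0.5, 1.2])


def test_containment_width_is_twice_the_sd():
    assert coincidence_containment_width(0.28) == pytest.approx(0.56)


class TestResiduals:
    def test_collinear_points_have_zero_residuals(self):
        times = np.arange(10) * 10.0
        amps = np.linspace(0.1, 1.0, 10)
        pair = match_events(series(times, amps), series(times, 0.6 * amps))
        res = residual_analysis([pair], normalized=False)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-8)
        assert res.slope == pytest.approx(0.6, abs=1e-8)

    def test_robust_fit_ignores_gross_outlier_matching_lts_oracle(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0.05, 1.0, 20)
        y = 0.3 + 0.5 * x
        x_all = np.concatenate([x, [0.5]])
        y_all = np.concatenate([y, [5.0]])  # gross outlier
        slope, intercept = robust_fit(x_all, y_all)
        # oracle: exhaustive least-trimmed-squares over all 2-point lines
        best = None
        h = 11  # majority subset
        for i, j in itertools.combinations(range(21), 2):
            if x_all[i] == x_all[j]:
                continue
            s = (y_all[j] - y_all[i]) / (x_all[j] - x_all[i])
            b = y_all[i] - s * x_all[i]
            r2 = np.sort((y_all - (b + s * x_all)) ** 2)[:h].sum()
            if best is None or r2 < best[0]:
                best = (r2, s, b)
        assert slope == pytest.approx(best[1], abs=1e-6)
        assert intercept == pytest.approx(best[2], abs=1e-6)
        res = residual_analysis(
            [match_events(series(np.arange(21) * 10.0, x_all),
                          series(np.arange(21) * 10.0, y_all))],
            normalized=False)
        inliers = np.abs(res.residuals) < 0.01
        assert inliers.sum() == 20
        assert res.residuals[~inliers][0] == pytest.approx(
            5.0 - (best[2] + best[1] * 0.5), abs=1e-4)

    def test_condition_permutation_only_relabels_residuals(self):
        times = np.arange(30) * 10.0
        rng = np.random.default_rng(13)
        amps = rng.lognormal(0, 0.4, 30)
        pair = match_events(series(times, amps),
                            series(times, 0.5 * amps + rng.normal(0, 0.05, 30)))
        labels = np.array(["dark"] * 15 + ["stim"] * 15)
        a = residual_analysis([pair], conditions=[labels])
        b = residual_analysis([pair], conditions=[labels[::-1]])
        np.testing.assert_allclose(np.sort(a.residuals), np.sort(b.residuals))

    def test_degenerate_x_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            robust_fit(np.full(5, 0.3), np.arange(5.0))
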