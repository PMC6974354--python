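"""Forward-simulator contracts: kernel shape, propagation, determinism."""

import math

import numpy as np
import pytest

from cacoupling import (
    FlatAttenuation,
    SynthConfig,
    generate_event_pair,
    generate_neuron,
    generate_speed,
    generate_stim_schedule,
    generate_tuned_responses,
    truth_event_series,
)
from cacoupling.synthetic import kernel, kernel_peak_time


def test_zero_rate_gives_baseline_plus_noise_and_empty_truth():
    cfg = SynthConfig(duration=60.0, soma_event_rate=0.0,
                      tuft_initiated_rate=0.0, noise_sd=0.02, seed=3)
    traces, truth = generate_neuron(cfg)
    assert truth.events == []
    for tr in traces.values():
        dff = tr.values / cfg.baseline_f0 - 1.0
        assert abs(np.mean(dff)) < 0.01
        assert np.std(dff) == pytest.approx(0.02, rel=0.15)


def test_single_impulse_peak_matches_closed_form_kernel_maximum():
    """A noiseless impulse of amplitude a peaks at a x (unit kernel max)."""
    rise, decay, a = 0.18, 1.0, 0.8
    fs = 2000.0  # fine grid so the sampled max approaches the analytic peak
    t = np.arange(0, 8.0, 1.0 / fs)
    trace = a * kernel(t - 2.0, rise, decay)
    # oracle: maximize the unnormalized kernel formula on the dense grid
    g = np.exp(-t / decay) - np.exp(-t / rise)
    tp = kernel_peak_time(rise, decay)
    k_analytic = math.exp(-tp / decay) - math.exp(-tp / rise)
    assert g.max() == pytest.approx(k_analytic, abs=1e-6)
    assert trace.max() == pytest.approx(a, abs=1e-6)  # unit-peak normalization
    assert t[np.argmax(trace)] == pytest.approx(2.0 + tp, abs=2.0 / fs)


def test_kernel_is_causal_and_unit_peak():
    t = np.linspace(-1, 10, 5000)
    k = kernel(t, 0.05, 0.3)
    assert np.all(k[t < 0] == 0)
    assert k.max() == pytest.approx(1.0, abs=1e-4)


def test_lossless_propagation_puts_every_event_everywhere():
    cfg = SynthConfig(duration=600.0, attenuation_curve=FlatAttenuation(1.0),
                      tuft_initiated_rate=0.0, seed=5)
    _, truth = generate_neuron(cfg)
    assert len(truth.events) > 0
    for e in truth.events:
        assert all(e.reached.values())
    assert truth.count_in("tuft") == truth.count_in("soma")


def test_seed_determinism_bit_identical():
    cfg = SynthConfig(duration=120.0, seed=11)
    t1, g1 = generate_neuron(cfg, 2)
    t2, g2 = generate_neuron(cfg, 2)
    for comp in t1:
        np.testing.assert_array_equal(t1[comp].values, t2[comp].values)
    assert [e.time for e in g1.events] == [e.time for e in g2.events]
    assert [e.reached for e in g1.events] == [e.reached for e in g2.events]


def test_event_count_conservation_along_chain():
    """Distal ground-truth events never exceed proximal + tuft-initiated."""
    cfg = SynthConfig(duration=900.0, seed=13, tuft_initiated_rate=1.0)
    _, truth = generate_neuron(cfg)
    n_tuft_init = sum(e.origin == "tuft" for e in truth.events)
    chain = cfg.chain
    for prox, dist in zip(chain, chain[1:]):
        assert truth.count_in(dist) <= truth.count_in(prox) + n_tuft_init
    for e in truth.events:
        # somatofugal monotonicity: a distal flag implies the proximal flag
        flags = [e.reached[c] for c in chain]
        if e.origin == "soma":
            assert flags == sorted(flags, reverse=True)
            assert e.reached["soma"]


def test_attenuation_recovery_frequency_ratio_matches_survival():
    """Flat survival p: distal/proximal count ratio ~ p within 3 binomial SE."""
    p = 0.8
    cfg = SynthConfig(duration=18000.0, soma_event_rate=6.0,
                      attenuation_curve=FlatAttenuation(p),
                      tuft_initiated_rate=0.0, seed=17,
                      chain=("soma", "pTrunk"), noise_sd=0.0)
    _, truth = generate_neuron(cfg)
    n = truth.count_in("soma")
    assert n >= 1000
    ratio = truth.count_in("pTrunk") / n
    se = math.sqrt(p * (1 - p) / n)
    assert abs(ratio - p) <= 3 * se


def test_truth_event_series_normalizes_per_compartment():
    cfg = SynthConfig(duration=600.0, seed=19)
    _, truth = generate_neuron(cfg)
    s = truth_event_series(truth, "soma")
    assert len(s) == truth.count_in("soma")
    assert s.norm_amplitudes.max() == pytest.approx(1.0)
    assert np.all(np.diff(s.peak_times) > 0)


class TestSpeedGeneration:
    def test_no_bouts_all_zero(self):
        sp = generate_speed(30.0, 10.0, [])
        assert np.all(sp.speed == 0)

    def test_single_bout_exact_plateau(self):
        sp = generate_speed(30.0, 10.0, [(10.0, 20.0, 5.0)])
        t = sp.times
        inside = (t >= 10.0) & (t < 20.0)
        assert np.all(sp.speed[inside] == 5.0)
        assert np.all(sp.speed[~inside] == 0.0)

    def test_jitter_deterministic_under_seed(self):
        a = generate_speed(30.0, 10.0, [(5.0, 25.0, 5.0)], seed=4, jitter_sd=0.5)
        b = generate_speed(30.0, 10.0, [(5.0, 25.0, 5.0)], seed=4, jitter_sd=0.5)
        np.testing.assert_array_equal(a.speed, b.speed)
        assert np.any(a.speed[(a.times >= 5) & (a.times < 25)] != 5.0)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_speed(30.0, 10.0, [(5.0, 15.0, 5.0), (10.0, 20.0, 3.0)])


class TestTunedResponses:
    def setup_method(self):
        self.schedule = generate_stim_schedule(n_repeats=3, seed=0)

    def test_untuned_equal_gains(self):
        g = generate_tuned_responses(self.schedule, preferred=30.0, osi_target=0.0)
        assert np.allclose(g, g[0])

    def test_fully_tuned_zero_orthogonal_gain(self):
        g = generate_tuned_responses(self.schedule, preferred=0.0, osi_target=1.0)
        orth = np.isclose(self.schedule.orientations, 90.0)
        assert np.allclose(g[orth], 0.0, atol=1e-12)

    def test_half_tuned_orthogonal_gain_is_one_third(self):
        # inverting OSI = (1 - g_orth)/(1 + g_orth) = 0.5 gives g_orth = 1/3
        g = generate_tuned_responses(self.schedule, preferred=0.0,
                                     osi_target=0.5, gain=1.0)
        orth = np.isclose(self.schedule.orientations, 90.0)
        pref = np.isclose(self.schedule.orientations, 0.0)
        assert np.allclose(g[orth], 1.0 / 3.0)
        assert np.allclose(g[pref], 1.0)
        assert (1 - 1 / 3) / (1 + 1 / 3) == pytest.approx(0.5)


def test_invalid_config_names_offending_field():
    with pytest.raises(ValueError, match="kernel_rise"):
        SynthConfig(kernel_rise=float("nan"))
    with pytest.raises(ValueError, match="soma_event_rate"):
        SynthConfig(soma_event_rate=-1.0)
    with pytest.raises(ValueError, match="kernel_rise"):
        SynthConfig(kernel_rise=2.0, kernel_decay=1.0)


def test_event_pair_generator_is_seeded_and_sorted():
    p1, d1 = generate_event_pair(seed=9)
    p2, d2 = generate_event_pair(seed=9)
    np.testing.assert_array_equal(p1.peak_times, p2.peak_times)
    np.testing.assert_array_equal(d1.peak_times, d2.peak_times)
    assert np.all(np.diff(d1.peak_times) > 0)
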