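"""Fidelity metrics: matching, failure rates, delays, regularity, reliability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonfid.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
)
from axonfid.spike_metrics import (
    PairedRecording,
    SpikeTrain,
    StepRecord,
    StepSession,
    axosomatic_delay_ms,
    classify_fidelity,
    failure_rate_per_1000,
    firing_stats,
    match_spikes,
    normalize_frequency,
    reliability_by_frequency,
    success_at_max_frequency,
)
from axonfid.synthetic_data import GeneratorConfig, gen_paired_recording, gen_soma_train

from conftest import make_pair


def brute_force_best_matching(soma, axon, delay_s, window_s):
    """Exhaustive optimum over all one-to-one, within-window assignments.

    Maximises the number of matched soma spikes; among maximal matchings,
    minimises total |axon - (soma + delay)| displacement.  Exponential —
    for oracle use on ~10-spike instances only.
    """
    candidates = []
    for s in soma:
        cands = [j for j, a in enumerate(axon) if abs(a - (s + delay_s)) <= window_s]
        candidates.append(cands + [None])
    best = (-1, np.inf, None)
    for choice in itertools.product(*candidates):
        used = [j for j in choice if j is not None]
        if len(set(used)) != len(used):
            continue
        n = len(used)
        disp = sum(
            abs(axon[j] - (s + delay_s)) for s, j in zip(soma, choice) if j is not None
        )
        if (n, -disp) > (best[0], -best[1]):
            best = (n, disp, choice)
    return best


class TestMatching:
    def test_pure_shift_matches_everything(self):
        soma = np.arange(1, 11) * 0.02
        pair = make_pair(soma, soma + 0.00015, 1.0)
        m = match_spikes(pair, window_ms=2.0)
        assert m.n_matched == 10 and m.n_failures == 0

    def test_empty_axon_all_failures(self):
        pair = make_pair([0.1, 0.2, 0.3], [], 1.0)
        m = match_spikes(pair)
        assert m.n_matched == 0 and m.n_failures == 3

    def test_empty_soma_raises(self):
        pair = make_pair([], [0.1], 1.0)
        with pytest.raises(InsufficientDataError):
            match_spikes(pair)

    def test_greedy_equals_brute_force_on_random_toys(self, rng):
        # 200 random 10-spike instances with deletions and jitter
        for _ in range(200):
            soma = np.sort(rng.uniform(0, 0.25, size=10))
            soma = soma[np.concatenate(([True], np.diff(soma) > 0.004))]
            keep = rng.random(soma.size) > 0.2
            axon = np.sort(soma[keep] + 0.0002 + rng.normal(0, 0.0003, int(keep.sum())))
            if axon.size > 1:
                axon = axon[np.concatenate(([True], np.diff(axon) > 0))]
            axon = axon[(axon >= 0) & (axon <= 0.3)]
            pair = make_pair(soma, axon, 0.3)
            m = match_spikes(pair, window_ms=2.0)
            n_opt, _, _ = brute_force_best_matching(
                soma, axon, m.delay_estimate_ms / 1000.0, m.window_ms / 1000.0
            )
            assert m.n_matched == n_opt

    def test_conservation(self, paired_recording):
        m = match_spikes(paired_recording)
        assert m.n_matched + m.n_failures == m.n_soma


class TestFailureRate:
    def test_direct_arithmetic(self):
        soma = np.arange(1, 1001) * 0.02
        pair = make_pair(soma, soma + 0.0002, 25.0)
        assert failure_rate_per_1000(match_spikes(pair)) == 0.0
        pair = make_pair(soma, soma[6:] + 0.0002, 25.0)  # first 6 soma spikes fail
        assert failure_rate_per_1000(match_spikes(pair)) == pytest.approx(6.0)

    def test_recovers_generating_probability(self):
        p = 0.002
        dur = 1.0e5 / 45.2
        cfg = GeneratorConfig(failure_prob=p, duration_s=dur, seed=21)
        rec = gen_paired_recording(gen_soma_train(cfg), cfg)
        rate = failure_rate_per_1000(match_spikes(rec))
        n = rec.soma.n_spikes
        assert abs(rate - 2.0) < 3 * np.sqrt(p * (1 - p) / n) * 1000

    def test_classification(self):
        assert classify_fidelity(6.07) == "low"
        assert classify_fidelity(0.5) == "high"
        assert classify_fidelity(1.0) == "low"  # boundary assigned low
        with pytest.raises(InvalidParameterError):
            classify_fidelity(-0.1)


class TestDelay:
    def test_constant_offsets_recovered_exactly(self):
        soma = np.arange(1, 101) * 0.02
        for offset in (0.00015, -0.0001):
            pair = make_pair(soma, soma + offset, 3.0)
            m = match_spikes(pair)
            assert axosomatic_delay_ms(m) == pytest.approx(offset * 1000, abs=1e-9)

    def test_jittered_delay_clt(self):
        cfg = GeneratorConfig(delay_ms=0.2, delay_jitter_ms=0.05,
                              duration_s=1.0e4 / 45.2, failure_prob=0.0, seed=22)
        rec = gen_paired_recording(gen_soma_train(cfg), cfg)
        m = match_spikes(rec)
        assert m.n_matched >= 9900
        se = 0.05 / np.sqrt(m.n_matched)
        assert abs(axosomatic_delay_ms(m) - 0.2) < 3 * se

    def test_no_matches_raises(self):
        pair = make_pair([0.1, 0.2], [], 1.0)
        with pytest.raises(InsufficientDataError):
            axosomatic_delay_ms(match_spikes(pair))


class TestFiringStats:
    def test_periodic_train(self):
        t = SpikeTrain("c", "soma", np.arange(1, 101) * 0.02, 2.0)
        s = firing_stats(t)
        assert s.rate_hz == pytest.approx(50.0)
        assert s.cv == pytest.approx(0.0, abs=1e-12)
        assert s.cv2 == pytest.approx(0.0, abs=1e-12)

    def test_gamma_cv_law(self):
        cfg = GeneratorConfig(firing_rate_hz=50.0, isi_cv=0.5, duration_s=2000.0, seed=23)
        s = firing_stats(gen_soma_train(cfg))
        n = s.n_spikes - 1
        g1, g2 = 2 / np.sqrt(4), 6 / 4
        se = 0.5 * np.sqrt((0.25 - g1 * 0.5 + (g2 + 2) / 4) / n)
        assert abs(s.cv - 0.5) < 3 * se

    def test_degenerate_two_spike_train(self):
        s = firing_stats(SpikeTrain("c", "soma", np.array([0.1, 0.5]), 1.0))
        assert s.rate_hz == pytest.approx(2.0)
        assert not s.regularity_defined
        assert np.isnan(s.cv) and np.isnan(s.cv2)


class TestNormalizeFrequency:
    def test_identity_and_scaling(self):
        assert np.allclose(normalize_frequency([40.0, 40.0], 40.0), 1.0)
        assert normalize_frequency([10.0], 40.0)[0] == pytest.approx(0.25)
        with pytest.raises(InvalidParameterError):
            normalize_frequency([1.0], 0.0)

    def test_ttx_like_axon_suppression(self):
        # low TTX mimics failures: the axonal rate series drops more than
        # the somatic one; normalisation preserves that ordering pointwise
        cfg0 = GeneratorConfig(duration_s=20.0, failure_prob=0.0, seed=24)
        soma_rates, axon_rates = [], []
        for i, p_fail in enumerate([0.0, 0.4, 0.6, 0.75]):
            cfg = GeneratorConfig(duration_s=20.0, failure_prob=p_fail, seed=24 + i)
            soma = gen_soma_train(cfg)
            rec = gen_paired_recording(soma, cfg)
            soma_rates.append(firing_stats(soma).rate_hz)
            axon_rates.append(rec.axon.n_spikes / cfg.duration_s)
        ns = normalize_frequency(soma_rates, soma_rates[0])
        na = normalize_frequency(axon_rates, axon_rates[0])
        assert np.all(na[1:] < ns[1:])


def _session_from_steps(steps):
    records = []
    for n_soma, n_keep in steps:
        soma_t = np.linspace(0.01, 0.49, n_soma)
        axon_t = soma_t[:n_keep] + 0.0002
        records.append(
            StepRecord(
                amplitude_na=0.1 * (len(records) + 1),
                soma=SpikeTrain("c", "soma", soma_t, 0.5),
                axon=SpikeTrain("c", "axon", axon_t, 0.5),
            )
        )
    return StepSession(cell_id="c", records=tuple(records))


class TestReliabilityCurve:
    def test_all_propagate(self):
        sess = _session_from_steps([(10, 10), (20, 20)])
        curve = reliability_by_frequency(sess)
        occupied = curve.n_spikes_per_bin > 0
        assert np.allclose(curve.success_fraction[occupied], 1.0)

    def test_hand_counted_bin(self):
        # 60-Hz step with 3/30 failures pooled with a 64-Hz step with 0/32
        sess = _session_from_steps([(30, 27), (32, 32)])
        curve = reliability_by_frequency(sess, bin_hz=20.0)
        i = 3  # bin [60, 80)
        assert curve.n_spikes_per_bin[i] == 62
        assert curve.success_fraction[i] == pytest.approx(59 / 62)

    def test_weighted_mean_identity(self):
        sess = _session_from_steps([(30, 27), (32, 32), (75, 60), (10, 10)])
        curve = reliability_by_frequency(sess)
        occ = curve.n_spikes_per_bin > 0
        weighted = np.sum(
            curve.success_fraction[occ] * curve.n_spikes_per_bin[occ]
        ) / np.sum(curve.n_spikes_per_bin)
        assert weighted == pytest.approx(curve.pooled_success, abs=1e-15)

    def test_success_at_max_single_step(self):
        sess = _session_from_steps([(50, 50)])
        f, s = success_at_max_frequency(reliability_by_frequency(sess))
        assert (f, s) == (100.0, 1.0)

    def test_success_at_max_hand_count(self):
        # fastest step: 80 spikes in 0.5 s = 160 Hz, 2 failures
        sess = _session_from_steps([(40, 40), (80, 78)])
        f, s = success_at_max_frequency(reliability_by_frequency(sess))
        assert f == 160.0 and s == pytest.approx(78 / 80)

    def test_tied_max_steps_pooled(self):
        sess = _session_from_steps([(32, 31), (32, 32)])
        f, s = success_at_max_frequency(reliability_by_frequency(sess))
        assert f == 64.0 and s == pytest.approx(63 / 64)

    def test_empty_session_raises(self):
        sess = StepSession(cell_id="c", records=tuple())
        with pytest.raises(InsufficientDataError):
            reliability_by_frequency(sess)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(2, 80), st.floats(0, 1)), min_size=1, max_size=8))
def test_reliability_identity_property(step_spec):
    """Pooled success equals the spike-weighted mean of bin successes."""
    steps = [(n, max(0, min(n, round(frac * n)))) for n, frac in step_spec]
    sess = _session_from_steps(steps)
    curve = reliability_by_frequency(sess)
    occ = curve.n_spikes_per_bin > 0
    weighted = np.sum(curve.success_fraction[occ] * curve.n_spikes_per_bin[occ])
    assert weighted == pytest.approx(curve.pooled_success * curve.n_spikes_per_bin.sum())
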