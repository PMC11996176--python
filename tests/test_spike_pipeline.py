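"""Spike curation chain: drift removal, detection, curation, PC rules."""

import numpy as np
import pandas as pd
import pytest

from cbtdcs.protocol import StimProtocol
from cbtdcs.spike_pipeline import (
    classify_unit,
    cs_ss_pause,
    curate_amplitudes,
    dc_remove,
    detect_spikes,
    refractory_violation_rate,
    select_trials,
)
from cbtdcs.synth.neurons import NeuronSpec, simulate_pc_unit, trial_table_for_protocol
from cbtdcs.synth.traces import default_spike_template, render_extracellular_trace


class TestDcRemove:
    def test_constant_input_decays_to_zero(self):
        fs, tau = 10000.0, 0.0007
        y = dc_remove(np.full(int(fs), 3.0), tau, fs)
        assert abs(y[-1]) < 1e-6

    def test_step_response_matches_recursion_oracle(self):
        fs, tau = 5000.0, 0.001
        x = np.r_[np.zeros(100), np.ones(400)]
        y = dc_remove(x, tau, fs)
        # brute-force EMA recursion
        a = np.exp(-1.0 / (tau * fs))
        m, expect = 0.0, []
        for xi in x:
            m = a * m + (1 - a) * xi
            expect.append(xi - m)
        assert np.allclose(y, expect, atol=1e-12)
        # decay time constant: y at n samples past the step is exp(-(n+1)/(tau fs))
        n = int(round(tau * fs)) - 1
        assert np.isclose(y[100 + n], np.exp(-1.0), atol=1e-9)

    def test_high_frequency_passband(self):
        fs, tau = 25000.0, 0.0007  # cutoff ~230 Hz
        t = np.arange(int(fs * 0.1)) / fs
        x = np.sin(2 * np.pi * 5000.0 * t)
        y = dc_remove(x, tau, fs)
        assert np.corrcoef(x[500:], y[500:])[0, 1] > 0.99

    def test_invalid_time_constant(self):
        for tau in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                dc_remove(np.zeros(10), tau, 1000.0)


class TestDetectSpikes:
    def test_pure_noise_false_positive_rate(self):
        """Threshold at 4 robust SD: the false-positive event rate on white
        noise stays within 3x the Gaussian tail prediction (documented
        approximation: excursions cluster into events)."""
        fs = 25000.0
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 10.0, int(fs * 4))
        det, _ = detect_spikes(x, k_sd=4.0, sample_rate_hz=fs, refractory_ms=1.5)
        p_tail = 2 * 6.33e-5  # P(|z| > 4)
        expected_events = p_tail * len(x)
        assert len(det) < 3 * expected_events + 5

    def test_isolated_template_recovered_once(self):
        fs = 25000.0
        out = render_extracellular_trace(
            [(np.array([0.05]), np.array([120.0]))],
            noise_sd=20.0,
            sample_rate_hz=fs,
            duration_s=0.2,
            seed=3,
        )
        det, amps = detect_spikes(out["trace_uV"], k_sd=4.0, sample_rate_hz=fs)
        assert len(det) == 1
        assert abs(det[0] - 0.05) <= 0.5e-3
        assert amps[0] > 80.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([]))


class TestCurateAmplitudes:
    def test_constant_amplitudes_all_kept(self):
        keep, periods = curate_amplitudes(np.arange(100.0), np.full(100, 200.0))
        assert keep.all()
        assert len(periods) == 1

    def test_double_amplitude_outlier_dropped(self):
        amps = np.full(50, 200.0)
        amps[25] = 400.0
        keep, _ = curate_amplitudes(np.arange(50.0) * 0.1, amps)
        assert not keep[25]
        assert keep.sum() == 49

    def test_step_change_splits_stable_periods(self):
        """A mid-session 50% amplitude step yields two stable periods and
        the kept set equals a brute-force application of the 1/3 rule
        within each period."""
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0, 240.0, 2000))
        amps = np.where(times < 120.0, 300.0, 150.0) * (
            1 + 0.05 * rng.standard_normal(2000)
        )
        keep, periods = curate_amplitudes(times, amps, window_s=60.0)
        assert len(periods) == 2
        # brute force: same boundary, same rule
        boundary = periods[1][0]
        expect = np.zeros(2000, dtype=bool)
        for sel in (times < boundary, times >= boundary):
            mean = amps[sel].mean()
            expect[sel] = np.abs(amps[sel] - mean) <= mean / 3.0
        assert np.array_equal(keep, expect)

    def test_invariant_to_uniform_rescaling(self, rng):
        times = np.sort(rng.uniform(0, 300.0, 500))
        amps = 250.0 * (1 + 0.2 * rng.standard_normal(500))
        keep1, _ = curate_amplitudes(times, amps)
        keep2, _ = curate_amplitudes(times, amps * 7.3)
        assert np.array_equal(keep1, keep2)


class TestRefractoryViolations:
    def test_regular_train_clean(self):
        frac, ok = refractory_violation_rate(np.arange(0, 1, 0.01))
        assert frac == 0.0 and ok

    def test_single_duplicate_counted(self):
        t = np.sort(np.r_[np.arange(100) * 0.01, [0.0105]])
        frac, ok = refractory_violation_rate(t, t_ref_ms=1.5)
        assert np.isclose(frac, 1 / 100)  # 101 spikes -> 100 ISIs, one short
        assert ok  # exactly at the 1% contamination ceiling
        frac2, ok2 = refractory_violation_rate(t, t_ref_ms=1.5, max_frac=0.005)
        assert frac2 == frac and not ok2

    def test_poisson_rate_matches_analytic_probability(self, rng):
        t = np.cumsum(rng.exponential(1 / 60.0, 30000))
        frac, _ = refractory_violation_rate(t, t_ref_ms=1.5)
        p = 1 - np.exp(-60.0 * 0.0015)
        sem = np.sqrt(p * (1 - p) / 30000)
        assert abs(frac - p) < 3 * sem


class TestCsSsPause:
    def test_constructed_pause_measured_exactly(self):
        ss = np.arange(0.0, 10.0, 0.005)
        cs = np.arange(0.5, 9.5, 1.0)
        keep = np.ones(len(ss), dtype=bool)
        for c in cs:
            keep &= ~((ss >= c) & (ss < c + 0.020))
        pause, flag = cs_ss_pause(ss[keep], cs)
        assert np.isclose(pause, 20.0, atol=2.5)  # grid quantization
        assert flag

    def test_independent_trains_fail(self, rng):
        ss = np.cumsum(rng.exponential(1 / 100.0, 5000))
        cs = np.sort(rng.uniform(0, ss[-1], 40))
        pause, flag = cs_ss_pause(ss, cs)
        assert not flag
        assert pause < 10.0  # expected latency 1/rate = 10 ms, median below

    def test_generator_pc_passes(self, pc_unit_fixture):
        pause, flag = cs_ss_pause(
            pc_unit_fixture["ss_times"], pc_unit_fixture["cs_times"]
        )
        assert flag
        assert 10.0 <= pause <= 40.0

    def test_empty_cs_train(self):
        pause, flag = cs_ss_pause(np.arange(10.0), np.array([]))
        assert pause is None and not flag


class TestClassifyUnit:
    @pytest.mark.parametrize(
        "ss,cs,pause,expect",
        [
            (60.0, 1.0, True, "PC"),
            (20.0, 0.0, False, "nonPC"),
            (60.0, 5.0, True, "rejected"),
            (40.0, 1.0, True, "rejected"),
            (60.0, 1.0, False, "rejected"),
        ],
    )
    def test_rate_bands_and_pause(self, ss, cs, pause, expect):
        assert classify_unit(ss, cs, pause) == expect

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            classify_unit(-1.0, 0.0, False)


class TestSelectTrials:
    @staticmethod
    def _trials(n=5):
        return trial_table_for_protocol(StimProtocol(n_trials=n))

    def test_clean_trials_all_kept(self):
        kept, included = select_trials(self._trials(), [], min_trials=3)
        assert len(kept) == 5 and included

    def test_running_trials_break_inclusion(self):
        trials = self._trials()
        trials.loc[[0, 1, 2], "running"] = 1
        kept, included = select_trials(trials, [], min_trials=3)
        assert len(kept) == 2 and not included

    def test_millisecond_overlap_drops_trial(self):
        trials = self._trials()
        t0 = float(trials["t_ramp_in_s"].iloc[0])
        kept, _ = select_trials(trials, [(t0 - 1.0, t0 + 0.001)], min_trials=1)
        assert len(kept) == 4

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_trials(pd.DataFrame(columns=["t_end_s"]), [])


def test_detection_classification_agrees_with_event_table():
    """Detecting SS from a rendered trace and classifying from the event
    table give the same PC identification for a generator unit."""
    proto = StimProtocol(n_trials=3)
    spec = NeuronSpec(unit_id="pc", theta_deg=90.0)
    res = simulate_pc_unit(spec, proto, seed=17)
    fs = 25000.0
    dur = res["duration_s"]
    out = render_extracellular_trace(
    [
            (res["ss_times"], np.full(len(res["ss_times"]), 150.0)),
            (res["cs_times"], np.full(len(res["cs_times"]), 300.0)),
        ],
        noise_sd=25.0,
        sample_rate_hz=fs,
        duration_s=dur,
        seed=18,
    )
    det, amps = detect_spikes(out["trace_uV"], sample_rate_hz=fs)
    # crude kind split by amplitude (CS templates are larger)
    cs_det = det[amps > 225.0]
    ss_det = det[amps <= 225.0]
    span = det[-1] - det[0]
    pause, flag = cs_ss_pause(ss_det, cs_det)
    detected_class = classify_unit(len(ss_det) / span, len(cs_det) / span, flag)

    pause_e, flag_e = cs_ss_pause(res["ss_times"], res["cs_times"])
    span_e = res["ss_times"][-1] - res["ss_times"][0]
    event_class = classify_unit(
        len(res["ss_times"]) / span_e, len(res["cs_times"]) / span_e, flag_e
    )
    assert detected_class == event_class == "PC"
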