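"""Modulation quantification: windows, PSTH, z-scores, percent change."""

import numpy as np
import pandas as pd
import pytest

from cbtdcs.modulation import (
    analyze_unit_condition,
    build_psth,
    compare_windows,
    folded_modulation,
    normalized_modulation,
    population_scatter_fit,
    region_modulation_compare,
    trial_windows,
    window_rates,
    zscore_psth,
)
from cbtdcs.protocol import StimProtocol
from cbtdcs.synth.neurons import (
    NeuronSpec,
    plateau_modulation,
    simulate_unit_on_trials,
    trial_table_for_protocol,
)


def _trial_row(t_in=100.0, ramp=5.0, plateau=10.0):
    return pd.Series(
        {
            "t_ramp_in_s": t_in,
            "t_plateau_s": t_in + ramp,
            "t_ramp_out_s": t_in + ramp + plateau,
            "t_end_s": t_in + 2 * ramp + plateau,
        }
    )


class TestTrialWindows:
    def test_twenty_second_pulse_layout(self):
        w = trial_windows(_trial_row(100.0, 5.0, 10.0))
        assert w.during == (105.0, 110.0)
        assert w.before == (95.0, 100.0)
        assert w.after == (120.0, 125.0)

    def test_windows_disjoint_and_five_seconds(self):
        w = trial_windows(_trial_row(50.0, 5.0, 5.0))
        spans = w.as_list()
        assert all(np.isclose(hi - lo, 5.0) for lo, hi in spans)
        for (l1, h1), (l2, h2) in zip(spans[:-1], spans[1:]):
            assert h1 <= l2

    def test_short_plateau_rejected(self):
        with pytest.raises(ValueError):
            trial_windows(_trial_row(0.0, 5.0, 3.0))


class TestPsth:
    def test_deterministic_train_exact_rate(self):
        times = 0.05 + np.arange(2000) / 10.0  # 10 Hz clock, off bin edges
        aligns = np.array([50.0, 100.0])
        bins, rate = build_psth(times, aligns, bin_s=0.5, range_s=(-5.0, 5.0))
        assert np.allclose(rate, 10.0)
        assert bins[0] == -5.0 and len(bins) == 20

    def test_empty_train_zero_psth(self):
        _, rate = build_psth(np.array([]), np.array([10.0]), 0.1, (-5.0, 25.0))
        assert np.all(rate == 0.0)

    def test_matches_brute_force_histogram(self, rng):
        times = np.sort(rng.uniform(0, 300, 4000))
        aligns = np.array([60.0, 120.0, 180.0])
        bin_s, rng_s = 0.1, (-5.0, 20.0)
        bins, rate = build_psth(times, aligns, bin_s, rng_s)
        nb = len(bins)
        counts = np.zeros(nb)
        for a in aligns:
            for t in times:
                rel = t - a
                if rng_s[0] <= rel < rng_s[1]:
                    j = int((rel - rng_s[0]) / bin_s)
                    if j == nb:  # float edge
                        j -= 1
                    counts[j] += 1
        assert np.allclose(rate, counts / (len(aligns) * bin_s), atol=1e-9)

    def test_no_alignment_events_rejected(self):
        with pytest.raises(ValueError):
            build_psth(np.arange(10.0), np.array([]), 0.1, (-5.0, 5.0))


class TestZscore:
    def test_baseline_standardized(self, rng):
        psth = rng.uniform(20, 80, 300)
        base = np.arange(50)
        z, flag = zscore_psth(psth, base)
        assert not flag
        assert np.isclose(z[base].mean(), 0.0, atol=1e-12)
        assert np.isclose(z[base].std(ddof=1), 1.0, atol=1e-12)

    def test_hand_computed_fixture(self):
        psth = np.array([10.0, 12.0, 14.0, 20.0])
        z, _ = zscore_psth(psth, np.array([0, 1, 2]))
        mu, sd = 12.0, 2.0
        assert np.allclose(z, (psth - mu) / sd, atol=1e-12)

    def test_constant_baseline_flagged(self):
        z, flag = zscore_psth(np.full(10, 7.0), np.arange(5))
        assert flag and np.all(np.isnan(z))


class TestWindowRates:
    def test_counts_over_five_seconds(self):
        w = trial_windows(_trial_row(100.0))
        times = np.linspace(105.0, 110.0, 50, endpoint=False)
        rates = window_rates(times, [w])
        assert np.allclose(rates[0], [0.0, 10.0, 0.0])

    def test_generator_gain_recovered(self):
        """Mean during/before rate ratio matches the generator's plateau
        gain within 3 SEM."""
        proto = StimProtocol(polarity=1, n_trials=60)
        trials = trial_table_for_protocol(proto)
        spec = NeuronSpec(unit_id="x", theta_deg=0.0, depth_mm=1.0,
                          rebound_gain=0.0)
        m = plateau_modulation(spec, 1, 200.0)
        res = simulate_unit_on_trials(spec, trials, np.full(60, m), seed_or_rng=2)
        wins = [trial_windows(r) for _, r in trials.iterrows()]
        rates = window_rates(res["ss_times"], wins)
        ratio = rates[:, 1].mean() / rates[:, 0].mean()
        sem = ratio * np.sqrt(1 / rates[:, 1].sum() / 5 + 1 / rates[:, 0].sum() / 5)
        assert abs(ratio - (1 + m)) < 3 * max(sem, 0.01)


class TestCompareWindows:
    def test_identical_columns_friedman_null(self):
        out = compare_windows(np.ones((10, 3)) * 4.0)
        assert out["test_name"] == "Friedman"
        assert out["statistic"] == 0.0 and out["p"] == 1.0
        assert not out["significant"]

    def test_normal_data_routes_to_rm_anova(self, rng):
        m = rng.normal(50, 3, (30, 3))
        out = compare_windows(m)
        assert out["test_name"] == "RM-ANOVA"

    def test_skewed_data_routes_to_friedman(self, rng):
        m = rng.exponential(1.0, (40, 3)) ** 3
        out = compare_windows(m)
        assert out["test_name"] == "Friedman"

    def test_strong_effect_detected(self, rng):
        m = rng.normal(50, 3, (20, 3))
        m[:, 1] += 20.0
        out = compare_windows(m)
        assert out["significant"]
        assert len(out["posthoc"]) == 3

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            compare_windows(np.ones((2, 3)))


class TestNormalizedModulation:
    @pytest.mark.parametrize(
        "before,during,percent,folded",
        [(50.0, 75.0, 150.0, 50.0), (50.0, 50.0, 100.0, 0.0), (50.0, 25.0, 50.0, 50.0)],
    )
    def test_worked_rule(self, before, during, percent, folded):
        p = normalized_modulation(before, during)
        assert np.isclose(p, percent)
        assert np.isclose(folded_modulation(p), folded)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalized_modulation(0.0, 10.0)


class TestPopulationScatter:
    def test_anticorrelated_population(self):
        thetas = np.array([0.0, 180.0] * 8)
        anodal = 100 + 40 * np.cos(np.deg2rad(thetas))
        cathodal = 100 - 40 * np.cos(np.deg2rad(thetas))
        slope, _, r, p = population_scatter_fit(anodal, cathodal)
        assert slope < 0
        assert np.isclose(abs(r), 1.0)
        assert p < 1e-6

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(50, 150, 40)
        y = 0.7 * x + rng.normal(0, 5, 40)
        slope, intercept, r, _ = population_scatter_fit(x, y)
        # closed-form normal equations
        sb = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        ib = y.mean() - sb * x.mean()
        assert np.isclose(slope, sb, atol=1e-10)
        assert np.isclose(intercept, ib, atol=1e-10)
        assert np.isclose(r, np.corrcoef(x, y)[0, 1], atol=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            population_scatter_fit(np.full(5, 1.0), np.arange(5.0))


class TestRegionComparison:
    def test_identical_groups(self):
        u, p = region_modulation_compare(np.arange(6.0), np.arange(6.0))
        assert p > 0.9

    def test_aligned_vs_oblique_population(self, rng):
        """Folded modulations of field-aligned (vermis-like) units are
        clearly larger than oblique (crus-like) units under the default
        cosine law with measurement noise."""
        e = 46.0  # V/m at 1 mm, 200 uA
        verm = np.abs(0.01 * e * np.cos(np.deg2rad(rng.normal(0, 15, 20)))) * 100
        crus = np.abs(0.01 * e * np.cos(np.deg2rad(90 + rng.normal(0, 15, 20)))) * 100
        verm += rng.normal(0, 2, 20)
        crus += rng.normal(0, 2, 20)
        _, p = region_modulation_compare(np.abs(verm), np.abs(crus))
        assert p < 0.001


def test_analyze_unit_condition_end_to_end():
    proto = StimProtocol(polarity=1, n_trials=8)
    trials = trial_table_for_protocol(proto)
    spec = NeuronSpec(unit_id="u1", theta_deg=0.0, depth_mm=0.5)
    m = plateau_modulation(spec, 1, 200.0)
    res = simulate_unit_on_trials(spec, trials, np.full(8, m), seed_or_rng=3)
    out = analyze_unit_condition(res["ss_times"], trials, "u1")
    assert out.significant
    assert out.mod_percent > 120.0
    base = out.psth_bin_start_s < 0
    assert np.isclose(np.nanmean(out.z_psth[base]), 0.0, atol=1e-9)
    assert np.isclose(np.nanstd(out.z_psth[base], ddof=1), 1.0, atol=1e-9)
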