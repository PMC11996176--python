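"""Per-unit firing-rate modulation around tDCS pulses.

Each trial contributes three half-open 5 s windows: before (ending at
ramp-in), during (starting when the ramp reaches peak intensity) and
after (starting at ramp-out end).  Window rates feed the per-unit omnibus
test (RM-ANOVA or Friedman, gated by Shapiro-Wilk normality); the
trial-averaged PSTH is standardized against the baseline window
(Z = (X - mu) / sigma); and modulation is summarized as the during/before
rate as a percent (100 = no change), optionally folded to its absolute
deviation from 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from cbtdcs import stats as cbstats

__all__ = [
    "TrialWindows",
    "ModulationResult",
    "trial_windows",
    "build_psth",
    "zscore_psth",
    "window_rates",
    "compare_windows",
    "normalized_modulation",
    "folded_modulation",
    "population_scatter_fit",
    "region_modulation_compare",
]

WINDOW_S = 5.0


@dataclass(frozen=True)
class TrialWindows:
    """The three half-open 5 s analysis windows of one trial."""

    before: tuple[float, float]
    during: tuple[float, float]
    after: tuple[float, float]

    def as_list(self) -> list[tuple[float, float]]:
        return [self.before, self.during, self.after]


@dataclass
class ModulationResult:
    """Per-unit, per-polarity modulation summary."""

    unit_id: str
    polarity: str
    intensity_uA: float
    rates: np.ndarray  # trials x {before, during, after}
    test_name: str
    statistic: float
    df: tuple[int, ...]
    p: float
    posthoc: pd.DataFrame
    significant: bool
    mod_percent: float | None
    folded_percent: float | None
    sigma_zero: bool = False
    psth_bin_start_s: np.ndarray | None = None
    z_psth: np.ndarray | None = None


def trial_windows(trial) -> TrialWindows:
    """Analysis windows for one trial row (needs ramp/plateau/end times).

    For 15 s pulses (5 s plateau) the during window equals the plateau;
    the after window starts at ramp-out end.
    """
    t_in = float(trial["t_ramp_in_s"])
    t_plateau = float(trial["t_plateau_s"])
    t_out = float(trial["t_ramp_out_s"])
    t_end = float(trial["t_end_s"])
    if t_out - t_plateau < WINDOW_S:
        raise ValueError("plateau shorter than the 5 s analysis window")
    return TrialWindows(
        before=(t_in - WINDOW_S, t_in),
        during=(t_plateau, t_plateau + WINDOW_S),
        after=(t_end, t_end + WINDOW_S),
    )


def build_psth(
    times_s: np.ndarray,
    align_times_s: np.ndarray,
    bin_s: float = 0.1,
    range_s: tuple[float, float] = (-5.0, 25.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged peristimulus rate histogram.

    Spike counts are histogrammed per trial relative to each alignment
    event, converted to Hz and averaged over trials (averaging precedes
    any z-transform).  ``bin_s`` must divide the range.

    Returns (bin_start_s, rate_hz).
    """
    align = np.asarray(align_times_s, dtype=float)
    if len(align) == 0:
        raise ValueError("no alignment events")
    t0, t1 = range_s
    n_bins = (t1 - t0) / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_s must divide the PSTH range")
    n_bins = int(round(n_bins))
    edges = t0 + bin_s * np.arange(n_bins + 1)
    times = np.sort(np.asarray(times_s, dtype=float))
    counts = np.zeros(n_bins)
    for a in align:
        counts += np.histogram(times - a, bins=edges)[0]
    return edges[:-1], counts / (len(align) * bin_s)


def zscore_psth(
    psth_rate_hz: np.ndarray, baseline_bins: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Standardize a PSTH against its baseline bins.

    z_i = (X_i - mu) / sigma with mu and sigma (sample SD, ddof=1) taken
    from the baseline (pre-ramp-in) bins.  A silent/constant baseline has
    sigma 0: the z-PSTH is undefined (all-NaN) and flagged.

    Returns (z, sigma_zero).
    """
    x = np.asarray(psth_rate_hz, dtype=float)
    base = x[baseline_bins]
    if len(base) < 2:
        raise ValueError("need >= 2 baseline bins")
    mu = base.mean()
    sigma = base.std(ddof=1)
    if sigma == 0:
        return np.full_like(x, np.nan), True
    return (x - mu) / sigma, False


def window_rates(times_s: np.ndarray, windows: list[TrialWindows]) -> np.ndarray:
    """Spike rate (Hz) per trial per window: count / 5 s.

    Returns a len(windows) x 3 matrix ordered before, during, after.
    """
    if len(windows) == 0:
        raise ValueError("need at least one trial window")
    times = np.sort(np.asarray(times_s, dtype=float))
    out = np.empty((len(windows), 3))
    for i, w in enumerate(windows):
        for j, (lo, hi) in enumerate(w.as_list()):
            a, b = np.searchsorted(times, [lo, hi])
            out[i, j] = (b - a) / (hi - lo)
    return out


def compare_windows(rates: np.ndarray, alpha: float = 0.05):
    """Omnibus comparison of before/during/after rates across trials.

    Shapiro-Wilk is applied per condition column: if all pass (p > 0.05)
    a repeated-measures ANOVA with Tukey pairwise comparisons is run,
    otherwise the Friedman test with Nemenyi pairwise comparisons.

    Returns a dict with test_name, statistic, df, p, posthoc, significant.
    """
    m = np.asarray(rates, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("rates must be a trials x conditions matrix")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    if cbstats.shapiro_all_normal(m, alpha=alpha):
        f, df1, df2, p = cbstats.rm_anova(m)
        posthoc = cbstats.tukey_pairwise(m)
        name, stat, df = "RM-ANOVA", f, (df1, df2)
    else:
        chi2, df1, p = cbstats.friedman(m)
        posthoc = cbstats.nemenyi_pairwise(m)
        name, stat, df = "Friedman", chi2, (df1,)
    if not np.isfinite(p):  # fully degenerate ranks
        p = 1.0
    return {
        "test_name": name,
        "statistic": float(stat),
        "df": df,
        "p": float(p),
        "posthoc": posthoc,
        "significant": bool(p < alpha),
    }


def normalized_modulation(before_hz: float, during_hz: float) -> float:
    """Firing rate during stimulation as a percent of baseline.

    100 means no change; a rate increase of 50% gives 150, a decrease of
    50% gives 50.  Undefined (raises) for a silent baseline.
    """
    if before_hz <= 0:
        raise ValueError("baseline rate must be positive for normalization")
    return 100.0 * during_hz / before_hz


def folded_modulation(percent: float) -> float:
    """Absolute deviation of the normalized modulation from 100%."""
    return abs(percent - 100.0)


def population_scatter_fit(
    anodal_mod: np.ndarray, cathodal_mod: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS fit of cathodal vs anodal modulation across units.

    Returns (slope, intercept, R, p) with R the signed Pearson
    correlation and p its two-sided significance.
    """
    x = np.asarray(anodal_mod, dtype=float)
    y = np.asarray(cathodal_mod, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 units with both polarities")
    if np.ptp(x) == 0:
        raise ValueError("anodal modulations are identical: slope undefined")
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )


def region_modulation_compare(
    folded_a: np.ndarray, folded_b: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U comparison of folded modulations between regions.

    Exact by enumeration for combined n <= 20, tie-corrected normal
    approximation otherwise.  Returns (U, p).
    """
    return cbstats.mann_whitney_u(np.asarray(folded_a), np.asarray(folded_b))


def analyze_unit_condition(
    times_s: np.ndarray,
    trials: pd.DataFrame,
    unit_id: str,
    alpha: float = 0.05,
    bin_s: float = 0.1,
) -> ModulationResult:
    """Full modulation analysis of one unit under one (polarity, intensity).

    ``trials`` must already be restricted to the kept trials of a single
    polarity and intensity.
    """
    wins = [trial_windows(row) for _, row in trials.iterrows()]
    rates = window_rates(times_s, wins)
    test = compare_windows(rates, alpha=alpha)
    before, during = rates[:, 0].mean(), rates[:, 1].mean()
    if before > 0:
        mod = normalized_modulation(before, during)
        folded = folded_modulation(mod)
    else:
        mod = folded = None
    pulse_s = float(trials["t_end_s"].iloc[0] - trials["t_ramp_in_s"].iloc[0])
    bins, psth = build_psth(
        times_s,
        trials["t_ramp_in_s"].to_numpy(dtype=float),
        bin_s=bin_s,
        range_s=(-WINDOW_S, pulse_s + WINDOW_S),
    )
    z, sigma_zero = zscore_psth(psth, bins < 0)
    return ModulationResult(
        unit_id=unit_id,
        polarity=str(trials["polarity"].iloc[0]),
        intensity_uA=float(trials["intensity_uA"].iloc[0]),
        rates=rates,
        test_name=test["test_name"],
        statistic=test["statistic"],
        df=test["df"],
        p=test["p"],
        posthoc=test["posthoc"],
        significant=test["significant"],
        mod_percent=mod,
        folded_percent=folded,
        sigma_zero=sigma_zero,
        psth_bin_start_s=bins,
        z_psth=z,
    )
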