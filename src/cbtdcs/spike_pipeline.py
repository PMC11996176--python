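"""Spike detection, curation and Purkinje-cell identification.

Mirrors the experimental curation chain: DC drift removal, threshold
crossing at a multiple of the robust noise SD, template-amplitude
stability curation (events deviating more than a third from the local
mean amplitude are dropped), autocorrelogram refractory check, and PC
identification from the CS-triggered SS pause plus the rate bands
(<3 Hz CS, >50 Hz SS).  Trials contaminated by locomotion are excluded
and a unit enters the analysis only with at least three clean trials per
(intensity, polarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "UnitRecord",
    "dc_remove",
    "detect_spikes",
    "curate_amplitudes",
    "refractory_violation_rate",
    "cs_ss_pause",
    "classify_unit",
    "select_trials",
    "classify_session",
]

PAUSE_BAND_MS = (10.0, 40.0)
CS_RATE_MAX_HZ = 3.0
SS_RATE_MIN_HZ = 50.0


@dataclass
class UnitRecord:
    """Classification summary of one unit."""

    unit_id: str
    cell_class: str  # {"PC", "nonPC", "rejected"}
    ss_rate_hz: float
    cs_rate_hz: float
    pause_ms: float | None
    pause_flag: bool
    refractory_violation_frac: float
    included: bool = True


def dc_remove(
    trace: np.ndarray, time_constant_s: float, sample_rate_hz: float
) -> np.ndarray:
    """Subtract an exponential moving average (single-pole high-pass).

    The running mean m follows m[i] = a m[i-1] + (1-a) x[i] with
    a = exp(-1 / (tau fs)); the output is x - m, which decays to zero on
    constant input and passes frequencies well above 1/(2 pi tau).
    """
    if not 0.0 < time_constant_s < 1.0:
        raise ValueError("time_constant_s must be in (0, 1)")
    x = np.asarray(trace, dtype=float)
    a = np.exp(-1.0 / (time_constant_s * sample_rate_hz))
    # y = x - m where m = (1-a) x / (1 - a z^-1)
    m = signal.lfilter([1.0 - a], [1.0, -a], x)
    return x - m


def robust_sd(x: np.ndarray) -> float:
    """Noise SD estimate from the scaled median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_spikes(
    trace: np.ndarray,
    k_sd: float = 4.0,
    sample_rate_hz: float = 25000.0,
    refractory_ms: float = 1.5,
    use_robust_sd: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-crossing spike detection on a continuous trace.

    The threshold is ``k_sd`` times the robust (MAD-scaled) noise SD;
    events are the local extrema of supra-threshold excursions of |x|,
    with a dead time of ``refractory_ms`` after each accepted event.

    Returns (times_s, amplitudes) with amplitudes the unsigned extremum
    voltage in the trace's units.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) == 0:
        raise ValueError("empty trace")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    sd = robust_sd(x) if use_robust_sd else float(np.std(x))
    thr = k_sd * sd
    absx = np.abs(x)
    above = absx > thr
    if not np.any(above):
        return np.empty(0), np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]
    peak_idx = np.array(
        [s + np.argmax(absx[s:e]) for s, e in zip(starts, ends)], dtype=int
    )
    times = peak_idx / sample_rate_hz
    keep_times = _dead_time_mask(times, refractory_ms / 1000.0)
    return times[keep_times], absx[peak_idx[keep_times]]


def _dead_time_mask(times: np.ndarray, t_ref_s: float) -> np.ndarray:
    keep = np.zeros(len(times), dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= t_ref_s:
            keep[i] = True
            last = t
    return keep


def curate_amplitudes(
    times: np.ndarray,
    amplitudes: np.ndarray,
    window_s: float = 60.0,
    drift_threshold: float = 0.15,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Template-amplitude curation.

    The recording is cut into stable periods wherever the sliding-window
    mean amplitude drifts by more than ``drift_threshold`` (fractionally)
    between consecutive windows; within each stable period, events whose
    amplitude deviates from the period mean by more than a third of that
    mean are dropped.  Invariant to uniform amplitude rescaling.

    Returns (keep_mask, stable_periods) with half-open period intervals
    in seconds.
    """
    times = np.asarray(times, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if len(times) == 0:
        raise ValueError("need at least one event")
    if len(times) != len(amps):
        raise ValueError("times and amplitudes must match")

    # window means on a fixed time grid
    t_end = times[-1] + 1e-9
    n_win = max(int(np.ceil(t_end / window_s)), 1)
    win_of = np.minimum((times / window_s).astype(int), n_win - 1)
    means = np.full(n_win, np.nan)
    for w in range(n_win):
        sel = win_of == w
        if np.any(sel):
            means[w] = amps[sel].mean()
    # break between consecutive populated windows with fractional drift
    boundaries = [0.0]
    prev = None
    for w in range(n_win):
        if np.isnan(means[w]):
            continue
        if prev is not None and abs(means[w] - prev) > drift_threshold * prev:
            boundaries.append(w * window_s)
        prev = means[w]
    boundaries.append(np.inf)

    keep = np.zeros(len(times), dtype=bool)
    periods = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        sel = (times >= lo) & (times < hi)
        if not np.any(sel):
            continue
        periods.append((lo, float(times[sel].max()) if np.isinf(hi) else hi))
        mean_amp = amps[sel].mean()
        keep[sel] = np.abs(amps[sel] - mean_amp) <= mean_amp / 3.0
    return keep, periods


def refractory_violation_rate(
    times: np.ndarray, t_ref_ms: float = 1.5, max_frac: float = 0.01
) -> tuple[float, bool]:
    """Fraction of inter-spike intervals shorter than the refractory period.

    Returns (fraction, pass_flag); fewer than two spikes give (0, True).
    """
    if t_ref_ms <= 0:
        raise ValueError("t_ref_ms must be positive")
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        return 0.0, True
    isi = np.diff(times)
    frac = float(np.mean(isi < t_ref_ms / 1000.0))
    return frac, frac <= max_frac


def cs_ss_pause(
    ss_times: np.ndarray,
    cs_times: np.ndarray,
    max_lag_ms: float = 100.0,
    floor_frac: float = 0.5,
) -> tuple[float | None, bool]:
    """CS-triggered SS pause statistic.

    The pause is the median latency from each CS to the next SS.  The PC
    flag requires the pause to fall in the 10-40 ms acceptance band and
    the CS->SS cross-correlogram rate over the first 10 ms after a CS
    (the band minimum, where a genuine pause implies silence) to stay
    below ``floor_frac`` times the unit's overall SS rate -- a numeric
    stand-in for visual correlogram inspection.

    Returns (pause_ms, flag); an empty CS train gives (None, False).
    """
    ss = np.sort(np.asarray(ss_times, dtype=float))
    cs = np.sort(np.asarray(cs_times, dtype=float))
    if len(cs) == 0 or len(ss) == 0:
        return None, False
    nxt = np.searchsorted(ss, cs, side="right")
    valid = nxt < len(ss)
    if not np.any(valid):
        return None, False
    lat = ss[nxt[valid]] - cs[valid]
    lat = lat[lat <= max_lag_ms / 1000.0]
    if len(lat) == 0:
        return None, False
    pause_ms = float(np.median(lat) * 1000.0)

    lo, hi = PAUSE_BAND_MS
    in_band = lo <= pause_ms <= hi
    # correlogram floor: SS rate within [0, 10 ms) after CS vs overall rate
    win_s = lo / 1000.0
    count = 0
    for c in cs:
        a, b = np.searchsorted(ss, [c, c + win_s])
        count += b - a
    ccg_rate = count / (len(cs) * win_s)
    span = ss[-1] - ss[0]
    overall = len(ss) / span if span > 0 else np.inf
    flag = bool(in_band and ccg_rate < floor_frac * overall)
    return pause_ms, flag


def classify_unit(ss_rate_hz: float, cs_rate_hz: float, pause_flag: bool) -> str:
    """PC / nonPC / rejected classification from rates and the pause flag.

    PC: CS present below 3 Hz, SS above 50 Hz, pause flag true.
    nonPC: no CS detected.  rejected: CS present but criteria fail.
    """
    if ss_rate_hz < 0 or cs_rate_hz < 0:
        raise ValueError("rates must be nonnegative")
    if cs_rate_hz == 0:
        return "nonPC"
    if cs_rate_hz < CS_RATE_MAX_HZ and ss_rate_hz > SS_RATE_MIN_HZ and pause_flag:
        return "PC"
    return "rejected"


def select_trials(
    trials: pd.DataFrame,
    locomotion: list[tuple[float, float]] | None = None,
    min_trials: int = 3,
    max_duration_s: float = 3600.0,
) -> tuple[pd.DataFrame, bool]:
    """Drop running/late trials and apply the minimum-trial inclusion rule.

    A trial is dropped if its pulse overlaps any locomotion interval
    (any overlap, half-open intervals), if its own ``running`` flag is
    set, or if it ends after the 1 hr recording cap.  The unit is
    included only if every (intensity, polarity) group retains at least
    ``min_trials`` trials.

    Returns (kept_trials, included).
    """
    if min_trials < 1:
        raise ValueError("min_trials must be >= 1")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    keep = trials["t_end_s"].to_numpy() <= max_duration_s
    if "running" in trials.columns:
        keep &= trials["running"].to_numpy() == 0
    if locomotion:
        t0 = trials["t_ramp_in_s"].to_numpy()
        t1 = trials["t_end_s"].to_numpy()
        for lo, hi in locomotion:
            keep &= ~((t0 < hi) & (lo < t1))
    kept = trials.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        return kept, False
    counts = kept.groupby(["intensity_uA", "polarity"]).size()
    # every condition present in the original design must retain min_trials
    design = trials.groupby(["intensity_uA", "polarity"]).size()
    included = all(counts.get(cond, 0) >= min_trials for cond in design.index)
    return kept, included


def _baseline_rate(
    times: np.ndarray, pulses: list[tuple[float, float]], span: float
) -> float:
    """Firing rate (Hz) over the non-stimulation epochs of the recording."""
    if not np.isfinite(span) or span <= 0 or len(times) == 0:
        return 0.0
    t0, t1 = times[0], times[-1]
    in_pulse = np.zeros(len(times), dtype=bool)
    pulse_time = 0.0
    for lo, hi in pulses:
        lo_c, hi_c = max(lo, t0), min(hi, t1)
        if hi_c > lo_c:
            pulse_time += hi_c - lo_c
            in_pulse |= (times >= lo) & (times < hi)
    rest = span - pulse_time
    if rest <= 0:
        return len(times) / span
    return float(np.sum(~in_pulse) / rest)


def classify_session(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    locomotion: list[tuple[float, float]] | None = None,
    min_trials: int = 3,
    refractory_ms: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every unit of a session from its event table.

    Rates are computed over the recorded span; the CS->SS pause statistic
    drives PC identification.  Returns (units_classified, kept_trials).
    """
    kept, included = select_trials(trials, locomotion, min_trials)
    pulses = list(
        zip(
            trials["t_ramp_in_s"].to_numpy(dtype=float),
            trials["t_end_s"].to_numpy(dtype=float),
        )
    )
    records = []
    for unit_id, df in spikes.groupby("unit_id", sort=True):
        t = df["t_s"].to_numpy(dtype=float)
        span = t.max() - t.min() if len(t) > 1 else np.nan
        is_cs = (df["kind"] == "CS").to_numpy()
        ss_t = np.sort(t[~is_cs])
        cs_t = np.sort(t[is_cs])
        # characteristic rates are measured outside stimulation pulses, so
        # strong modulation cannot push a unit out of its rate band
        ss_rate = _baseline_rate(ss_t, pulses, span)
        cs_rate = _baseline_rate(cs_t, pulses, span)
        pause_ms, pause_flag = cs_ss_pause(ss_t, cs_t) if len(cs_t) else (None, False)
        viol, _ = refractory_violation_rate(ss_t, refractory_ms)
        records.append(
            UnitRecord(
                unit_id=unit_id,
                cell_class=classify_unit(ss_rate, cs_rate, pause_flag),
                ss_rate_hz=float(ss_rate),
                cs_rate_hz=float(cs_rate),
                pause_ms=pause_ms,
                pause_flag=pause_flag,
                refractory_violation_frac=viol,
                included=included,
            )
        )
    units = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "cell_class": r.cell_class,
                "ss_rate_hz": r.ss_rate_hz,
                "cs_rate_hz": r.cs_rate_hz,
                "pause_ms": r.pause_ms,
                "pause_flag": r.pause_flag,
                "refractory_violation_frac": r.refractory_violation_frac,
                "included": r.included,
            }
            for r in records
        ]
    )
    return units, kept
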