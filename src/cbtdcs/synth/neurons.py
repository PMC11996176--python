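"""Spike-train generation under the polarization rate law.

Simple spikes are drawn from a refractory-thinned inhomogeneous Poisson
process whose instantaneous rate follows the stimulation current:

    r(t) = r0 * max(0, 1 + m(t)),
    m(t) = polarity * gain_per_Vm * E(depth, |I(t)|) * cos(theta)

during pulses (so the modulation tracks the trapezoidal ramps), plus an
opposite-sign exponential rebound after ramp-out.  The generating hazard is
dead-time corrected, h = r / (1 - r * t_ref), so the realized rate equals
the target rate despite the absolute refractory period.

Complex spikes are homogeneous Poisson and unmodulated by default; each CS
silences SS for a pause drawn uniformly from ``pause_range_ms``, the
signature used downstream to identify Purkinje cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cbtdcs.fieldlaw import DEFAULT_FIELD_LAW, FieldLawParams, field_model
from cbtdcs.protocol import StimProtocol

__all__ = [
    "NeuronSpec",
    "trial_table_for_protocol",
    "simulate_unit_on_trials",
    "simulate_pc_unit",
    "simulate_nonpc_unit",
]


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth description of one simulated unit.

    ``gain_per_Vm`` is the fractional rate change per V/m of local field
    for a perfectly aligned soma (theta=0, anodal); the default 0.01/V/m
    puts a mid-depth unit at ~45% modulation for 200 µA, the scale seen in
    strongly modulated vermis recordings.
    """

    unit_id: str
    cell_class: str = "PC"  # {"PC", "nonPC"}
    baseline_ss_hz: float = 60.0
    baseline_cs_hz: float = 1.0
    depth_mm: float = 1.0
    theta_deg: float = 0.0
    gain_per_Vm: float = 0.01
    rebound_gain: float = 0.3
    rebound_tau_s: float = 2.0
    pause_range_ms: tuple[float, float] = (10.0, 40.0)
    refractory_ms: float = 1.5
    region: str = "vermis"  # {"vermis", "crus"}

    def __post_init__(self) -> None:
        if self.cell_class not in ("PC", "nonPC"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.baseline_ss_hz < 0 or self.baseline_cs_hz < 0:
            raise ValueError("baseline rates must be nonnegative")
        if self.cell_class == "PC" and self.baseline_cs_hz <= 0:
            raise ValueError("PC spec requires baseline_cs_hz > 0")
        if self.cell_class == "nonPC" and self.baseline_cs_hz > 0:
            raise ValueError("nonPC spec must have baseline_cs_hz == 0")
        if self.depth_mm < 0:
            raise ValueError("depth_mm must be nonnegative")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")


def trial_table_for_protocol(
    protocol: StimProtocol, lead_s: float | None = None
) -> pd.DataFrame:
    """Build a trial table for a single-polarity tDCS protocol.

    A lead-in rest (default: one rest interval) precedes the first pulse so
    that a full 5 s pre-stimulation window exists for every trial.
    """
    if protocol.mode != "tdcs":
        raise ValueError("trial tables are defined for tdcs protocols")
    if lead_s is None:
        lead_s = protocol.rest_s
    onsets = protocol.trial_onsets(lead_s=lead_s)
    pol = "anodal" if protocol.polarity > 0 else "cathodal"
    return pd.DataFrame(
        {
            "trial_id": np.arange(protocol.n_trials),
            "polarity": pol,
            "intensity_uA": protocol.intensity_uA,
            "t_ramp_in_s": onsets,
            "t_plateau_s": onsets + protocol.ramp_s,
            "t_ramp_out_s": onsets + protocol.ramp_s + protocol.plateau_s,
            "t_end_s": onsets + protocol.pulse_s,
            "running": 0,
        }
    )


def concat_trial_blocks(blocks: list[pd.DataFrame], gap_s: float = 10.0) -> pd.DataFrame:
    """Concatenate trial blocks end to end, shifting times and renumbering."""
    out, offset = [], 0.0
    for blk in blocks:
        blk = blk.copy()
        for col in ("t_ramp_in_s", "t_plateau_s", "t_ramp_out_s", "t_end_s"):
            blk[col] += offset
        offset = float(blk["t_end_s"].iloc[-1]) + gap_s
        out.append(blk)
    cat = pd.concat(out, ignore_index=True)
    cat["trial_id"] = np.arange(len(cat))
    return cat


def _polarity_sign(polarity) -> int:
    if isinstance(polarity, str):
        return {"anodal": 1, "cathodal": -1}[polarity]
    return int(np.sign(polarity))


def plateau_modulation(
    spec: NeuronSpec,
    polarity,
    intensity_uA: float,
    params: FieldLawParams = DEFAULT_FIELD_LAW,
) -> float:
    """Ground-truth plateau modulation fraction for a PC-law unit."""
    e = field_model(spec.depth_mm, intensity_uA, params)
    return (
        _polarity_sign(polarity)
        * spec.gain_per_Vm
        * e
        * np.cos(np.deg2rad(spec.theta_deg))
    )


def modulation_timecourse(
    t: np.ndarray,
    trials: pd.DataFrame,
    m_plateau: np.ndarray,
    rebound_gain: float,
    rebound_tau_s: float,
) -> np.ndarray:
    """Fractional rate modulation m(t) over a session.

    During each pulse m(t) ramps linearly with the current (trapezoid times
    the trial's plateau modulation); after ramp-out it flips sign and
    decays exponentially (rebound).  Trials are assumed non-overlapping.
    """
    t = np.asarray(t, dtype=float)
    m = np.zeros_like(t)
    t_next = np.append(trials["t_ramp_in_s"].to_numpy()[1:], np.inf)
    for i, row in enumerate(trials.itertuples(index=False)):
        in_pulse = (t >= row.t_ramp_in_s) & (t < row.t_end_s)
        if np.any(in_pulse):
            tp = t[in_pulse]
            up = np.clip((tp - row.t_ramp_in_s) / (row.t_plateau_s - row.t_ramp_in_s), 0, 1)
            down = np.clip((row.t_end_s - tp) / (row.t_end_s - row.t_ramp_out_s), 0, 1)
            m[in_pulse] = m_plateau[i] * np.minimum(up, down)
        if rebound_gain != 0:
            in_rest = (t >= row.t_end_s) & (t < t_next[i])
            if np.any(in_rest):
                dt = t[in_rest] - row.t_end_s
                m[in_rest] = -m_plateau[i] * rebound_gain * np.exp(-dt / rebound_tau_s)
    return m


def _dead_time_filter(times: np.ndarray, t_ref_s: float) -> np.ndarray:
    """Greedy enforcement of an absolute refractory period.

    Equivalent to a left-to-right scan keeping each spike at least
    ``t_ref_s`` after the last kept one, but vectorized: each pass drops
    the second spike of every violating pair whose first spike survives,
    which resolves chains of violations in a few passes.
    """
    t = np.asarray(times, dtype=float)
    while len(t) >= 2:
        viol = np.diff(t) < t_ref_s  # viol[i]: gap before t[i+1] too short
        if not viol.any():
            break
        first_of_pair_ok = np.r_[True, ~viol[:-1]]
        drop = np.r_[False, viol & first_of_pair_ok]
        t = t[~drop]
    return t


def sample_modulated_train(
    baseline_hz: float,
    duration_s: float,
    rate_gain_fn,
    refractory_s: float,
    rng: np.random.Generator,
    gain_max: float,
) -> np.ndarray:
    """Refractory-thinned inhomogeneous Poisson train on [0, duration).

    ``rate_gain_fn(t)`` returns the multiplicative gain max(0, 1+m(t)); the
    hazard is dead-time corrected so the realized rate matches
    ``baseline_hz * gain``.  ``gain_max`` must bound the gain.
    """
    if baseline_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    r_cap = 0.95 / refractory_s if refractory_s > 0 else np.inf

    def hazard(r):
        r = np.minimum(r, r_cap)
        return r / (1.0 - r * refractory_s)

    lam_max = hazard(baseline_hz * gain_max)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    if len(cand) == 0:
        return cand
    lam = hazard(baseline_hz * np.asarray(rate_gain_fn(cand), dtype=float))
    keep = rng.uniform(0.0, lam_max, len(cand)) < lam
    return _dead_time_filter(cand[keep], refractory_s)


def _apply_cs_pauses(
    ss: np.ndarray,
    cs: np.ndarray,
    pause_range_ms: tuple[float, float],
    rng: np.random.Generator,
    refractory_s: float = 0.0015,
) -> tuple[np.ndarray, np.ndarray]:
    """Impose a per-CS SS pause; returns (ss_out, pauses_s).

    SS within [cs, cs + pause) are deleted and firing resumes at pause
    end (an SS is placed there unless one follows within a refractory
    period), so the realized CS->next-SS latency equals the drawn pause.
    """
    lo, hi = pause_range_ms
    pauses = rng.uniform(lo, hi, len(cs)) / 1000.0
    if len(cs) == 0 or len(ss) == 0:
        return ss, pauses
    train = ss
    for c, p in zip(cs, pauses):  # sequential: overlapping windows re-clear
        a, b = np.searchsorted(train, [c, c + p])
        resume = c + p
        gap_next = train[b] - resume if b < len(train) else np.inf
        mid = [resume] if gap_next >= refractory_s else []
        train = np.concatenate([train[:a], mid, train[b:]])
    return train, pauses


def simulate_unit_on_trials(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    m_plateau: np.ndarray,
    seed_or_rng,
    duration_s: float | None = None,
    cs_modulated: bool = False,
) -> dict:
    """Simulate one unit over an arbitrary trial table.

    ``m_plateau`` gives the plateau modulation fraction per trial.  Returns
    a dict with ss/cs spike times, per-CS pauses and ground truth.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    m_plateau = np.asarray(m_plateau, dtype=float)
    if len(m_plateau) != len(trials):
        raise ValueError("m_plateau must have one entry per trial")
    if duration_s is None:
        duration_s = float(trials["t_end_s"].iloc[-1]) + 10.0
    t_ref = spec.refractory_ms / 1000.0

    def gain_fn(t):
        m = modulation_timecourse(
            t, trials, m_plateau, spec.rebound_gain, spec.rebound_tau_s
        )
        return np.maximum(0.0, 1.0 + m)

    gain_max = 1.0 + np.max(np.abs(m_plateau), initial=0.0) * (
        1.0 + spec.rebound_gain
    )
    ss = sample_modulated_train(
        spec.baseline_ss_hz, duration_s, gain_fn, t_ref, rng, gain_max
    )

    if spec.baseline_cs_hz > 0:
        cs_gain_fn = gain_fn if cs_modulated else (lambda t: np.ones(len(t)))
        cs = sample_modulated_train(
            spec.baseline_cs_hz, duration_s, cs_gain_fn, t_ref, rng,
            gain_max if cs_modulated else 1.0,
        )
    else:
        cs = np.empty(0)
    ss, pauses = _apply_cs_pauses(ss, cs, spec.pause_range_ms, rng, t_ref)

    return {
        "unit_id": spec.unit_id,
        "spec": spec,
        "ss_times": ss,
        "cs_times": cs,
        "cs_pauses_s": pauses,
        "m_plateau_per_trial": m_plateau,
        "duration_s": duration_s,
    }


def simulate_pc_unit(
    spec: NeuronSpec,
    protocol: StimProtocol,
    params: FieldLawParams = DEFAULT_FIELD_LAW,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Simulate a Purkinje cell under a single-polarity tDCS protocol.

    SS follow the orientation rate law; CS are homogeneous Poisson,
    unmodulated, each followed by a uniform 10-40 ms SS pause.  The result
    carries the ground-truth plateau modulation fraction.
    """
    if spec.cell_class != "PC":
        raise ValueError("simulate_pc_unit requires a PC spec")
    trials = trial_table_for_protocol(protocol)
    m = plateau_modulation(spec, protocol.polarity, protocol.intensity_uA, params)
    out = simulate_unit_on_trials(spec, trials, np.full(len(trials), m), seed)
    out["trials"] = trials
    out["true_mod_fraction"] = m
    return out


def simulate_nonpc_unit(
    spec: NeuronSpec,
    protocol: StimProtocol,
    seed: int | np.random.Generator = 0,
    mod_sd: float = 0.5,
    polarity_corr: float = 0.6,
    mod_fraction: float | None = None,
) -> dict:
    """Simulate a non-Purkinje unit (no CS, heterogeneous modulation).

    The unit's anodal modulation fraction is drawn once from N(0, mod_sd²)
    (truncated to keep the rate nonnegative) and the cathodal fraction from
    a negatively correlated draw; pass ``mod_fraction`` to fix the draw for
    the protocol's polarity.
    """
    if spec.cell_class != "nonPC":
        raise ValueError("simulate_nonpc_unit requires a nonPC spec")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mod_fraction is None:
        m_anodal, m_cathodal = draw_nonpc_modulation(rng, mod_sd, polarity_corr)
        m = m_anodal if protocol.polarity > 0 else m_cathodal
    else:
        m = float(mod_fraction)
    trials = trial_table_for_protocol(protocol)
    out = simulate_unit_on_trials(spec, trials, np.full(len(trials), m), rng)
    out["trials"] = trials
    out["true_mod_fraction"] = m
    return out


def draw_nonpc_modulation(
    rng: np.random.Generator, mod_sd: float = 0.5, polarity_corr: float = 0.6
) -> tuple[float, float]:
    """Draw (anodal, cathodal) modulation fractions for a non-PC unit.

    Zero-centred, wide, negatively correlated between polarities; both
    truncated to (-0.95, inf) so rates stay positive.
    """
    m_a = rng.normal(0.0, mod_sd)
    m_c = -polarity_corr * m_a + np.sqrt(1 - polarity_corr**2) * rng.normal(
        0.0, mod_sd
    )
    return max(m_a, -0.95), max(m_c, -0.95)
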