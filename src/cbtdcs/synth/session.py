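"""Full synthetic-session assembly and on-disk export.

A session bundles everything one animal/recording contributes: a unit
table, a spike-event table, a stimulation trial table, morphologies for
labeled PCs, depth-profiled calibration LFPs and a ground-truth record
that every exported row can be traced back to.

Population defaults encode the study conditions: Purkinje cells in the
vermis have somatodendritic axes near 0° or 180° (oppositely oriented
adjacent layers), crus I/II cells lie obliquely near 90°/270°, and
non-PC units modulate heterogeneously with no orientation structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cbtdcs.fieldlaw import DEFAULT_FIELD_LAW, FieldLawParams
from cbtdcs.protocol import StimProtocol
from cbtdcs.synth.lfp import simulate_lfp_depth_series
from cbtdcs.synth.neurons import (
    NeuronSpec,
    concat_trial_blocks,
    draw_nonpc_modulation,
    plateau_modulation,
    simulate_unit_on_trials,
    trial_table_for_protocol,
)

__all__ = ["SessionData", "simulate_locomotion", "simulate_session", "export_session"]

_THETA_JITTER_DEG = 15.0
_DENDRITE_LEN_UM = 80.0


@dataclass
class SessionData:
    """In-memory synthetic session (see module docstring)."""

    units: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    morphology: pd.DataFrame
    truth: dict
    lfp: dict | None = None


def simulate_locomotion(
    trials, run_prob_per_trial: float, seed: int | np.random.Generator = 0
) -> list[tuple[float, float]]:
    """Flag trials as running and return the running intervals.

    Each trial is independently flagged with probability
    ``run_prob_per_trial``; a flagged trial's interval covers its whole
    pulse (half-open [ramp-in, end)).  Accepts a trial table or a
    ``StimProtocol`` (converted to its trial table).
    """
    if not 0.0 <= run_prob_per_trial <= 1.0:
        raise ValueError("run_prob_per_trial must be in [0, 1]")
    if isinstance(trials, StimProtocol):
        trials = trial_table_for_protocol(trials)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = rng.uniform(size=len(trials)) < run_prob_per_trial
    trials.loc[:, "running"] = flags.astype(int)
    return [
        (float(row.t_ramp_in_s), float(row.t_end_s))
        for row, f in zip(trials.itertuples(index=False), flags)
        if f
    ]


def _vermis_theta(rng: np.random.Generator) -> float:
    base = 0.0 if rng.uniform() < 0.5 else 180.0
    return float(np.mod(base + rng.normal(0.0, _THETA_JITTER_DEG), 360.0))


def _crus_theta(rng: np.random.Generator) -> float:
    base = 90.0 if rng.uniform() < 0.5 else 270.0
    return float(np.mod(base + rng.normal(0.0, _THETA_JITTER_DEG), 360.0))


def _session_trials(
    intensities_uA, n_trials: int, plateau_s: float, rest_s: float
) -> pd.DataFrame:
    blocks = []
    for intensity in intensities_uA:
        for polarity in (1, -1):
            proto = StimProtocol(
                polarity=polarity,
                intensity_uA=float(intensity),
                plateau_s=plateau_s,
                rest_s=rest_s,
                n_trials=n_trials,
            )
            blocks.append(trial_table_for_protocol(proto))
    return concat_trial_blocks(blocks, gap_s=rest_s)


def simulate_session(
    seed: int,
    n_pc_vermis: int = 6,
    n_pc_crus: int = 6,
    n_nonpc: int = 8,
    intensities_uA=(200.0,),
    n_trials: int = 5,
    plateau_s: float = 5.0,
    rest_s: float = 10.0,
    field_params: FieldLawParams = DEFAULT_FIELD_LAW,
    run_prob_per_trial: float = 0.1,
    nonpc_mod_sd: float = 0.5,
    nonpc_polarity_corr: float = 0.6,
    gain_per_Vm: float = 0.01,
    rebound_gain: float = 0.3,
    rebound_tau_s: float = 2.0,
    include_lfp: bool = True,
    lfp_duration_s: float = 10.0,
    lfp_intensities_uA=(2.0, 20.0, 200.0),
) -> SessionData:
    """Generate a complete labeled session.

    Trials run in blocks (anodal then cathodal per intensity); every unit
    is recorded across all trials.  PC modulation follows the cosine
    polarization law at the unit's depth; non-PC modulation is drawn per
    unit, wide and negatively correlated across polarities.
    """
    rng = np.random.default_rng(seed)
    trials = _session_trials(intensities_uA, n_trials, plateau_s, rest_s)
    locomotion = simulate_locomotion(trials, run_prob_per_trial, rng)
    duration_s = float(trials["t_end_s"].iloc[-1]) + rest_s

    units_rows, spike_frames, morph_rows, truth_units = [], [], [], []
    pol_sign = trials["polarity"].map({"anodal": 1, "cathodal": -1}).to_numpy()
    trial_intensity = trials["intensity_uA"].to_numpy()

    def _simulate(spec: NeuronSpec, m_plateau: np.ndarray, truth_mod: dict) -> None:
        res = simulate_unit_on_trials(spec, trials, m_plateau, rng, duration_s)
        amp = rng.uniform(150.0, 400.0)
        frames = []
        for kind, times, scale in (
            ("SS", res["ss_times"], 1.0),
            ("CS", res["cs_times"], 1.5),
        ):
            if len(times) == 0:
                continue
            amps = amp * scale * (1.0 + 0.05 * rng.standard_normal(len(times)))
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": spec.unit_id,
                        "t_s": times,
                        "kind": kind,
                        "amplitude_uV": amps,
                    }
                )
            )
        if spec.cell_class == "nonPC" and len(res["ss_times"]):
            frames[-1]["kind"] = "NA"
        df = (
            pd.concat(frames, ignore_index=True).sort_values("t_s", kind="stable")
            if frames
            else pd.DataFrame(columns=["unit_id", "t_s", "kind", "amplitude_uV"])
        )
        spike_frames.append(df)
        units_rows.append(
            {
                "unit_id": spec.unit_id,
                "cell_class": spec.cell_class,
                "depth_mm": spec.depth_mm,
                "theta_deg": spec.theta_deg if spec.cell_class == "PC" else np.nan,
                "region": spec.region,
            }
        )
        truth_units.append(
            {
                "unit_id": spec.unit_id,
                "cell_class": spec.cell_class,
                "region": spec.region,
                "depth_mm": spec.depth_mm,
                "theta_deg": spec.theta_deg if spec.cell_class == "PC" else None,
                "mod_fraction": truth_mod,
                "n_ss": int(len(res["ss_times"])),
                "n_cs": int(len(res["cs_times"])),
            }
        )

    def _pc(unit_id: str, region: str, theta: float) -> None:
        spec = NeuronSpec(
            unit_id=unit_id,
            cell_class="PC",
            depth_mm=float(rng.uniform(0.3, 2.3)),
            theta_deg=theta,
            gain_per_Vm=gain_per_Vm,
            rebound_gain=rebound_gain,
            rebound_tau_s=rebound_tau_s,
            region=region,
        )
        m_plateau = np.array(
            [
                plateau_modulation(spec, int(s), float(i), field_params)
                for s, i in zip(pol_sign, trial_intensity)
            ]
        )
        truth_mod = {
            f"{pol}@{int(i)}": plateau_modulation(spec, ps, float(i), field_params)
            for i in np.unique(trial_intensity)
            for pol, ps in (("anodal", 1), ("cathodal", -1))
        }
        _simulate(spec, m_plateau, truth_mod)
        soma = rng.uniform(100.0, 400.0, 2)
        th = np.deg2rad(theta)
        dend = soma + _DENDRITE_LEN_UM * np.array([-np.sin(th), np.cos(th)])
        morph_rows.append(
            {
                "unit_id": unit_id,
                "soma_x_um": soma[0],
                "soma_y_um": soma[1],
                "dend_x_um": dend[0],
                "dend_y_um": dend[1],
                "axis_x": 0.0,
                "axis_y": 1.0,
            }
        )

    k = 0
    for _ in range(n_pc_vermis):
        _pc(f"u{k:03d}", "vermis", _vermis_theta(rng)); k += 1
    for _ in range(n_pc_crus):
        _pc(f"u{k:03d}", "crus", _crus_theta(rng)); k += 1
    for _ in range(n_nonpc):
        m_a, m_c = draw_nonpc_modulation(rng, nonpc_mod_sd, nonpc_polarity_corr)
        spec = NeuronSpec(
            unit_id=f"u{k:03d}",
            cell_class="nonPC",
            baseline_ss_hz=float(rng.uniform(15.0, 45.0)),
            baseline_cs_hz=0.0,
            depth_mm=float(rng.uniform(0.3, 2.3)),
            rebound_gain=rebound_gain,
            rebound_tau_s=rebound_tau_s,
            region="vermis" if rng.uniform() < 0.5 else "crus",
        )
        m_plateau = np.where(pol_sign > 0, m_a, m_c)
        _simulate(spec, m_plateau, {"anodal": m_a, "cathodal": m_c})
        k += 1

    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "t_s", "kind", "amplitude_uV"])
    )
    lfp = (
        simulate_lfp_depth_series(
            field_params,
            duration_s=lfp_duration_s,
            intensities_uA=lfp_intensities_uA,
            seed=rng,
        )
        if include_lfp
        else None
    )
    truth = {
        "seed": seed,
        "units": truth_units,
        "locomotion": [[a, b] for a, b in locomotion],
        "field": None
        if lfp is None
        else {
            "depths_mm": lfp["depths_mm"].tolist(),
            "segment_mid_mm": lfp["segment_mid_mm"].tolist(),
            "field_Vm": {
                str(i): v.tolist() for i, v in lfp["true_field_Vm"].items()
            },
        },
    }
    return SessionData(
        units=pd.DataFrame(units_rows),
        spikes=spikes,
        trials=trials,
        morphology=pd.DataFrame(morph_rows),
        truth=truth,
        lfp=lfp,
    )


def export_session(session: SessionData, out_dir) -> Path:
    """Write a session to disk in the plain-text exchange formats.

    Layout: ``units.csv``, ``spikes.csv`` (times to 6 decimals),
    ``trials.csv``, ``morphology.csv``, ``truth.json`` and, when present,
    ``lfp/<depth>_<intensity>.bin`` (little-endian float32) with a
    ``lfp_meta.json`` sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.units.to_csv(out / "units.csv", index=False, float_format="%.6f")
    spikes = session.spikes.copy()
    spikes["t_s"] = spikes["t_s"].map(lambda v: f"{v:.6f}")
    spikes["amplitude_uV"] = spikes["amplitude_uV"].map(lambda v: f"{v:.3f}")
    spikes.to_csv(out / "spikes.csv", index=False)
    session.trials.to_csv(out / "trials.csv", index=False, float_format="%.6f")
    session.morphology.to_csv(out / "morphology.csv", index=False, float_format="%.6f")
    with open(out / "truth.json", "w") as fh:
        json.dump(session.truth, fh, indent=1, sort_keys=True)
    if session.lfp is not None:
        lfp_dir = out / "lfp"
        lfp_dir.mkdir(exist_ok=True)
        meta = {
            "sample_rate_hz": session.lfp["sample_rate_hz"],
            "stim_freq_hz": session.lfp["stim_freq_hz"],
            "units": "mV",
            "traces": [],
        }
        for (d, i), tr in session.lfp["traces"].items():
            name = f"{d:g}_{i:g}.bin"
            tr.astype("<f4").tofile(lfp_dir / name)
            meta["traces"].append(
                {"file": name, "depth_mm": d, "intensity_uA": i}
            )
        with open(out / "lfp_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
    return out
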