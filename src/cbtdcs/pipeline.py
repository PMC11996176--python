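"""End-to-end orchestration: generate, estimate field, classify, modulate,
orient, summarize.

Each stage reads only the exported session files of the previous stages
and writes its own outputs; a run manifest records seed, configuration
hash and package version so identical configurations reproduce identical
numeric outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

import cbtdcs
from cbtdcs import io as cbio
from cbtdcs.config import PipelineConfig
from cbtdcs.field_estimation import (
    fit_log_decay,
    fit_polynomial_surface,
    profiles_from_lfp,
    profiles_to_frame,
)
from cbtdcs.modulation import ModulationResult, analyze_unit_condition
from cbtdcs.orientation import (
    Morphology,
    OrientationResult,
    cosine_model_fit,
    polar_summary,
    predicted_sign,
    somatodendritic_angle,
)
from cbtdcs.spike_pipeline import classify_session
from cbtdcs.synth.session import export_session, simulate_session

__all__ = [
    "stage_simulate",
    "stage_field",
    "stage_classify",
    "stage_modulate",
    "stage_orient",
    "run_full_pipeline",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(f"[{name}] {exc}") from exc

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, out_dir: Path) -> Path:
    """Generate and export a synthetic session."""
    g = config.generator
    session = simulate_session(
        seed=config.seed,
        n_pc_vermis=g.n_pc_vermis,
        n_pc_crus=g.n_pc_crus,
        n_nonpc=g.n_nonpc,
        intensities_uA=g.intensities_uA,
        n_trials=g.n_trials,
        plateau_s=g.plateau_s,
        rest_s=g.rest_s,
        field_params=g.field_params(),
        run_prob_per_trial=g.run_prob_per_trial,
        nonpc_mod_sd=g.nonpc_mod_sd,
        nonpc_polarity_corr=g.nonpc_polarity_corr,
        gain_per_Vm=g.gain_per_Vm,
        rebound_gain=g.rebound_gain,
        rebound_tau_s=g.rebound_tau_s,
        lfp_duration_s=g.lfp_duration_s,
        lfp_intensities_uA=g.lfp_intensities_uA,
    )
    session_dir = out_dir / "session"
    export_session(session, session_dir)
    return session_dir


@_stage("field")
def stage_field(session_dir: Path, out_dir: Path) -> dict:
    """Estimate the field depth profile and interpolation surface."""
    lfp = cbio.read_lfp(session_dir)
    profiles = profiles_from_lfp(lfp)
    frame = profiles_to_frame(profiles)
    frame.to_csv(out_dir / "field_profile.csv", index=False, float_format="%.6f")

    log_fits = {}
    for p in profiles:
        if len(p.field_Vm) >= 3:
            a, b, r = fit_log_decay(p.field_Vm, p.segment_mid_mm)
            log_fits[p.intensity_uA] = {"a": a, "b": b, "R": r}
    surface = fit_polynomial_surface(
        frame["segment_mid_mm"].to_numpy(),
        frame["intensity_uA"].to_numpy(),
        frame["field_Vm"].to_numpy(),
    )
    out = {
        "log_fits": {str(k): v for k, v in log_fits.items()},
        "surface": {
            "coefficients": {f"d{i}_i{j}": c for (i, j), c in surface.coef.items()},
            "conf_bounds_95": {
                f"d{i}_i{j}": list(b) for (i, j), b in surface.conf_bounds.items()
            },
            "R": surface.r,
            "depth_range_mm": list(surface.depth_range_mm),
            "intensity_range_uA": list(surface.intensity_range_uA),
        },
    }
    with open(out_dir / "field_surface.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


@_stage("classify")
def stage_classify(
    session_dir: Path, out_dir: Path, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify units and select clean trials."""
    spikes = cbio.read_spikes(session_dir / "spikes.csv")
    trials = cbio.read_trials(session_dir / "trials.csv")
    truth = cbio.read_truth(session_dir / "truth.json")
    locomotion = [tuple(iv) for iv in truth.get("locomotion", [])]
    units, kept = classify_session(
        spikes,
        trials,
        locomotion,
        min_trials=config.analysis.min_trials,
        refractory_ms=config.analysis.refractory_ms,
    )
    units.to_csv(out_dir / "units_classified.csv", index=False)
    kept.to_csv(out_dir / "kept_trials.csv", index=False, float_format="%.6f")
    return units, kept


@_stage("modulate")
def stage_modulate(
    session_dir: Path,
    out_dir: Path,
    config: PipelineConfig,
    units: pd.DataFrame,
    kept_trials: pd.DataFrame,
) -> list[ModulationResult]:
    """Per-unit modulation statistics for every (polarity, intensity)."""
    spikes = cbio.read_spikes(session_dir / "spikes.csv")
    psth_dir = out_dir / "psth"
    psth_dir.mkdir(exist_ok=True)
    results: list[ModulationResult] = []
    analyzable = units.loc[units["included"] & (units["cell_class"] != "rejected")]
    for unit_id in analyzable["unit_id"]:
        is_pc = units.set_index("unit_id").loc[unit_id, "cell_class"] == "PC"
        kind = "SS" if is_pc else None
        times = cbio.unit_spike_times(spikes, unit_id, kind=kind)
        for (pol, intensity), tr in kept_trials.groupby(
            ["polarity", "intensity_uA"], sort=True
        ):
            if len(tr) < config.analysis.min_trials:
                continue
            res = analyze_unit_condition(
                times,
                tr,
                unit_id,
                alpha=config.analysis.alpha,
                bin_s=config.analysis.bin_ss_s,
            )
            results.append(res)
            if not res.sigma_zero:
                pd.DataFrame(
                    {"bin_start_s": res.psth_bin_start_s, "z": res.z_psth}
                ).to_csv(
                    psth_dir / f"{unit_id}_{pol}.csv",
                    index=False,
                    float_format="%.6f",
                )
    rows = [
        {
            "unit_id": r.unit_id,
            "polarity": r.polarity,
            "intensity_uA": r.intensity_uA,
            "rate_before_hz": r.rates[:, 0].mean(),
            "rate_during_hz": r.rates[:, 1].mean(),
            "rate_after_hz": r.rates[:, 2].mean(),
            "test_name": r.test_name,
            "statistic": r.statistic,
            "p": r.p,
            "significant": r.significant,
            "mod_percent": r.mod_percent,
            "folded_percent": r.folded_percent,
            "sigma_zero": r.sigma_zero,
        }
        for r in results
    ]
    cols = [
        "unit_id", "polarity", "intensity_uA", "rate_before_hz",
        "rate_during_hz", "rate_after_hz", "test_name", "statistic", "p",
        "significant", "mod_percent", "folded_percent", "sigma_zero",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(out_dir / "modulation.csv", index=False)
    return results


@_stage("orient")
def stage_orient(
    session_dir: Path, out_dir: Path, config: PipelineConfig
) -> pd.DataFrame:
    """Relate morphology-derived angles to measured modulation."""
    morph = cbio.read_morphology(session_dir / "morphology.csv")
    mod = pd.read_csv(out_dir / "modulation.csv")
    empty_cols = [
        "unit_id", "theta_deg", "polarity", "arrow_length_percent",
        "predicted_sign", "observed_sign",
    ]
    results = []
    for row in morph.itertuples(index=False):
        theta = somatodendritic_angle(
            Morphology(
                unit_id=row.unit_id,
                soma_xy=(row.soma_x_um, row.soma_y_um),
                dendrite_centroid_xy=(row.dend_x_um, row.dend_y_um),
                electrode_axis=(row.axis_x, row.axis_y),
            )
        )
        sub = mod.loc[mod["unit_id"] == row.unit_id]
        mods = {
            r.polarity: r.mod_percent
            for r in sub.itertuples(index=False)
            if pd.notna(r.mod_percent)
        }
        if not mods:
            continue
        results.append(
            OrientationResult(
                unit_id=row.unit_id,
                theta_deg=theta,
                mod_percent=mods,
                predicted={
                    pol: predicted_sign(theta, pol, config.analysis.dead_zone_cos)
                    for pol in mods
                },
            )
        )
    if not results:
        table = pd.DataFrame(columns=empty_cols)
        table.to_csv(out_dir / "orientation.csv", index=False)
        return table
    table = polar_summary(results)
    table["predicted_sign"] = [
        r.predicted[pol]
        for r in results
        for pol in r.mod_percent
    ]
    table["observed_sign"] = np.sign(table["arrow_length_percent"] - 100.0).astype(int)
    for pol in ("anodal", "cathodal"):
        sub = table.loc[table["polarity"] == pol]
        if len(sub) >= 4:
            try:
                amp, phi, r = cosine_model_fit(
                    sub["theta_deg"].to_numpy(),
                    sub["arrow_length_percent"].to_numpy(),
                )
                table.loc[sub.index, "cosine_amplitude"] = amp
                table.loc[sub.index, "cosine_phase_deg"] = phi
                table.loc[sub.index, "cosine_r"] = r
            except ValueError:
                pass
    table.to_csv(out_dir / "orientation.csv", index=False, float_format="%.6f")
    return table


def run_full_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages and write a summary report plus run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_dir = stage_simulate(config, out)
    field = stage_field(session_dir, out)
    units, kept = stage_classify(session_dir, out, config)
    mod_results = stage_modulate(session_dir, out, config, units, kept)
    orient = stage_orient(session_dir, out, config)

    n_sig = sum(r.significant for r in mod_results)
    summary = {
        "n_units": int(len(units)),
        "n_pc": int((units["cell_class"] == "PC").sum()),
        "n_nonpc": int((units["cell_class"] == "nonPC").sum()),
        "n_rejected": int((units["cell_class"] == "rejected").sum()),
        "n_kept_trials": int(len(kept)),
        "n_unit_conditions_tested": len(mod_results),
        "n_significant": int(n_sig),
        "log_fit_R": {k: v["R"] for k, v in field["log_fits"].items()},
        "surface_R": field["surface"]["R"],
        "n_orientation_rows": int(len(orient)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": config.digest(),
        "package_version": cbtdcs.__version__,
        "python": platform.python_version(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary
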