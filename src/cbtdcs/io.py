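"""Readers and writers for the on-disk session exchange formats.

All tabular formats are plain CSV; continuous LFP traces are raw
little-endian float32 with a JSON sidecar describing sample rate, depth
and intensity.  See :mod:`cbtdcs.synth.session` for the writer side.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_units",
    "read_spikes",
    "read_trials",
    "read_morphology",
    "read_truth",
    "read_lfp",
    "unit_spike_times",
]

_SPIKE_COLS = ["unit_id", "t_s", "kind", "amplitude_uV"]
_TRIAL_COLS = [
    "trial_id",
    "polarity",
    "intensity_uA",
    "t_ramp_in_s",
    "t_plateau_s",
    "t_ramp_out_s",
    "t_end_s",
    "running",
]


def _read_csv(path, required_cols, name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"failed to parse {name} table {path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table {path} missing columns {missing}")
    return df


def read_units(path) -> pd.DataFrame:
    return _read_csv(path, ["unit_id", "cell_class", "depth_mm", "region"], "units")


def read_spikes(path) -> pd.DataFrame:
    df = _read_csv(path, _SPIKE_COLS, "spikes")
    return df.sort_values(["unit_id", "t_s"], kind="stable").reset_index(drop=True)


def read_trials(path) -> pd.DataFrame:
    return _read_csv(path, _TRIAL_COLS, "trials")


def read_morphology(path) -> pd.DataFrame:
    cols = ["unit_id", "soma_x_um", "soma_y_um", "dend_x_um", "dend_y_um",
            "axis_x", "axis_y"]
    return _read_csv(path, cols, "morphology")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_lfp(session_dir) -> dict:
    """Load all LFP traces of a session via the ``lfp_meta.json`` sidecar.

    Returns ``{"sample_rate_hz", "stim_freq_hz", "traces"}`` with traces
    keyed by (depth_mm, intensity_uA), values in mV.
    """
    session_dir = Path(session_dir)
    with open(session_dir / "lfp_meta.json") as fh:
        meta = json.load(fh)
    traces = {}
    for entry in meta["traces"]:
        data = np.fromfile(session_dir / "lfp" / entry["file"], dtype="<f4")
        traces[(entry["depth_mm"], entry["intensity_uA"])] = data.astype(float)
    return {
        "sample_rate_hz": meta["sample_rate_hz"],
        "stim_freq_hz": meta["stim_freq_hz"],
        "units": meta.get("units", "mV"),
        "traces": traces,
    }


def unit_spike_times(
    spikes: pd.DataFrame, unit_id: str, kind: str | None = None
) -> np.ndarray:
    """Ascending spike times of one unit, optionally restricted to a kind."""
    sel = spikes["unit_id"] == unit_id
    if kind is not None:
        sel &= spikes["kind"] == kind
    return np.sort(spikes.loc[sel, "t_s"].to_numpy(dtype=float))
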