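"""Electric-field estimation from depth-profiled tACS LFP recordings.

The field imposed intracranially is estimated exactly as in the
experimental design: the peak-to-peak amplitude of the stimulation-locked
LFP oscillation is averaged over cycles at each depth, the field strength
per 1 mm segment is the difference of peak-to-peak potentials between
consecutive depths (mV over mm is numerically V/m), the depth decay is
summarized by a log fit, and a degree-2 x degree-2 polynomial surface
interpolates the field over (depth, intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DepthProfile",
    "SurfaceModel",
    "cycle_peak_to_peak",
    "field_from_profile",
    "fit_log_decay",
    "fit_polynomial_surface",
    "evaluate_surface",
    "profiles_from_lfp",
]


@dataclass
class DepthProfile:
    """Per-intensity depth profile of LFP amplitude and derived field."""

    intensity_uA: float
    depths_mm: np.ndarray
    p2p_mV: np.ndarray
    field_Vm: np.ndarray
    segment_mid_mm: np.ndarray


@dataclass
class SurfaceModel:
    """Bivariate polynomial field surface, degree 2 in depth and intensity.

    ``coef`` maps monomial powers (i, j) -> coefficient of
    depth^i * intensity^j; ``conf_bounds`` holds the 95% confidence
    interval per coefficient; ``r`` is the Pearson correlation between
    fitted and observed field values.  The fitted hull is the bounding
    rectangle of the training grid; evaluations outside it are flagged
    as extrapolation.
    """

    coef: dict[tuple[int, int], float]
    conf_bounds: dict[tuple[int, int], tuple[float, float]]
    r: float
    depth_range_mm: tuple[float, float]
    intensity_range_uA: tuple[float, float]


def cycle_peak_to_peak(
    trace: np.ndarray, stim_freq_hz: float, sample_rate_hz: float
) -> float:
    """Mean per-cycle peak-to-peak amplitude of a stimulation-locked trace.

    The trace is split into whole cycles of ``1/stim_freq_hz``; the
    max-min within each cycle is averaged; a trailing partial cycle is
    discarded.  Raises if the trace is shorter than one full cycle.
    """
    trace = np.asarray(trace, dtype=float)
    cycle_len = int(round(sample_rate_hz / stim_freq_hz))
    if cycle_len < 2 or len(trace) < cycle_len:
        raise ValueError("trace shorter than one stimulation cycle")
    n_cycles = len(trace) // cycle_len
    x = trace[: n_cycles * cycle_len].reshape(n_cycles, cycle_len)
    return float(np.mean(x.max(axis=1) - x.min(axis=1)))


def field_from_profile(
    p2p_mV: np.ndarray,
    depths_mm: np.ndarray,
    require_unit_spacing: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment field from consecutive-depth peak-to-peak differences.

    field_i = (p2p_i - p2p_{i+1}) / Δdepth, in V/m, assigned to the
    segment midpoint.  By default consecutive depths must be exactly
    1 mm apart (the calibrated design); pass
    ``require_unit_spacing=False`` for other spacings.

    Returns (field_Vm, segment_mid_mm).
    """
    p2p = np.asarray(p2p_mV, dtype=float)
    depths = np.asarray(depths_mm, dtype=float)
    if len(p2p) != len(depths) or len(depths) < 2:
        raise ValueError("need matching p2p/depth arrays with >= 2 depths")
    dd = np.diff(depths)
    if np.any(dd <= 0):
        raise ValueError("depths must be strictly ascending")
    if require_unit_spacing and not np.allclose(dd, 1.0):
        raise ValueError(
            "consecutive depths are not 1 mm apart; pass require_unit_spacing=False"
        )
    fld = -np.diff(p2p) / dd
    mids = 0.5 * (depths[:-1] + depths[1:])
    return fld, mids


def fit_log_decay(
    field_Vm: np.ndarray, segment_mid_mm: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of ``field = a - b * ln(depth)``.

    Returns (a, b, R) where R is the Pearson correlation between fitted
    and observed values (1.0 for an exact constant fit).  Requires >= 3
    segments at positive depths.
    """
    y = np.asarray(field_Vm, dtype=float)
    d = np.asarray(segment_mid_mm, dtype=float)
    if len(y) != len(d) or len(y) < 3:
        raise ValueError("need >= 3 segments for the log fit")
    if np.any(d <= 0):
        raise ValueError("segment depths must be positive")
    x = np.log(d)
    A = np.column_stack([np.ones_like(x), -x])
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = a - b * x
    resid = y - fitted
    if np.std(y) == 0 or np.std(fitted) == 0:
        r = 1.0 if np.max(np.abs(resid)) < 1e-12 * max(1.0, np.max(np.abs(y))) else 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    return float(a), float(b), r


_POWERS = [(i, j) for i in range(3) for j in range(3)]


def _design(depth: np.ndarray, intensity: np.ndarray, powers) -> np.ndarray:
    return np.column_stack([depth**i * intensity**j for i, j in powers])


def fit_polynomial_surface(
    depth_mm: np.ndarray,
    intensity_uA: np.ndarray,
    field_Vm: np.ndarray,
    force_zero_intensity: bool = False,
) -> SurfaceModel:
    """Fit the degree-2 x degree-2 polynomial field surface.

    All monomials depth^i * intensity^j with i, j in {0, 1, 2} are fitted
    by ordinary least squares; 95% confidence bounds come from the
    linear-model covariance.  ``force_zero_intensity=True`` drops the
    j=0 terms so the surface vanishes at zero intensity.  Requires at
    least 9 points spanning >= 3 depths and >= 3 intensities.
    """
    d = np.asarray(depth_mm, dtype=float)
    i_ = np.asarray(intensity_uA, dtype=float)
    y = np.asarray(field_Vm, dtype=float)
    if not (len(d) == len(i_) == len(y)):
        raise ValueError("inputs must have equal length")
    powers = [(a, b) for a, b in _POWERS if not (force_zero_intensity and b == 0)]
    if len(y) < len(powers) or len(np.unique(d)) < 3 or len(np.unique(i_)) < 3:
        raise ValueError("need >= 9 points spanning >= 3 depths x >= 3 intensities")
    X = _design(d, i_, powers)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: grid does not span the model")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    fitted = res.fittedvalues
    if np.std(y) == 0 or np.std(fitted) == 0:
        r = 1.0 if np.max(np.abs(y - fitted)) < 1e-10 else 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    coef = dict(zip(powers, map(float, res.params)))
    bounds = {p: (float(lo), float(hi)) for p, (lo, hi) in zip(powers, np.asarray(ci))}
    for p in _POWERS:  # dropped terms are fixed at zero
        coef.setdefault(p, 0.0)
        bounds.setdefault(p, (0.0, 0.0))
    return SurfaceModel(
        coef=coef,
        conf_bounds=bounds,
        r=r,
        depth_range_mm=(float(d.min()), float(d.max())),
        intensity_range_uA=(float(i_.min()), float(i_.max())),
    )


def evaluate_surface(
    model: SurfaceModel,
    depth_mm,
    intensity_uA,
    allow_extrapolation: bool = True,
):
    """Evaluate the fitted surface at (depth, intensity).

    Returns ``(field_Vm, extrapolated)``; ``extrapolated`` flags points
    outside the fitted hull.  With ``allow_extrapolation=False`` such
    points raise instead.
    """
    if model is None or not model.coef:
        raise ValueError("surface model is unfitted")
    d = np.asarray(depth_mm, dtype=float)
    i_ = np.asarray(intensity_uA, dtype=float)
    out = np.zeros(np.broadcast(d, i_).shape)
    for (a, b), c in model.coef.items():
        out = out + c * d**a * i_**b
    d_lo, d_hi = model.depth_range_mm
    i_lo, i_hi = model.intensity_range_uA
    extrap = (d < d_lo) | (d > d_hi) | (i_ < i_lo) | (i_ > i_hi)
    if np.any(extrap):
        if not allow_extrapolation:
            raise ValueError("evaluation point outside the fitted hull")
        warnings.warn("surface evaluated outside the fitted hull", stacklevel=2)
    if np.ndim(out) == 0 or out.shape == ():
        return float(out), bool(np.any(extrap))
    return out, np.asarray(extrap)


def profiles_from_lfp(lfp: dict, require_unit_spacing: bool = True) -> list[DepthProfile]:
    """Build per-intensity depth profiles from loaded LFP traces.

    ``lfp`` is the dict returned by :func:`cbtdcs.io.read_lfp` (or the
    generator): traces keyed by (depth_mm, intensity_uA).
    """
    fs = lfp["sample_rate_hz"]
    f0 = lfp["stim_freq_hz"]
    by_intensity: dict[float, list[tuple[float, float]]] = {}
    for (d, i_), tr in lfp["traces"].items():
        by_intensity.setdefault(float(i_), []).append(
            (float(d), cycle_peak_to_peak(tr, f0, fs))
        )
    profiles = []
    for intensity in sorted(by_intensity):
        rows = sorted(by_intensity[intensity])
        depths = np.array([d for d, _ in rows])
        p2p = np.array([p for _, p in rows])
        if len(depths) < 3:
            warnings.warn(
                f"intensity {intensity}: fewer than 3 depths, log fit will be skipped",
                stacklevel=2,
            )
        fld, mids = field_from_profile(p2p, depths, require_unit_spacing)
        profiles.append(DepthProfile(intensity, depths, p2p, fld, mids))
    return profiles


def profiles_from_p2p(
    p2p_table: pd.DataFrame, require_unit_spacing: bool = True
) -> list[DepthProfile]:
    """Build depth profiles from a precomputed peak-to-peak table.

    Expects columns depth_mm, intensity_uA, p2p_mV (e.g. a ``p2p.csv``
    exported by other acquisition software).
    """
    for col in ("depth_mm", "intensity_uA", "p2p_mV"):
        if col not in p2p_table.columns:
            raise ValueError(f"p2p table missing column {col!r}")
    profiles = []
    for intensity, grp in p2p_table.groupby("intensity_uA", sort=True):
        grp = grp.sort_values("depth_mm")
        fld, mids = field_from_profile(
            grp["p2p_mV"].to_numpy(),
            grp["depth_mm"].to_numpy(),
            require_unit_spacing,
        )
        profiles.append(
            DepthProfile(
                float(intensity),
                grp["depth_mm"].to_numpy(dtype=float),
                grp["p2p_mV"].to_numpy(dtype=float),
                fld,
                mids,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[DepthProfile]) -> pd.DataFrame:
    """Flatten depth profiles to the ``field_profile.csv`` layout."""
    rows = [
        {
            "intensity_uA": p.intensity_uA,
            "segment_mid_mm": m,
            "field_Vm": f,
        }
        for p in profiles
        for m, f in zip(p.segment_mid_mm, p.field_Vm)
    ]
    return pd.DataFrame(rows)
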