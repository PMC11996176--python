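"""Somatodendritic orientation and the cosine polarization model.

The angle theta between a neuron's somatodendritic axis (soma toward
dendritic centroid) and the line perpendicular to the skull under the
active electrode determines the sign and magnitude of the somatic
polarization: anodal stimulation increases excitability of cells whose
dendrites point toward the electrode (theta near 0), decreases it when
they point away (theta near 180), and has little effect near 90/270.
Angles are signed in the 2-D section plane, counterclockwise positive,
with the electrode axis at 0, mapped to [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Morphology",
    "OrientationResult",
    "somatodendritic_angle",
    "predicted_sign",
    "cosine_model_fit",
    "polar_summary",
]

DEAD_ZONE_COS = 0.1


@dataclass(frozen=True)
class Morphology:
    """Section-plane coordinates of one labeled neuron (µm).

    ``electrode_axis`` is the unit vector perpendicular to the skull under
    the active electrode, pointing from tissue toward the electrode.
    """

    unit_id: str
    soma_xy: tuple[float, float]
    dendrite_centroid_xy: tuple[float, float]
    electrode_axis: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if np.allclose(self.soma_xy, self.dendrite_centroid_xy):
            raise ValueError("soma and dendritic centroid coincide")
        norm = np.hypot(*self.electrode_axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("electrode_axis must be a unit vector")


@dataclass
class OrientationResult:
    """Orientation-vs-modulation summary for one unit."""

    unit_id: str
    theta_deg: float
    mod_percent: dict[str, float]
    predicted: dict[str, int]


def somatodendritic_angle(morph: Morphology) -> float:
    """Signed angle (degrees, [0, 360)) from the electrode axis to the
    somatodendritic axis, counterclockwise positive.

    0 means the dendrites point toward the electrode, 180 away from it.
    Invariant to uniform translation and scaling of the coordinates.
    """
    ax, ay = morph.electrode_axis
    vx = morph.dendrite_centroid_xy[0] - morph.soma_xy[0]
    vy = morph.dendrite_centroid_xy[1] - morph.soma_xy[1]
    cross = ax * vy - ay * vx
    dot = ax * vx + ay * vy
    return float(np.mod(np.degrees(np.arctan2(cross, dot)), 360.0))


def predicted_sign(theta_deg: float, polarity, dead_zone_cos: float = DEAD_ZONE_COS):
    """Predicted modulation sign {-1, 0, +1} under the cosine model.

    sign(polarity * cos theta), with a dead zone |cos theta| <
    ``dead_zone_cos`` returning 0 (near-perpendicular cells are
    unmodulated).
    """
    if not 0.0 <= theta_deg < 360.0:
        raise ValueError("theta_deg must be in [0, 360)")
    pol = {"anodal": 1, "cathodal": -1}.get(polarity, polarity)
    c = np.cos(np.deg2rad(theta_deg))
    if abs(c) < dead_zone_cos:
        return 0
    return int(np.sign(pol * c))


def cosine_model_fit(
    thetas_deg: np.ndarray, signed_mod_percent: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares cosine fit of modulation versus orientation.

    Fits mod - 100 = A cos(theta - phi) via the linear parametrization
    a cos(theta) + b sin(theta); returns (A, phi_deg, r) with r the
    Pearson correlation between cos(theta - phi) and the data.
    """
    th = np.deg2rad(np.asarray(thetas_deg, dtype=float))
    y = np.asarray(signed_mod_percent, dtype=float) - 100.0
    if len(th) != len(y) or len(th) < 4:
        raise ValueError("need >= 4 units for the cosine fit")
    quadrants = np.unique((np.asarray(thetas_deg) // 90).astype(int) % 4)
    if len(quadrants) < 2:
        raise ValueError("orientations span fewer than 2 quadrants")
    X = np.column_stack([np.cos(th), np.sin(th)])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = float(np.hypot(a, b))
    phi = float(np.mod(np.degrees(np.arctan2(b, a)), 360.0))
    pred = np.cos(th - np.deg2rad(phi))
    if np.std(pred) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    return amp, phi, r


def polar_summary(results: list[OrientationResult]) -> pd.DataFrame:
    """Arrow table for a polar modulation plot.

    One row per unit per polarity; arrow length is the normalized
    modulation percent (100 = the no-change reference circle).
    """
    if not results:
        raise ValueError("no orientation results")
    rows = [
        {
            "unit_id": r.unit_id,
            "theta_deg": r.theta_deg,
            "polarity": pol,
            "arrow_length_percent": mod,
        }
        for r in results
        for pol, mod in r.mod_percent.items()
    ]
    return pd.DataFrame(rows)
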