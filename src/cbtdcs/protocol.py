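"""Stimulation protocols and current waveforms.

A tDCS session is a sequence of trapezoidal current pulses: a linear
ramp-in, a plateau at the target intensity, a linear ramp-out, and a rest
interval before the next pulse.  tACS sessions used for field calibration
are continuous low-frequency sinusoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimProtocol", "build_current_waveform"]

ANODAL = 1
CATHODAL = -1


@dataclass(frozen=True)
class StimProtocol:
    """Description of one tDCS/tACS stimulation session.

    Parameters
    ----------
    mode
        ``"tdcs"`` for trapezoidal direct-current pulses, ``"tacs"`` for a
        continuous sinusoid.
    polarity
        +1 (anodal) or -1 (cathodal); tDCS only.
    intensity_uA
        Peak current in microamperes (positive magnitude).
    ramp_s, plateau_s, rest_s
        Pulse phases in seconds.  The canonical pulse lasts
        ``2 * ramp_s + plateau_s`` = 15 s (5 s plateau) or 20 s (10 s
        plateau), separated by 10 s of rest.
    n_trials
        Number of pulses in the session.
    tacs_freq_hz
        Sinusoid frequency for tACS (1 Hz in the field-calibration design).
    sample_rate_hz
        Sampling rate used when the waveform is rendered to samples.
    """

    mode: str = "tdcs"
    polarity: int = ANODAL
    intensity_uA: float = 200.0
    ramp_s: float = 5.0
    plateau_s: float = 5.0
    rest_s: float = 10.0
    n_trials: int = 5
    tacs_freq_hz: float = 1.0
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in ("tdcs", "tacs"):
            raise ValueError(f"unknown stimulation mode {self.mode!r}")
        if self.mode == "tdcs" and self.polarity not in (ANODAL, CATHODAL):
            raise ValueError("polarity must be +1 (anodal) or -1 (cathodal)")
        if self.intensity_uA <= 0:
            raise ValueError("intensity_uA must be positive")
        if self.ramp_s <= 0 or self.plateau_s <= 0 or self.rest_s < 0:
            raise ValueError("ramp_s and plateau_s must be positive, rest_s >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def pulse_s(self) -> float:
        """Pulse duration: ramp-in + plateau + ramp-out."""
        return 2.0 * self.ramp_s + self.plateau_s

    @property
    def trial_period_s(self) -> float:
        """Pulse plus the rest interval that follows it."""
        return self.pulse_s + self.rest_s

    @property
    def duration_s(self) -> float:
        """Total session duration (tDCS: n_trials periods)."""
        return self.n_trials * self.trial_period_s

    def trial_onsets(self, lead_s: float = 0.0) -> np.ndarray:
        """Ramp-in times of each trial, after an optional lead-in rest."""
        return lead_s + np.arange(self.n_trials) * self.trial_period_s


def current_at(protocol: StimProtocol, t: np.ndarray) -> np.ndarray:
    """Signed instantaneous current (µA) at times ``t`` seconds.

    tDCS trials tile the session back to back starting at t=0; the pulse
    occupies the first ``pulse_s`` seconds of each period.
    """
    t = np.asarray(t, dtype=float)
    if protocol.mode == "tacs":
        return protocol.intensity_uA * np.sin(
            2.0 * np.pi * protocol.tacs_freq_hz * t
        )
    phase = np.mod(t, protocol.trial_period_s)
    n_full = np.floor_divide(t, protocol.trial_period_s)
    frac = _trapezoid_fraction(protocol, phase)
    # outside the session (t<0 or beyond the last trial) the current is 0
    frac = np.where((t < 0) | (n_full >= protocol.n_trials), 0.0, frac)
    return protocol.polarity * protocol.intensity_uA * frac


def _trapezoid_fraction(protocol: StimProtocol, phase: np.ndarray) -> np.ndarray:
    """Fractional current [0, 1] at time ``phase`` within one trial period."""
    r, p = protocol.ramp_s, protocol.plateau_s
    up = np.clip(phase / r, 0.0, 1.0)
    down = np.clip((2 * r + p - phase) / r, 0.0, 1.0)
    frac = np.minimum(up, down)
    return np.where(phase >= 2 * r + p, 0.0, frac)


def build_current_waveform(protocol: StimProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Render the session current trace.

    Returns
    -------
    t : ndarray
        Sample times in seconds.
    i_uA : ndarray
        Signed current in µA at each sample.  tDCS: trapezoidal pulses
        repeated ``n_trials`` times with rest gaps; tACS: a sinusoid of the
        same total duration.
    """
    n = int(round(protocol.duration_s * protocol.sample_rate_hz))
    t = np.arange(n) / protocol.sample_rate_hz
    return t, current_at(protocol, t)
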