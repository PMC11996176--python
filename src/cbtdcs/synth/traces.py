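"""Rendering of continuous extracellular voltage traces from event times.

Used to exercise the threshold-crossing detector end to end: a stereotyped
biphasic waveform is placed at each ground-truth spike time (scaled by the
per-event amplitude) on top of Gaussian background noise.  Overlapping
templates simply sum; saturation of near-coincident spikes is not modeled.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_spike_template", "render_extracellular_trace"]


def default_spike_template(
    sample_rate_hz: float, duration_ms: float = 2.0
) -> np.ndarray:
    """Biphasic extracellular waveform, peak-normalized to -1.

    A sharp negative deflection followed by a slower positive rebound,
    the classic shape of a soma-proximal extracellular spike.
    """
    n = max(int(round(duration_ms / 1000.0 * sample_rate_hz)), 5)
    t = np.arange(n) / sample_rate_hz * 1000.0  # ms
    neg = -np.exp(-0.5 * ((t - 0.4) / 0.12) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((t - 0.9) / 0.3) ** 2)
    w = neg + pos
    return w / np.abs(w.min())


def render_extracellular_trace(
    trains,
    waveform_templates=None,
    noise_sd: float = 20.0,
    sample_rate_hz: float = 25000.0,
    seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
) -> dict:
    """Sum spike templates at event times plus Gaussian noise.

    Parameters
    ----------
    trains
        List of (times_s, amplitudes_uV) pairs, one per unit.  Amplitudes
        scale the unit's template (whose peak is normalized to 1).
    waveform_templates
        Optional list of template arrays, one per train; defaults to the
        stereotyped biphasic shape for all units.
    noise_sd
        Background noise SD in µV.

    Returns a dict with the voltage trace (µV), sample times, and the
    ground-truth times per unit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trains = [(np.asarray(ts, float), np.asarray(amp, float)) for ts, amp in trains]
    if duration_s is None:
        t_max = max((ts[-1] for ts, _ in trains if len(ts)), default=0.0)
        duration_s = t_max + 0.01
    n = int(round(duration_s * sample_rate_hz))
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    if waveform_templates is None:
        waveform_templates = [default_spike_template(sample_rate_hz)] * len(trains)
    for (times, amps), tmpl in zip(trains, waveform_templates):
        tmpl = np.asarray(tmpl, float)
        idx = np.round(times * sample_rate_hz).astype(int)
        for i0, a in zip(idx, amps):
            j1 = min(i0 + len(tmpl), n)
            if i0 < n and j1 > i0:
                trace[i0 : j1] += a * tmpl[: j1 - i0]
    return {
        "trace_uV": trace,
        "t_s": np.arange(n) / sample_rate_hz,
        "sample_rate_hz": sample_rate_hz,
        "truth_times": [ts for ts, _ in trains],
    }
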