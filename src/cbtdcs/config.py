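"""Pipeline configuration: all tunable parameters with study defaults.

Defaults mirror the experimental design: 200 µA pulses with 5 s ramps,
5 s plateau and 10 s rest; 0.1 s SS PSTH bins and 1 s CS bins; 5 s
analysis windows; alpha 0.05; 1.5 ms refractory; at least three clean
trials per condition.  The field-law constants are the package's log-decay
calibration (first-millimetre mean 64.8 V/m at 200 µA).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cbtdcs.fieldlaw import FieldLawParams

__all__ = ["GeneratorConfig", "AnalysisConfig", "PipelineConfig"]


@dataclass
class GeneratorConfig:
    """Synthetic-session generator parameters."""

    n_pc_vermis: int = 6
    n_pc_crus: int = 6
    n_nonpc: int = 8
    intensities_uA: list = field(default_factory=lambda: [200.0])
    n_trials: int = 5
    plateau_s: float = 5.0
    rest_s: float = 10.0
    run_prob_per_trial: float = 0.1
    nonpc_mod_sd: float = 0.5
    nonpc_polarity_corr: float = 0.6
    gain_per_Vm: float = 0.01
    # rebound size/decay are qualitative placeholders (not quantified in
    # the literature this emulates); see docs/methods.md
    rebound_gain: float = 0.3
    rebound_tau_s: float = 2.0
    cs_modulated: bool = False
    lfp_duration_s: float = 10.0
    lfp_intensities_uA: list = field(default_factory=lambda: [2.0, 20.0, 200.0])
    field_alpha_Vm_per_uA: float = 0.4527
    field_beta_Vm_per_uA: float = 0.2169
    field_d0_mm: float = 0.5663
    field_noise_sd_frac: float = 0.05

    def field_params(self) -> FieldLawParams:
        return FieldLawParams(
            alpha_Vm_per_uA=self.field_alpha_Vm_per_uA,
            beta_Vm_per_uA=self.field_beta_Vm_per_uA,
            d0_mm=self.field_d0_mm,
            noise_sd_frac=self.field_noise_sd_frac,
        )


@dataclass
class AnalysisConfig:
    """Analysis-side parameters."""

    alpha: float = 0.05
    bin_ss_s: float = 0.1
    bin_cs_s: float = 1.0
    window_s: float = 5.0
    refractory_ms: float = 1.5
    min_trials: int = 3
    k_sd: float = 4.0
    dc_time_constant_s: float = 0.0007
    amplitude_window_s: float = 60.0
    amplitude_drift_threshold: float = 0.15
    pool_animals: bool = False
    bh_correction: bool = False
    per_trial_psth: bool = False
    dead_zone_cos: float = 0.1


@dataclass
class PipelineConfig:
    """Top-level configuration for a reproducible end-to-end run."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = GeneratorConfig(**d.get("generator", {}))
        ana = AnalysisConfig(**d.get("analysis", {}))
        return cls(seed=int(d.get("seed", 0)), generator=gen, analysis=ana)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
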