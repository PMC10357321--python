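"""Configuration objects for the synthetic generator and model fitting."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError

# Between-prime marginal SD of each channel's smooth variability, in the
# channel's own units.  W_V variability instead comes from peak-amplitude
# jitter (see synth module).
CHANNEL_SD: dict[str, float] = {
    "W_V": 80.0, "W_H": 25.0, "W_HT": 20.0, "G_A": 8.0,
    "T_X": 5.0, "T_Y": 5.0, "T_Z": 5.0,
    "I_X": 5.0, "I_Y": 5.0, "I_Z": 5.0,
    "FP_X": 0.06, "FP_Y": 0.06, "FP_Z": 0.06,
    "DP_X": 0.06, "DP_Y": 0.06, "DP_Z": 0.06,
}

#: Default intention effect sizes (SD units of the movement-averaged
#: channel): wrist height large, wrist horizontal trajectory moderate,
#: dorsum-plane y small, everything else uninformative.
DEFAULT_EFFECT_PROFILE: dict[str, float] = {"W_H": 4.0, "W_HT": 2.5, "DP_Y": 1.5}


@dataclass
class GeneratorConfig:
    n_primes_per_intention: int = 30
    n_perceivers: int = 20
    sample_rate: float = 100.0
    duration_range: tuple[float, float] = (0.84, 1.36)
    effect_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE)
    )
    trajectory_noise_sd: float = 0.05  # relative to each channel's SD
    readout_subspace: tuple[str, ...] = ("W_H", "W_HT")
    readout_gain_range: tuple[float, float] = (0.9, 1.8)
    readout_noise_sd: float = 0.02  # scaled by the perceiver's gain
    lapse_rate: float = 0.05
    rt_base_ms: float = 600.0
    rt_probe_effect_ms: float = 10.0
    rt_priming_gain_ms_per_logodds: float = 20.0
    rt_gamma_shape: float = 20.0
    fixation_base_logit: float = -1.0
    fixation_priming_gain: float = 0.5
    confidence_thresholds: tuple[float, float, float] = (0.5, 1.5, 3.0)
    congruent_fraction: float = 0.75
    n_priming_trials: int = 240
    n_discrimination_reps: int = 4
    error_rate: float = 0.02
    seed: int = 0
    # smoothness of the between-prime variability, in normalized-time units
    gp_length_scale: float = 0.1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_primes_per_intention", "n_perceivers", "n_priming_trials",
                     "n_discrimination_reps"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 < self.congruent_fraction < 1.0:
            raise ConfigurationError("congruent_fraction must lie in (0, 1)")
        th = tuple(self.confidence_thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ConfigurationError("confidence_thresholds must be strictly increasing")
        if self.rt_gamma_shape <= 0:
            raise ConfigurationError("rt_gamma_shape must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid duration_range")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ConfigurationError("lapse_rate must lie in [0, 1]")
        glo, ghi = self.readout_gain_range
        if glo > ghi:
            raise ConfigurationError("readout_gain_range must be ordered")
        unknown = set(self.effect_profile) - set(CHANNEL_SD)
        if unknown:
            raise ConfigurationError(f"unknown effect_profile variables: {sorted(unknown)}")
        unknown = set(self.readout_subspace) - set(CHANNEL_SD)
        if unknown:
            raise ConfigurationError(f"unknown readout_subspace variables: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("duration_range", "readout_subspace", "readout_gain_range",
                    "confidence_thresholds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RegularizationSpec:
    """Elastic-net settings shared by encoding and readout models."""

    alpha: float = 0.95
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-2
    lambdas: np.ndarray | None = None
    lambda_min: float | None = None
    cv_scheme: str = "leave-one-video-out"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.n_lambda < 2:
            raise ConfigurationError("n_lambda must be >= 2")
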