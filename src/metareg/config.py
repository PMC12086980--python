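"""Model and MCMC configuration.

``ModelConfig`` collects every knob of the meta-regression in one place so a
full analysis is reproducible from a single YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VALID_EFFECTS_MODES = ("random", "fixed")
VALID_OUTCOME_SUBSETS = ("all", "zbmi_only", "bmi_only", "zbmi_and_percentile")


@dataclass
class ModelConfig:
    """Configuration of the three-level meta-regression.

    Parameters
    ----------
    rho_time
        Correlation between residuals of the same comparison observed at
        different follow-up times. Default 0.8; sensitivity values 0.5 and
        0.95 are supported by simply changing this field.
    rho_arm
        Correlation between residuals of different comparisons that share a
        reference arm (the common-control induced correlation). Default 0.5,
        the equal-variance heuristic.
    effects_mode
        'random' includes a between-trial heterogeneity SD tau (Uniform(0,
        tau_upper) prior); 'fixed' fixes tau = 0.
    prior_coef_sd
        SD of the mean-zero normal prior on every regression coefficient, in
        zBMI units. 10 is effectively flat for effects of magnitude << 1.
    tau_upper
        Upper bound of the uniform prior on tau (zBMI units).
    chains, draws, warmup
        MCMC layout: independent chains, post-warmup draws per chain, and
        warmup iterations discarded per chain.
    seed
        Base seed; chain c uses seed + c.
    outcome_subset
        Restrict to observations originally reported on particular scales
        ('all', 'zbmi_only', 'bmi_only', 'zbmi_and_percentile').
    center
        Centre all covariates (including interactions) about their dataset
        mean before fitting. The intercept then represents the effect at
        mean indicator values.
    """

    rho_time: float = 0.8
    rho_arm: float = 0.5
    effects_mode: str = "random"
    prior_coef_sd: float = 10.0
    tau_upper: float = 2.0
    chains: int = 2
    draws: int = 2000
    warmup: int = 1000
    seed: int = 0
    outcome_subset: str = "all"
    center: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_time < 1.0:
            raise ValueError(f"rho_time must be in [0, 1), got {self.rho_time}")
        if not 0.0 <= self.rho_arm < 1.0:
            raise ValueError(f"rho_arm must be in [0, 1), got {self.rho_arm}")
        if self.effects_mode not in VALID_EFFECTS_MODES:
            raise ValueError(f"effects_mode must be one of {VALID_EFFECTS_MODES}")
        if self.outcome_subset not in VALID_OUTCOME_SUBSETS:
            raise ValueError(f"outcome_subset must be one of {VALID_OUTCOME_SUBSETS}")
        if self.prior_coef_sd <= 0 or self.tau_upper <= 0:
            raise ValueError("prior scales must be positive")
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("invalid MCMC layout")

    @property
    def tau_fixed(self) -> float | None:
        """Value tau is pinned to (0.0 in fixed-effects mode) or None."""
        return 0.0 if self.effects_mode == "fixed" else None

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
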