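"""Species life-history profiles used by the synthetic-data generator.

A :class:`SpeciesProfile` bundles the "true" parameter values a simulated
population is built from: a growth curve (with multiplicative lognormal size
error), an allometric disc-width–weight relationship, a logistic maturity
ogive, and an exponential age structure under total mortality Z with
knife-edge recruitment. The bundled defaults carry posterior-mean estimates
for the two Indian Ocean devil rays so downstream parameter-recovery tests
exercise realistic values.

Units: disc widths are millimetres internally; CSV/YAML I/O uses centimetres
(the convention of the width–weight literature). Weights are kg, ages years.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

VALID_GROWTH_MODELS = ("vb", "gompertz", "logistic", "lester")


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    growth_model: str  # vb | gompertz | logistic
    growth_coef: float  # k (vb) or g (sigmoid), per year
    dw0_mm: float  # disc width at age 0
    dwinf_mm: float  # asymptotic disc width
    sigma2_log: float  # variance of log disc width around the growth mean
    lw_log_a: float  # allometric log intercept, ln(kg) at DW = 1 cm
    lw_b: float  # allometric exponent
    lw_sigma2_log: float  # variance of ln weight around the allometric mean
    maturity_x50_age: float  # age at 50% maturity, years
    maturity_slope_age: float  # logistic slope per year
    maturity_x50_dw_cm: float  # DW at 50% maturity, cm
    maturity_slope_dw: float  # logistic slope per cm
    z_true: float  # total instantaneous mortality, per year
    recruit_age: int  # knife-edge full selectivity (peak age class)
    max_age: int  # truncation age for the simulated age structure
    sex_ratio: float = 0.5  # proportion female

    def __post_init__(self):
        if self.growth_model not in VALID_GROWTH_MODELS:
            raise ValueError(f"unknown growth model {self.growth_model!r}")
        if not (self.dwinf_mm > self.dw0_mm > 0):
            raise ValueError("require DWinf > DW0 > 0")
        if self.z_true <= 0:
            raise ValueError("Z_true must be positive")
        if not (0 <= self.recruit_age < self.max_age):
            raise ValueError("require 0 <= recruit_age < max_age")
        if self.sigma2_log < 0 or self.lw_sigma2_log < 0:
            raise ValueError("log-scale variances must be non-negative")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")

    @property
    def growth_params(self) -> dict:
        key = "k" if self.growth_model in ("vb", "lester") else "g"
        return {key: self.growth_coef, "dw0": self.dw0_mm, "dwinf": self.dwinf_mm}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesProfile":
        return cls(**yaml.safe_load(Path(path).read_text()))


def mobula_mobular() -> SpeciesProfile:
    """Spinetail devil ray defaults (von Bertalanffy growth, slow, large)."""
    return SpeciesProfile(
        name="Mobula mobular",
        growth_model="vb",
        growth_coef=0.05,
        dw0_mm=1166.53,
        dwinf_mm=3502.95,
        sigma2_log=0.12,
        lw_log_a=-9.26,
        lw_b=2.51,
        lw_sigma2_log=0.27,
        maturity_x50_age=8.2,
        maturity_slope_age=0.66,
        maturity_x50_dw_cm=204.0,
        maturity_slope_dw=0.07,
        z_true=0.215,
        recruit_age=3,
        max_age=18,
        sex_ratio=0.5,
    )


def mobula_thurstoni() -> SpeciesProfile:
    """Bentfin devil ray defaults (logistic growth, smaller-bodied)."""
    return SpeciesProfile(
        name="Mobula thurstoni",
        growth_model="logistic",
        growth_coef=0.19,
        dw0_mm=870.21,
        dwinf_mm=2022.11,
        sigma2_log=0.10,
        lw_log_a=-10.74,
        lw_b=2.84,
        lw_sigma2_log=0.23,
        maturity_x50_age=7.0,
        maturity_slope_age=0.66,
        maturity_x50_dw_cm=150.0,
        maturity_slope_dw=0.07,
        z_true=0.232,
        recruit_age=2,
        max_age=13,
        sex_ratio=0.57,
    )


BUILTIN_PROFILES = {
    "mobular": mobula_mobular,
    "thurstoni": mobula_thurstoni,
}
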