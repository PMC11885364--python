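"""Synthetic specimen tables, paired age reads, and catch-at-age structure.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without field data:

* ages follow a discrete (geometric) exponential decline under total
  mortality Z with knife-edge recruitment at the peak age class, optionally
  contaminated with pre-recruit ages to give catch curves an ascending limb;
* disc width at age is the species growth curve times multiplicative
  lognormal error;
* weight follows the allometric power law on the cm/kg scale with lognormal
  error;
* maturity is Bernoulli from a logistic ogive on age;
* paired reader band counts are the true age plus integer-ish read error,
  rounded to the nearest 0.5 year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .growth import growth_mean
from .profiles import SpeciesProfile

logger = logging.getLogger(__name__)

SPECIMEN_COLUMNS = [
    "id", "species", "country", "sex", "dw_cm", "weight_kg", "maturity", "gear", "date",
]
AGE_READ_COLUMNS = ["id", "reader", "section", "bands"]

_COUNTRIES = ["Indonesia", "Kenya", "Pakistan"]
_GEARS = ["gillnet", "gillnet", "gillnet", "gillnet", "longline", "handline"]


@dataclass
class SyntheticDataset:
    """Specimen table + (optional) age reads + the generating truth."""

    specimens: pd.DataFrame
    true_ages: np.ndarray
    profile: SpeciesProfile
    age_reads: pd.DataFrame | None = None

    def write_specimens(self, path: str | Path) -> None:
        self.specimens[SPECIMEN_COLUMNS].to_csv(path, index=False)

    def write_age_reads(self, path: str | Path) -> None:
        if self.age_reads is None:
            raise ValueError("dataset has no age reads; call simulate_age_reads first")
        self.age_reads[AGE_READ_COLUMNS].to_csv(path, index=False)


def simulate_ages(
    profile: SpeciesProfile,
    n: int,
    seed: int,
    pre_recruit_fraction: float = 0.15,
) -> np.ndarray:
    """Draw ``n`` integer true ages from the profile's age structure.

    Post-recruit ages follow P(age = recruit_age + x) proportional to
    exp(-Z * x), truncated at max_age. A ``pre_recruit_fraction`` of ages is
    drawn uniformly on the integer pre-recruit classes to emulate the
    ascending limb of a real catch curve.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= pre_recruit_fraction < 1.0):
        raise ValueError("pre_recruit_fraction must be in [0, 1)")
    rng = substream(seed, "simulate_ages")

    post_ages = np.arange(profile.recruit_age, profile.max_age + 1)
    w = np.exp(-profile.z_true * (post_ages - profile.recruit_age))
    w /= w.sum()

    if profile.recruit_age == 0:
        pre_recruit_fraction = 0.0
    n_pre = rng.binomial(n, pre_recruit_fraction)
    ages = np.empty(n, dtype=float)
    ages[: n - n_pre] = rng.choice(post_ages, size=n - n_pre, p=w)
    if n_pre:
        ages[n - n_pre:] = rng.integers(0, profile.recruit_age, size=n_pre)
    rng.shuffle(ages)
    return ages


def simulate_specimens(
    profile: SpeciesProfile, ages, seed: int
) -> SyntheticDataset:
    """Build a specimen table (sizes, weights, sex, maturity) from true ages."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    rng = substream(seed, "simulate_specimens")
    n = ages.size

    mean_dw_mm = growth_mean(profile.growth_model, profile.growth_params, ages)
    dw_mm = mean_dw_mm * np.exp(
        np.sqrt(profile.sigma2_log) * rng.standard_normal(n)
    )
    dw_cm = dw_mm / 10.0

    ln_w = profile.lw_log_a + profile.lw_b * np.log(dw_cm)
    weight_kg = np.exp(ln_w + np.sqrt(profile.lw_sigma2_log) * rng.standard_normal(n))

    p_mat = 1.0 / (
        1.0 + np.exp(-profile.maturity_slope_age * (ages - profile.maturity_x50_age))
    )
    maturity = (rng.random(n) < p_mat).astype(int)
    sex = np.where(rng.random(n) < profile.sex_ratio, "F", "M")

    species_tag = profile.name.split()[-1][:4]
    specimens = pd.DataFrame(
        {
            "id": [f"{species_tag}-{i:04d}" for i in range(1, n + 1)],
            "species": profile.name,
            "country": rng.choice(_COUNTRIES, size=n, p=[0.6, 0.2, 0.2]),
            "sex": sex,
            "dw_cm": np.round(dw_cm, 2),
            "weight_kg": np.round(weight_kg, 3),
            "maturity": maturity,
            "gear": rng.choice(_GEARS, size=n),
            "date": "2021-06-15",
        }
    )
    return SyntheticDataset(specimens=specimens, true_ages=ages, profile=profile)


def round_half_year(x):
    """Round to the nearest 0.5 year (bankers' rounding on the doubled value)."""
    return np.round(np.asarray(x, dtype=float) * 2.0) / 2.0


def simulate_age_reads(
    dataset: SyntheticDataset,
    readers: int = 2,
    sections_per_reader: int = 2,
    error_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per reader x section band counts: true age + normal read error, rounded
    to the nearest 0.5 year and floored at 0. Attaches the table to the dataset
    and returns it."""
    if readers < 1:
        raise ValueError("need at least one reader")
    if sections_per_reader < 1:
        raise ValueError("need at least one section per reader")
    if error_sd < 0:
        raise ValueError("error_sd must be non-negative")
    rng = substream(seed, "simulate_age_reads")

    ids = dataset.specimens["id"].to_numpy()
    true = dataset.true_ages
    rows = []
    for reader in range(1, readers + 1):
        for section in range(1, sections_per_reader + 1):
            noisy = true + error_sd * rng.standard_normal(true.size)
            bands = np.maximum(0.0, round_half_year(noisy))
            rows.append(
                pd.DataFrame(
                    {"id": ids, "reader": reader, "section": section, "bands": bands}
                )
            )
    reads = pd.concat(rows, ignore_index=True)
    dataset.age_reads = reads
    return reads


def load_specimens(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECIMEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    return df


def load_age_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(AGE_READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"age-read table missing columns: {sorted(missing)}")
    return df
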