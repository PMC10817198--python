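"""Synthetic country tables with known ground truth.

The generator emulates the World-Bank-style country indicator table the
pipeline consumes: per income group it draws Gini, household expenditure
per capita (HEpc), a GDPpc/HEpc ratio, and OOP share uniformly within
configured ranges, then computes each country's poverty headcounts
($1.90 and $3.20/day) and poverty gap ($2.15/day) in closed form from the
generating gamma model, optionally perturbed by truncated Gaussian noise.
Because the observed poverty statistics are (noisy images of) the exact
closed forms of the generating model, calibration and the full pipeline
can be validated against known ground truth.

The default roster is 20 LIC / 49 LMIC / 39 UMIC / 41 HIC countries
(149 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibrate import DAYS_PER_YEAR
from .income import GammaIncomeModel, make_income_model, poverty_gap, poverty_headcount
from .io import CountryRecord, INCOME_GROUPS, WHO_REGIONS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticCountrySet",
    "generate_countries",
    "sample_incomes",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ranges and sizes for the synthetic country generator.

    All ranges are (low, high) and sampled uniformly.  ``noise_sd`` is the
    standard deviation of the truncated Gaussian perturbation (truncated at
    3 SD, then clipped to [0, 1]) applied to the observed poverty
    statistics on the fraction scale.
    """

    seed: int
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"LIC": 20, "LMIC": 49, "UMIC": 39, "HIC": 41}
    )
    gini_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LIC": (0.30, 0.55),
            "LMIC": (0.30, 0.55),
            "UMIC": (0.30, 0.50),
            "HIC": (0.25, 0.45),
        }
    )
    hepc_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LIC": (300.0, 900.0),
            "LMIC": (800.0, 3000.0),
            "UMIC": (2500.0, 9000.0),
            "HIC": (8000.0, 40000.0),
        }
    )
    gdp_ratio_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LIC": (1.2, 2.2),
            "LMIC": (1.2, 2.2),
            "UMIC": (1.3, 2.4),
            "HIC": (1.3, 2.4),
        }
    )
    oop_share_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LIC": (0.30, 0.60),
            "LMIC": (0.30, 0.60),
            "UMIC": (0.20, 0.45),
            "HIC": (0.10, 0.25),
        }
    )
    population_range: tuple[float, float] = (1e6, 2e8)
    headcount_lines_per_day: tuple[float, float] = (1.90, 3.20)
    gap_line_per_day: float = 2.15
    noise_sd: float = 0.01
    data_year: int = 2020

    def __post_init__(self) -> None:
        for grp in self.n_per_group:
            if grp not in INCOME_GROUPS:
                raise ValueError(f"unknown income group {grp!r}")
        for name, ranges in (
            ("gini_range", self.gini_range),
            ("hepc_range", self.hepc_range),
            ("gdp_ratio_range", self.gdp_ratio_range),
            ("oop_share_range", self.oop_share_range),
        ):
            for grp, (lo, hi) in ranges.items():
                if not 0 < lo <= hi:
                    raise ValueError(f"{name}[{grp!r}]: invalid range ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for grp, (lo, hi) in self.gini_range.items():
            if hi >= 1:
                raise ValueError(f"gini_range[{grp!r}] must stay below 1")
        for grp, (lo, hi) in self.oop_share_range.items():
            if hi > 1:
                raise ValueError(f"oop_share_range[{grp!r}] must stay within [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Generating gamma model of one synthetic country."""

    mean: float
    shape: float
    scale: float

    @property
    def model(self) -> GammaIncomeModel:
        return GammaIncomeModel(shape=self.shape, scale=self.scale)


@dataclass(frozen=True)
class SyntheticCountrySet:
    """Generated records plus the generating models per country."""

    countries: tuple[CountryRecord, ...]
    ground_truth: Mapping[str, GroundTruth]


def _iso3_codes(n: int) -> list[str]:
    """Synthetic 3-letter codes ZAA, ZAB, ... (Z-prefix avoids real ISO codes)."""
    if n > 26 * 26:
        raise ValueError("too many synthetic countries requested")
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [f"Z{letters[i // 26]}{letters[i % 26]}" for i in range(n)]


def _draw_eps(rng: np.random.Generator, sd: float) -> float:
    """Gaussian perturbation truncated at 3 SD."""
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))


def _noisy(value: float, eps: float) -> float:
    return float(np.clip(value + eps, 0.0, 1.0))


def generate_countries(config: SyntheticConfig) -> SyntheticCountrySet:
    """Generate a synthetic country table; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    total = sum(config.n_per_group.values())
    codes = iter(_iso3_codes(total))
    line_lo, line_hi = (
        line * DAYS_PER_YEAR for line in config.headcount_lines_per_day
    )
    gap_line = config.gap_line_per_day * DAYS_PER_YEAR

    records: list[CountryRecord] = []
    truth: dict[str, GroundTruth] = {}
    for group in INCOME_GROUPS:
        for _ in range(config.n_per_group.get(group, 0)):
            iso3 = next(codes)
            gini = float(rng.uniform(*config.gini_range[group]))
            hepc = float(rng.uniform(*config.hepc_range[group]))
            ratio = float(rng.uniform(*config.gdp_ratio_range[group]))
            oop = float(rng.uniform(*config.oop_share_range[group]))
            population = float(rng.uniform(*config.population_range))
            region = str(rng.choice(WHO_REGIONS))
            pct_urban = float(rng.uniform(0.2, 0.95))

            model = make_income_model(hepc, gini)
            # one shared perturbation for both headcounts keeps the
            # $3.20 >= $1.90 ordering intact under noise
            eps_hc = _draw_eps(rng, config.noise_sd)
            eps_gap = _draw_eps(rng, config.noise_sd)
            rec = CountryRecord(
                iso3=iso3,
                name=f"Synthetic {iso3}",
                income_group=group,
                who_region=region,
                population=population,
                gini=gini,
                hepc=hepc,
                gdp_pc=hepc * ratio,
                oop_share=oop,
                pov_headcount_190=_noisy(poverty_headcount(model, line_lo), eps_hc),
                pov_headcount_320=_noisy(poverty_headcount(model, line_hi), eps_hc),
                pov_gap_215=_noisy(poverty_gap(model, gap_line), eps_gap),
                pct_urban=pct_urban,
                data_year=config.data_year,
            )
            records.append(rec)
            truth[iso3] = GroundTruth(
                mean=model.mean, shape=model.shape, scale=model.scale
            )
    return SyntheticCountrySet(countries=tuple(records), ground_truth=truth)


def sample_incomes(model: GammaIncomeModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` incomes from the gamma model; deterministic given ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    return rng.gamma(model.shape, model.scale, size=n)
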