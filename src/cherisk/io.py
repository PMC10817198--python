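"""Country tables, run configuration, the pipeline driver, and result writers.

The country table is a UTF-8 comma-separated file with a header row; column
names are matched case-insensitively.  Mandatory columns: iso3, name,
income_group, who_region, population, gini, hepc, oop_share,
pov_headcount_190, pov_headcount_320.  Optional: gdp_pc, pov_gap_215,
pct_urban, data_year.  Fraction-valued columns supplied on the percent
scale (e.g. a Gini of 35) are auto-detected per column and converted, with
a logged warning; individual rows violating the record invariants are
rejected with per-row diagnostics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .aggregate import GroupSummary, group_summaries
from .calibrate import GridConfig, choose_proxy
from .che import RiskCell, ScenarioSpec, country_risk_profile

__all__ = [
    "CountryRecord",
    "RunConfig",
    "INCOME_GROUPS",
    "WHO_REGIONS",
    "read_country_table",
    "write_country_table",
    "run_pipeline",
    "write_results",
    "cells_to_frame",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

INCOME_GROUPS: tuple[str, ...] = ("LIC", "LMIC", "UMIC", "HIC")
WHO_REGIONS: tuple[str, ...] = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")

_MANDATORY_COLUMNS = (
    "iso3",
    "name",
    "income_group",
    "who_region",
    "population",
    "gini",
    "hepc",
    "oop_share",
    "pov_headcount_190",
    "pov_headcount_320",
)
_OPTIONAL_COLUMNS = ("gdp_pc", "pov_gap_215", "pct_urban", "data_year")
#: columns on the fraction scale, eligible for percent-scale auto-detection
_FRACTION_COLUMNS = (
    "gini",
    "oop_share",
    "pov_headcount_190",
    "pov_headcount_320",
    "pov_gap_215",
    "pct_urban",
)


@dataclass(frozen=True)
class CountryRecord:
    """One country's indicators, the unit of input to the pipeline."""

    iso3: str
    name: str
    income_group: str
    who_region: str
    population: float
    gini: float
    hepc: float
    oop_share: float
    pov_headcount_190: float
    pov_headcount_320: float
    gdp_pc: Optional[float] = None
    pov_gap_215: Optional[float] = None
    pct_urban: Optional[float] = None  # carried for completeness, unused
    data_year: Optional[int] = None

    def problems(self) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        out = []
        if len(self.iso3) != 3:
            out.append(f"iso3={self.iso3!r} is not a 3-letter code")
        if self.income_group not in INCOME_GROUPS:
            out.append(f"income_group={self.income_group!r} not in {INCOME_GROUPS}")
        if self.who_region not in WHO_REGIONS:
            out.append(f"who_region={self.who_region!r} not in {WHO_REGIONS}")
        if not self.population > 0:
            out.append(f"population={self.population!r} must be positive")
        if not 0 < self.gini < 1:
            out.append(f"gini={self.gini!r} must be in (0, 1)")
        if not self.hepc > 0:
            out.append(f"hepc={self.hepc!r} must be positive")
        if not 0 <= self.oop_share <= 1:
            out.append(f"oop_share={self.oop_share!r} must be in [0, 1]")
        for fname in ("pov_headcount_190", "pov_headcount_320", "pov_gap_215"):
            v = getattr(self, fname)
            if v is not None and not 0 <= v <= 1:
                out.append(f"{fname}={v!r} must be in [0, 1]")
        return out

    def validate(self) -> None:
        problems = self.problems()
        if problems:
            raise ValueError(f"country {self.iso3}: " + "; ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run."""

    cost: float = 200.0
    threshold: float = 0.10
    multipliers: tuple[float, ...] = (1.0, 0.7, 0.5, 0.3, 0.1)
    weighting: str = "equal"
    calibrate: bool = False
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 0
    rounding: int = 3

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ValueError("rounding digits must be >= 0")
        self.scenario_spec()  # validates cost/threshold/multipliers

    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            cost=self.cost, threshold=self.threshold, multipliers=self.multipliers
        )


def _coerce_optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_country_table(path: str | Path) -> list[CountryRecord]:
    """Read and validate a country table; invalid rows are dropped with warnings."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: table has no rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")

    # percent-scale auto-detection: a fraction column where most values
    # exceed 1 was supplied as percentages
    for col in _FRACTION_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if len(vals) and (vals > 1).mean() > 0.5:
            logger.warning(
                "%s: column %r looks percent-scaled (median %.3g); dividing by 100",
                path, col, float(vals.median()),
            )
            df[col] = pd.to_numeric(df[col], errors="coerce") / 100.0

    records: list[CountryRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = CountryRecord(
                iso3=str(row["iso3"]).strip(),
                name=str(row["name"]).strip(),
                income_group=str(row["income_group"]).strip().upper(),
                who_region=str(row["who_region"]).strip().upper(),
                population=float(row["population"]),
                gini=float(row["gini"]),
                hepc=float(row["hepc"]),
                oop_share=float(row["oop_share"]),
                pov_headcount_190=float(row["pov_headcount_190"]),
                pov_headcount_320=float(row["pov_headcount_320"]),
                gdp_pc=_coerce_optional(row.get("gdp_pc")),
                pov_gap_215=_coerce_optional(row.get("pov_gap_215")),
                pct_urban=_coerce_optional(row.get("pct_urban")),
                data_year=(
                    int(row["data_year"])
                    if "data_year" in df.columns and pd.notna(row.get("data_year"))
                    else None
                ),
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s: row %d rejected: %s", path, idx + 2, exc)
            continue
        problems = rec.problems()
        if problems:
            logger.warning(
                "%s: row %d (%s) rejected: %s",
                path, idx + 2, rec.iso3, "; ".join(problems),
            )
            continue
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records


def write_country_table(records: Sequence[CountryRecord], path: str | Path) -> None:
    """Write records in the same CSV format ``read_country_table`` reads."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False)


def run_pipeline(
    countries: Sequence[CountryRecord], config: RunConfig = RunConfig()
) -> tuple[list[RiskCell], list[GroupSummary]]:
    """Run the full analysis: optional calibration, per-country risk, grouping.

    Returns the per-country risk cells and the group summaries for both
    groupings (World Bank income level and WHO region) concatenated;
    deterministic given ``config``.
    """
    if not countries:
        raise ValueError("at least one valid country is required")
    for rec in countries:
        rec.validate()

    if config.calibrate:
        calibrated = []
        for rec in countries:
            result = choose_proxy(rec, config.grid)
            calibrated.append(dataclasses.replace(rec, hepc=result.chosen_mean))
        countries = calibrated

    spec = config.scenario_spec()
    cells: list[RiskCell] = []
    for rec in countries:
        try:
            cells.extend(country_risk_profile(rec, spec))
        except ValueError as exc:
            raise ValueError(f"country {rec.iso3}: {exc}") from exc

    summaries: list[GroupSummary] = []
    for grouping in ("wb_income", "who_region"):
        summaries.extend(
            group_summaries(cells, countries, grouping, config.weighting)
        )
    return cells, summaries


def cells_to_frame(cells: Sequence[RiskCell]) -> pd.DataFrame:
    """Long-format DataFrame of per-country cells, values unrounded."""
    return pd.DataFrame([dataclasses.asdict(c) for c in cells])


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def _pivot(
    frame: pd.DataFrame, value: str, rounding: int, drop_baseline: bool
) -> pd.DataFrame:
    """Wide layout: one row per (grouping, group, quintile), one column per scenario."""
    df = frame
    if drop_baseline:
        df = df[df["scenario"] != "baseline"]
    wide = df.pivot_table(
        index=["grouping", "group", "quintile"],
        columns="scenario",
        values=value,
        sort=False,
    )
    # baseline first, then descending multiplier order
    order = [c for c in ("baseline", "70%", "50%", "30%", "10%") if c in wide.columns]
    extra = [c for c in wide.columns if c not in order]
    return wide[order + extra].round(rounding).reset_index()


def write_results(
    cells: Sequence[RiskCell],
    summaries: Sequence[GroupSummary],
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
    n_warnings: int = 0,
) -> list[Path]:
    """Write the per-country cell file, the presentation tables, and metadata.

    The cell file keeps full precision; the group tables (risk and
    protection in the two-table layout) are rounded to ``config.rounding``
    digits, so protection always equals the difference of unrounded risks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_frame = summaries_to_frame(summaries)

    paths = {
        "cells": out_dir / "risk_cells.csv",
        "risk": out_dir / "risk_by_group.csv",
        "protection": out_dir / "protection_by_group.csv",
        "meta": out_dir / "run_metadata.yaml",
    }
    cells_to_frame(cells).to_csv(paths["cells"], index=False)
    _pivot(summary_frame, "mean_risk", config.rounding, drop_baseline=False).to_csv(
        paths["risk"], index=False
    )
    _pivot(
        summary_frame, "mean_protected", config.rounding, drop_baseline=True
    ).to_csv(paths["protection"], index=False)

    meta = {
        "config": {
            "cost": config.cost,
            "threshold": config.threshold,
            "multipliers": list(config.multipliers),
            "weighting": config.weighting,
            "calibrate": config.calibrate,
            "grid": dataclasses.asdict(config.grid),
            "seed": config.seed,
            "rounding": config.rounding,
        },
        "versions": {
            "cherisk": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_countries": int(cells_to_frame(cells)["country"].nunique()),
        "n_warnings": int(n_warnings),
    }
    with open(paths["meta"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return list(paths.values())


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("cherisk")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
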