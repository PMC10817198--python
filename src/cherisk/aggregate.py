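"""Group-level aggregation of per-country CHE risk and protection.

Country-level risk cells are averaged within World Bank income groups or
WHO regions, per quintile and scenario, with the standard error of the
mean (sample SD / sqrt(n)) as the dispersion measure.  The default treats
each country as one observation (equal weights); population weighting is
available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .che import RiskCell
    from .io import CountryRecord

__all__ = ["GroupSummary", "group_summaries", "equity_gap"]

logger = logging.getLogger(__name__)

GROUPINGS = ("wb_income", "who_region")


@dataclass(frozen=True)
class GroupSummary:
    """Mean risk/protection with SEM for one (group, quintile, scenario)."""

    grouping: str  # "wb_income" or "who_region"
    group: str
    quintile: str
    scenario: str
    mean_risk: float
    mean_protected: float
    sem: float
    sem_protected: float
    n_countries: int


def _weighted_mean_sem(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and SEM; reduces to mean and SD/sqrt(n) for equal weights.

    Uses the frequency-reliability-corrected weighted variance
    var = sum w (x-m)^2 / (1 - sum w^2) with normalized weights, and
    SEM = sqrt(var * sum w^2); with w = 1/n this is the n-1 sample
    SD / sqrt(n) exactly.
    """
    w = weights / weights.sum()
    m = float(np.sum(w * values))
    sw2 = float(np.sum(w**2))
    if len(values) == 1 or sw2 >= 1.0 - 1e-15:
        return m, 0.0
    var = float(np.sum(w * (values - m) ** 2) / (1.0 - sw2))
    return m, math.sqrt(max(var, 0.0) * sw2)


def group_summaries(
    cells: Iterable["RiskCell"],
    countries: Sequence["CountryRecord"],
    grouping: str = "wb_income",
    weighting: str = "equal",
) -> list[GroupSummary]:
    """Aggregate risk cells into group x quintile x scenario summaries.

    Parameters
    ----------
    cells
        Per-country risk cells (one per country x quintile x scenario).
    countries
        The country records the cells refer to; supplies the group labels
        and populations.
    grouping
        "wb_income" (LIC/LMIC/UMIC/HIC) or "who_region" (AFR..WPR).
    weighting
        "equal" (each country one observation; default) or "population".
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    if weighting not in ("equal", "population"):
        raise ValueError(f"weighting must be 'equal' or 'population', got {weighting!r}")

    cells = list(cells)
    by_iso = {c.iso3: c for c in countries}
    buckets: dict[tuple[str, str, str], list[tuple[float, float, float]]] = {}
    unknown = sorted({cell.country for cell in cells if cell.country not in by_iso})
    if unknown:
        raise ValueError(f"risk cells reference unknown countries: {unknown}")
    for cell in cells:
        rec = by_iso[cell.country]
        group = rec.income_group if grouping == "wb_income" else rec.who_region
        key = (group, cell.quintile, cell.scenario)
        prot = 0.0 if cell.protected is None else cell.protected
        buckets.setdefault(key, []).append((cell.risk, prot, rec.population))

    quintile_rank = {
        q: i for i, q in enumerate(
            ("overall", "poorest", "poor", "middle", "rich", "richest")
        )
    }
    scenario_rank = {
        s: i for i, s in enumerate(("baseline", "70%", "50%", "30%", "10%"))
    }

    def order(item):
        group, quintile, scenario = item[0]
        return (
            group,
            quintile_rank.get(quintile, len(quintile_rank)), quintile,
            scenario_rank.get(scenario, len(scenario_rank)), scenario,
        )

    out: list[GroupSummary] = []
    for (group, quintile, scenario), rows in sorted(buckets.items(), key=order):
        risks = np.array([r for r, _, _ in rows])
        prots = np.array([p for _, p, _ in rows])
        if weighting == "population":
            weights = np.array([pop for _, _, pop in rows], dtype=float)
        else:
            weights = np.ones(len(rows))
        mean_risk, sem = _weighted_mean_sem(risks, weights)
        mean_prot, sem_prot = _weighted_mean_sem(prots, weights)
        if len(rows) == 1:
            logger.warning(
                "group %s/%s/%s has a single country; SEM reported as 0",
                group, quintile, scenario,
            )
        out.append(
            GroupSummary(
                grouping=grouping,
                group=group,
                quintile=quintile,
                scenario=scenario,
                mean_risk=mean_risk,
                mean_protected=mean_prot,
                sem=sem,
                sem_protected=sem_prot,
                n_countries=len(rows),
            )
        )
    return out


def equity_gap(
    summaries: Sequence[GroupSummary], group: str, scenario: str = "baseline"
) -> float:
    """Poorest-minus-richest mean risk for a group/scenario, in percentage points."""
    by_quintile = {
        s.quintile: s for s in summaries if s.group == group and s.scenario == scenario
    }
    missing = {"poorest", "richest"} - set(by_quintile)
    if missing:
        raise ValueError(
            f"no {sorted(missing)} cells for group {group!r}, scenario {scenario!r}"
        )
    return 100.0 * (by_quintile["poorest"].mean_risk - by_quintile["richest"].mean_risk)
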