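"""Catastrophic health expenditure (CHE) risk under OOP-reduction scenarios.

A household incurs CHE when its out-of-pocket (OOP) payment for a surgical
procedure is at least a threshold share t (default 10%) of its income y:
``oop_paid >= t * y``.  Under a gamma income law the population risk is the
distribution's CDF evaluated at ``oop_paid / t``.  The baseline OOP payment
is the country's OOP share of health expenditure times the unit procedure
cost (default $200); reduction scenarios multiply that payment by
0.7 / 0.5 / 0.3 / 0.1.  Protection is baseline risk minus scenario risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

from .income import GammaIncomeModel, quintile_models

if TYPE_CHECKING:  # pragma: no cover
    from .io import CountryRecord

__all__ = [
    "ScenarioSpec",
    "RiskCell",
    "QUINTILE_LABELS",
    "OVERALL_LABEL",
    "scenario_label",
    "che_risk",
    "scenario_oop",
    "protection",
    "country_risk_profile",
]

QUINTILE_LABELS: tuple[str, ...] = ("poorest", "poor", "middle", "rich", "richest")
OVERALL_LABEL = "overall"


def scenario_label(multiplier: float) -> str:
    """Human label for an OOP multiplier: 1.0 -> 'baseline', 0.7 -> '70%'."""
    if multiplier == 1.0:
        return "baseline"
    return f"{round(multiplier * 100):g}%"


@dataclass(frozen=True)
class ScenarioSpec:
    """Unit cost, CHE threshold, and the ordered OOP multipliers."""

    cost: float = 200.0
    threshold: float = 0.10
    multipliers: tuple[float, ...] = (1.0, 0.7, 0.5, 0.3, 0.1)

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"cost must be non-negative, got {self.cost!r}")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold!r}")
        if not self.multipliers or self.multipliers[0] != 1.0:
            raise ValueError("multipliers must start with the baseline 1.0")
        if any(not 0 < m <= 1 for m in self.multipliers):
            raise ValueError("multipliers must lie in (0, 1]")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(scenario_label(m) for m in self.multipliers)


@dataclass(frozen=True)
class RiskCell:
    """One country x quintile x scenario result."""

    country: str
    quintile: str  # one of QUINTILE_LABELS or "overall"
    scenario: str
    risk: float
    expected_count: float
    protected: Optional[float] = None  # None for the baseline scenario

    def __post_init__(self) -> None:
        if not 0 <= self.risk <= 1:
            raise ValueError(f"risk must be in [0, 1], got {self.risk!r}")


def che_risk(model: GammaIncomeModel, oop_paid: float, threshold: float) -> float:
    """Population share incurring CHE: P(income <= oop_paid / threshold)."""
    if oop_paid < 0:
        raise ValueError(f"oop_paid must be non-negative, got {oop_paid!r}")
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    return model.cdf(oop_paid / threshold)


def scenario_oop(baseline_share: float, multiplier: float, cost: float) -> float:
    """Household OOP payment (USD) under a reduction scenario.

    ``multiplier * baseline_share * cost`` — the scenario pays the stated
    fraction of the baseline OOP payment, not a new OOP share.
    """
    if baseline_share < 0 or baseline_share > 1:
        raise ValueError(f"baseline_share must be in [0, 1], got {baseline_share!r}")
    if multiplier < 0 or multiplier > 1:
        raise ValueError(f"multiplier must be in [0, 1], got {multiplier!r}")
    if cost < 0:
        raise ValueError(f"cost must be non-negative, got {cost!r}")
    return multiplier * baseline_share * cost


def protection(baseline_risk: float, scenario_risk: float) -> float:
    """Population share protected from CHE: baseline risk minus scenario risk."""
    for r in (baseline_risk, scenario_risk):
        if not 0 <= r <= 1:
            raise ValueError(f"risks must be in [0, 1], got {r!r}")
    return baseline_risk - scenario_risk


def country_risk_profile(
    country: "CountryRecord", spec: ScenarioSpec = ScenarioSpec()
) -> list[RiskCell]:
    """CHE risk for every quintile x scenario of one country.

    Builds the pegged quintile models from the country's HEpc and Gini,
    evaluates the risk at each OOP multiplier, appends an unweighted
    "overall" cell per scenario (mean of the five quintile risks), and the
    protection relative to baseline for non-baseline scenarios.
    ``expected_count`` is ``population/5 * risk`` per quintile and
    ``population * risk`` for the overall cell.
    """
    country.validate()
    quintiles = quintile_models(country.hepc, country.gini)
    cells: list[RiskCell] = []
    baseline_by_quintile: dict[str, float] = {}
    for multiplier in spec.multipliers:
        label = scenario_label(multiplier)
        oop_paid = scenario_oop(country.oop_share, multiplier, spec.cost)
        risks = [
            che_risk(model, oop_paid, spec.threshold) for model in quintiles.members
        ]
        for qlabel, risk in zip(QUINTILE_LABELS, risks):
            if multiplier == 1.0:
                baseline_by_quintile[qlabel] = risk
                prot = None
            else:
                prot = protection(baseline_by_quintile[qlabel], risk)
            cells.append(
                RiskCell(
                    country=country.iso3,
                    quintile=qlabel,
                    scenario=label,
                    risk=risk,
                    expected_count=country.population / 5.0 * risk,
                    protected=prot,
                )
            )
        overall = sum(risks) / len(risks)
        if multiplier == 1.0:
            baseline_by_quintile[OVERALL_LABEL] = overall
            prot = None
        else:
            prot = protection(baseline_by_quintile[OVERALL_LABEL], overall)
        cells.append(
            RiskCell(
                country=country.iso3,
                quintile=OVERALL_LABEL,
                scenario=label,
                risk=overall,
                expected_count=country.population * overall,
                protected=prot,
            )
        )
    return cells
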