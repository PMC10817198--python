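"""Gamma income distributions parameterized by Gini index and mean income.

A country's income distribution is modeled as a gamma law whose shape
``alpha`` is determined by the Gini index alone and whose scale ``beta``
carries the mean (household expenditure per capita, USD per person-year).
For a gamma distribution the Gini coefficient has the closed form

    G(alpha) = Gamma(alpha + 1/2) / (Gamma(alpha + 1) * sqrt(pi)),

which is strictly decreasing in ``alpha`` (more shape mass = less
inequality) and equals exactly 1/2 at ``alpha = 1`` (the exponential
distribution).  Quintile sub-populations share the country shape with
means pegged to {0.1, 0.3, 0.5, 0.7, 0.9} times the country mean.

All incomes are annual USD per capita; no purchasing-power-parity
conversion is applied anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import special

__all__ = [
    "GammaIncomeModel",
    "QuintileSet",
    "DEFAULT_PEG_FACTORS",
    "shape_to_gini",
    "gini_to_shape",
    "make_income_model",
    "quintile_models",
    "poverty_headcount",
    "poverty_gap",
]

#: Quintile mean multipliers, poorest -> richest.
DEFAULT_PEG_FACTORS: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)

#: Accepted Gini range; out-of-range inputs error rather than clamp.
GINI_MIN = 0.01
GINI_MAX = 0.99

#: Bisection bracket for the shape parameter and tolerance on Gini.
#: Gini ~ 1/sqrt(pi*shape) for large shape, so the bracket must reach
#: ~3.2e3 to represent Gini = 0.01.
_SHAPE_LO = 1e-3
_SHAPE_HI = 1e4
_GINI_TOL = 1e-10


def shape_to_gini(shape: float) -> float:
    """Gini coefficient of a gamma distribution with the given shape.

    Computed in log-space as exp(lgamma(a+1/2) - lgamma(a+1) - log(pi)/2)
    for stability at large shape.  Strictly decreasing in ``shape``;
    ``shape_to_gini(1.0) == 0.5`` exactly up to floating point.
    """
    if not shape > 0:
        raise ValueError(f"shape must be positive, got {shape!r}")
    return float(
        math.exp(
            special.gammaln(shape + 0.5)
            - special.gammaln(shape + 1.0)
            - 0.5 * math.log(math.pi)
        )
    )


def gini_to_shape(gini: float) -> float:
    """Invert the gamma Gini identity by bisection.

    Parameters
    ----------
    gini
        Target Gini coefficient, required to lie in [0.01, 0.99].

    Returns
    -------
    Shape ``alpha`` with ``|shape_to_gini(alpha) - gini| <= 1e-10``.
    """
    if not (GINI_MIN <= gini <= GINI_MAX):
        raise ValueError(
            f"gini must be within [{GINI_MIN}, {GINI_MAX}], got {gini!r}"
        )
    lo, hi = _SHAPE_LO, _SHAPE_HI  # g(lo) > gini > g(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = shape_to_gini(mid)
        if abs(g - gini) <= _GINI_TOL:
            return mid
        if g > gini:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class GammaIncomeModel:
    """Gamma income law: shape ``alpha`` (dimensionless), scale ``beta`` (USD/yr)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"shape must be positive, got {self.shape!r}")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale!r}")

    @property
    def mean(self) -> float:
        """Mean income, USD per person-year (= shape * scale)."""
        return self.shape * self.scale

    @property
    def gini(self) -> float:
        """Gini coefficient implied by the shape."""
        return shape_to_gini(self.shape)

    def cdf(self, x: float) -> float:
        """P(income <= x): regularized lower incomplete gamma."""
        if x <= 0:
            return 0.0
        return float(special.gammainc(self.shape, x / self.scale))


def make_income_model(mean_income: float, gini: float) -> GammaIncomeModel:
    """Build the gamma income model with the given mean and Gini index."""
    if not mean_income > 0:
        raise ValueError(f"mean_income must be positive, got {mean_income!r}")
    shape = gini_to_shape(gini)
    return GammaIncomeModel(shape=shape, scale=mean_income / shape)


@dataclass(frozen=True)
class QuintileSet:
    """Five gamma models sharing one shape, means pegged to the base mean.

    ``members`` are ordered poorest -> richest with means equal to
    ``peg_factors * base_mean``.
    """

    base_mean: float
    members: tuple[GammaIncomeModel, ...]
    peg_factors: tuple[float, ...] = field(default=DEFAULT_PEG_FACTORS)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.peg_factors):
            raise ValueError("one member per peg factor required")
        shapes = {m.shape for m in self.members}
        if len(shapes) != 1:
            raise ValueError("quintile members must share a single shape")
        means = [m.mean for m in self.members]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("quintile means must be strictly increasing")


def quintile_models(
    base_mean: float,
    gini: float,
    peg_factors: tuple[float, ...] = DEFAULT_PEG_FACTORS,
) -> QuintileSet:
    """Quintile income models: shared shape from ``gini``, pegged means."""
    if not base_mean > 0:
        raise ValueError(f"base_mean must be positive, got {base_mean!r}")
    shape = gini_to_shape(gini)
    members = tuple(
        GammaIncomeModel(shape=shape, scale=f * base_mean / shape)
        for f in peg_factors
    )
    return QuintileSet(base_mean=base_mean, members=members, peg_factors=peg_factors)


def poverty_headcount(model: GammaIncomeModel, line: float) -> float:
    """Fraction of the population with income below ``line`` (USD/yr)."""
    if line < 0:
        raise ValueError(f"poverty line must be non-negative, got {line!r}")
    return model.cdf(line)


def poverty_gap(model: GammaIncomeModel, line: float) -> float:
    """FGT-1 poverty gap: mean relative shortfall below ``line``.

    E[max(0, (z - y)/z)] under a gamma law has the closed form
    F(z; a, b) - (mean/z) * F(z; a+1, b), with F the regularized lower
    incomplete gamma CDF.
    """
    if not line > 0:
        raise ValueError(f"poverty line must be positive, got {line!r}")
    z = line / model.scale
    f1 = float(special.gammainc(model.shape, z))
    f2 = float(special.gammainc(model.shape + 1.0, z))
    return f1 - (model.mean / line) * f2
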