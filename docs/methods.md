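# Methods

## The income model

Each country's per-capita income distribution is modeled as a gamma law
Γ(α, β). The model has exactly two degrees of freedom and is pinned by two
published indicators:

- **Inequality → shape.** For a gamma distribution the Gini coefficient
  depends on the shape alone: G(α) = Γ(α+½)/(Γ(α+1)√π). The function is
  strictly decreasing, G(1) = ½ (exponential incomes), G(α) ≈ 1/√(πα) for
  large α. The inverse is computed by bisection on the bracket
  α ∈ [10⁻³, 10⁴] to a tolerance of 10⁻¹⁰ on the Gini; the bracket upper
  end must reach ~3.2·10³ so that the whole accepted Gini range
  [0.01, 0.99] is invertible. Out-of-range Gini inputs raise an error
  rather than being clamped — silent clamping would hide bad data.
- **Level → scale.** β = mean/α, with the mean taken from household
  expenditure per capita (HEpc, USD per person-year). HEpc, not GDP per
  capita, is the income proxy for the headline analysis; GDP per capita is
  retained as an alternative proxy for the calibration stage. All incomes
  are annual USD per capita; **no purchasing-power-parity conversion is
  applied anywhere**, and no household-size equivalization is attempted.

Wealth quintiles are represented by five gamma laws that share the country
shape and have means pegged to {0.1, 0.3, 0.5, 0.7, 0.9} × HEpc. The pegs
are applied exactly as multipliers of the country mean; note they average
to 0.5 × HEpc, not HEpc, so the quintile construction is a stylized
inequality profile rather than a partition of the country distribution.

Poverty statistics have closed forms under the gamma law: the headcount at
line z is the regularized lower incomplete gamma CDF F(z; α, β), and the
FGT-1 poverty gap is F(z; α, β) − (mean/z)·F(z; α+1, β). Poverty lines
quoted per day are annualized by × 365 ($2.15/day → $784.75/yr).

## CHE risk and OOP scenarios

A household with income y incurs catastrophic health expenditure (CHE)
when its out-of-pocket payment is at least t·y, with threshold t = 0.10 by
default. The baseline OOP payment is (OOP share) × (unit cost), with a
unit procedure cost of $200 — a mid-range estimate for a pediatric
surgical procedure in low-income settings; published unit costs for common
procedures span roughly $130–$480, so the default is conservative. The
population risk is the income CDF at (payment)/t, and the expected number
of affected people is population share × risk.

Reduction scenarios **multiply the baseline payment** by 0.7, 0.5, 0.3 or
0.1; they do not set the OOP *share* to those values. The multiplier
reading is the only one under which risk falls monotonically at every
level for every country, including countries whose baseline OOP share is
already below 70%. Protection is baseline risk minus scenario risk, always
non-negative for multipliers ≤ 1. The weak inequality (payment ≥ t·y)
defines CHE; the boundary has measure zero under the continuous model, so
the choice is inconsequential.

Per country the pipeline emits 6 × 5 cells (five quintiles plus an
"overall" row, five scenarios). The overall cell is the **unweighted mean
of the five quintile risks** — the construction under which the overall
row of a quintile table equals the average of its quintile rows exactly.

## Calibration

The income proxy may misstate the mean of the distribution that generated
a country's observed poverty statistics. The calibration stage scans 41
log-spaced candidate means spanning [0.25, 4] × the proxy value (adjacent
candidates differ by ≈ 7.2%), evaluates the closed-form $1.90/day
headcount at each, and selects the candidate minimizing the absolute
headcount error, ties broken toward the larger mean (a larger mean is the
conservative, lower-risk reading). The $2.15/day poverty gap is evaluated
at the selected candidate and enters the reported residual
|Δheadcount| + |Δgap| as the accuracy check. Both the HEpc-based and the
GDPpc-based grids are calibrated; the proxy with the smaller residual is
flagged selected, ties going to HEpc. When the $2.15 gap is unavailable
the residual degrades to the headcount term alone, with a logged warning.

Selection uses closed forms because they are deterministic and exact; a
Monte Carlo routine that averages empirical headcounts and gaps over 25
replicate samples is provided as a stochastic cross-check of those closed
forms, not as the selection path. No inconsistency threshold is imposed:
residuals are reported and the cutoff is left to the user.

**Identifiability limitation.** The $1.90/day headcount is nearly flat in
the mean for upper-middle- and high-income countries (headcount ~10⁻³–10⁻²),
so small absolute perturbations of the observed headcount displace the
calibrated mean by many grid steps there. Parameter recovery under
observation noise is therefore excellent for LIC/LMIC-type countries and
poor for HIC-type countries; the acceptance script reports the measured
recovery rates with and without noise. Calibrating rich countries would
require a higher poverty line or a different moment.

## Aggregation

Group summaries (per World Bank income group and per WHO region, per
quintile and scenario) are means across countries with the standard error
of the mean, SEM = sample SD (n−1) / √n. The default weight is **equal by
country** — SEM-across-countries error bars imply country-level
observations — with population weighting available as an option (weighted
SEM uses the reliability-corrected weighted variance, which reduces to the
equal-weight formula when populations are equal). Groups with a single
country report SEM = 0 with a logged warning rather than a missing value,
keeping outputs rectangular. The equity gap is 100 × (poorest − richest
mean risk) in percentage points.

Presentation tables are rounded (3 decimals by default) only at write
time; the per-country cell file keeps full precision, so protection tables
are differences of unrounded risks.

## Synthetic data generator

The generator emulates the structure of a World-Bank-style country
indicator table with known ground truth. Per income group it draws Gini,
HEpc, GDPpc/HEpc ratio and OOP share uniformly within configured ranges
(defaults: Gini 0.30–0.55 for LIC/LMIC, 0.30–0.50 UMIC, 0.25–0.45 HIC;
HEpc 300–900 LIC, 800–3000 LMIC, 2500–9000 UMIC, 8000–40000 HIC USD/yr;
OOP share 0.30–0.60 LIC/LMIC, 0.20–0.45 UMIC, 0.10–0.25 HIC; GDPpc/HEpc
1.2–2.4), assigns WHO regions at random, and computes the observed poverty
statistics ($1.90 and $3.20/day headcounts, $2.15/day gap) **in closed
form from the generating model**, optionally perturbed by Gaussian noise
(sd 0.01 by default, truncated at 3 sd, clipped to [0, 1]; the two
headcounts share one noise draw so their ordering survives perturbation).
The default roster is 20 LIC / 49 LMIC / 39 UMIC / 41 HIC = 149 countries,
matching the coverage a global analysis of public indicators typically
achieves.

What the generator does **not** emulate: real countries' joint indicator
correlations (Gini and HEpc are drawn independently within a group),
national poverty lines, non-gamma income shapes, or survey measurement
error structure. Passing tests on synthetic data therefore demonstrate
internal correctness of the pipeline — parameter recovery, identities,
monotonicity — not agreement with any published country estimate. In
particular, with these ranges a $200 procedure is a near-certain
catastrophic expense for the poorest quintiles of low-income countries;
absolute risk levels produced under synthetic conditions are properties of
those conditions, not forecasts.

## Numerical choices

- Gini↔shape: log-space evaluation of the gamma-function ratio
  (gammaln) to avoid overflow; bisection, deterministic and monotone.
- CDFs and poverty statistics: `scipy.special.gammainc` (regularized);
  no quadrature in the main path (a quadrature identity is verified in
  tests).
- Degenerate inputs error early with the offending field named: Gini
  outside [0.01, 0.99], non-positive means and scales, thresholds ≤ 0,
  negative poverty lines, OOP shares outside [0, 1].
- Table reading auto-detects percent-scaled fraction columns (a column
  where most values exceed 1 is divided by 100, logged); a single
  out-of-range value in an otherwise valid column is treated as a bad row
  and rejected with a per-row diagnostic.
- All Monte Carlo paths take explicit seeds (`numpy.random.default_rng`);
  equal seeds give bit-identical output.

## Known limitations

- Absolute risk levels depend strongly on the income proxy and its units;
  the pipeline is designed around internal identities (overall = mean of
  quintiles, protection = baseline − scenario) and recovery on synthetic
  ground truth rather than reproduction of any specific published table.
- One global unit cost ($200) for all countries; no cost growth with
  income level, no indirect or non-medical costs.
- CHE only: impoverishment (poverty-line crossing) is not an outcome.
- Quintile pegs are a fixed stylized profile, identical across countries.
- Calibration is weakly identified for rich countries (see above).
- The percent-urban column is carried through but unused.
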