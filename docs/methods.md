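# Methods

## Model structure and assumptions

The model is a deterministic compartmental (stock-and-flow) system for the
adult (15+) population, stratified by WHO DMFT severity band (VL, L, M, H),
treatment status, age band (15–34 / 35+), sex and income group — 64 stocks
in all. Severity transitions are progressive and unidirectional (DMFT
cannot decrease by definition); treated/untreated transitions are
bidirectional. Three sub-models interact:

1. **Caries prevalence.** Forward hazards ρ(VL→L), ρ(L→M), ρ(M→H) act on
   both treatment layers and are scaled by two multipliers: a sugar
   multiplier (S/S₀)^ε per income group, and a behavior multiplier that
   discounts progression as awareness/self-care rise above base-year
   levels. Untreated→treated flows occur at the service-uptake hazard;
   treated→untreated relapse occurs at an expert-estimated base hazard
   discounted by the fraction making regular dental visits.
2. **Service utilization.** Uptake per (severity band, income group) is a
   goal-gap stock: it relaxes toward an indicated uptake — the survey base
   rate (VL 0.384, L 0.066, M 0.041, H 0.075) × access multiplier ×
   affordability multiplier × scenario boost — with a 1-year adjustment
   time. Uptake is interpreted as a per-year hazard on the untreated
   stock, not a prevalence target for the treated fraction; the two
   readings are observationally different and the hazard one composes
   naturally with the other flows.
3. **Behavior.** SSB demand responds to the cumulative relative price
   change with constant elasticities (low income −1.46, high −0.39),
   recomputed each year against the pre-tax reference price rather than
   compounded per step, so the demand path is independent of the
   integration step. Awareness and self-care are goal-gap stocks in
   [0, 1]; with the default zero promotion/loss rates they hold their
   initial values (0.5 and 0.529), leaving the behavior multiplier at
   exactly 1 — the behavior channel is a policy lever, deliberately
   neutral in all three named scenarios.

## Policy representation

The tiered specific tax (Baht/litre) is a lookup on sugar-content tiers
(g/100 ml, intervals closed on top, partitioning [0, ∞)) × calendar
periods (2018–20, 2021–22, 2023–24, 2025–40; the first period absorbs 2020
so periods tile the horizon). The consumer price signal is
passthrough × tax / reference price (passthrough 1.0 — the standard
assumption when unstated; the ad valorem component of the real mixed
system is exposed only as an optional extra increment, default 0).

Reformulation: the tiered design rewards cutting sugar content, but no
mechanism is published. We model average content as
base × (1 − r·f·φ(y)) with r = 0.8 the proportional reduction achieved by
reformulating products, f = 0.5 the reformulating market share, and
φ(y) = tax(base content, y)/tax(base content, final period) a phase-in
factor that follows the schedule's escalation (0.2 / 0.6 / 1.0 for the
default 15 g/100 ml product). The price-relevant tax is then looked up at
the *reformulated* content, avoiding a circular content↔tier dependence.

Scenarios: `base_case` (everything off), `ssb_tax` (tax from 2018),
`aggressive` (tax + 80% non-SSB sugar reduction + 50% uptake boost from
2018, held to 2040).

## Synthetic inputs

No microdata ship with the package; generators reproduce printed anchors:

* **Population.** Totals pass through the anchors 50.40 M (2010), 53.37 M
  (2020), 54.10 M (2030), 52.62 M (2040) via PCHIP (monotone
  piecewise-cubic — no overshoot between anchors, exact at anchors). A
  two-band bookkeeping model (aging hazard 1/20 y⁻¹; deaths on the 35+
  band at 0.015 y⁻¹, a realistic crude adult rate) back-solves annual
  entrants so population(y) = population(y−1) + entrants(y) − deaths(y)
  holds exactly. The simulator consumes the entrant series and the annual
  death *counts* (allocated proportionally across 35+ stocks), so the
  simulated total tracks the synthetic trajectory to machine precision.
* **Non-SSB sugar.** Per income group, a constant-growth series through
  the printed anchors (low: 22.35 kg/person/y in 2018 → 28.04 in 2040;
  high: 33.01 → 43.15), extended beyond the reported segment with the
  4-year percent-change moving average; for a constant-growth history the
  moving average continues the same rate, so both anchors are met exactly.
* **Initial SSB quantities.** The national anchors (total sugar
  76.19 g/person/day in 2000 → 104.46 in 2015; SSB share 15% → 21%) are
  converted to litres via the 0.15 kg/litre average content, interpolated
  to the 2010 start year, and split across income groups at a 1.5 high:low
  ratio (the direction — higher income consumes more SSB — is stated; the
  magnitude is not, and only the population-level share anchors constrain
  it). The population is split 50/50 low/high income, and equally by sex;
  60% of the 15+ population starts in the 35+ band.
* **SSB price.** Constant real 20 Baht/litre unless a series is supplied —
  only relative price changes enter the demand response.

What the generator does *not* emulate: real age pyramids and cohort
effects (two coarse bands only), migration, income-specific mortality,
price inflation, and any secular trend in SSB demand beyond the price
response. Tests passing on these inputs show the machinery is correct and
internally consistent; they do not validate the projections against new
Thai data.

## Initial conditions and reporting conventions

The 2010 stock distributes 50.40 M across severity bands at the reference
shares (38.7 / 19.7 / 16.6 / 24.9%), 9% treated / 91% untreated within
each band (making the base case consistent with the observed ~91%
untreated share), and equal sex/income splits (the joint distribution is
unpublished). Entrants default to the 2010 category shares of the 15–34
band.

Prevalence is the population share in L ∪ M ∪ H — the only definition
consistent with 61.3% at the 2010 distribution. Mean DMFT is a
population-weighted mean of representative per-band values, scaled so the
2010 means hit 2.42 (15–34) and 2.22 (35+); the printed adult mean is
arithmetically incompatible with the adult WHO thresholds (any adult
beyond VL has DMFT ≥ 5, forcing a mean ≥ 3 at 61% prevalence), so the
quantity should be read as a calibrated severity index, not literal teeth.
Printed-table reproduction uses round-half-away-from-zero.

## Numerics

Euler integration at Δt = 0.25 y (typical system-dynamics practice), all
flows evaluated simultaneously from the start-of-step state. Per-cell
outflows are proportionally rescaled if they would exceed the stock, which
keeps every stock non-negative and preserves the population balance
identically (observed residual ~3 × 10⁻¹⁶ relative per step). Halving the
step changes 2040 category populations by <0.1% under the calibrated
rates. Exogenous signals are resolved annually and held constant within
the year.

Calibration minimizes Σ w((sim − target)/target)² — relative errors, so
counts in millions and fractions can mix — over the three progression
hazards in [0.001, 0.2] y⁻¹, using bounded Nelder–Mead from 8
Latin-hypercube starts (deterministic per seed; ~2000 model evaluations,
~20 s). Noise-free self-generated targets are recovered to <10⁻⁶ relative.
Against the reference projections the fit leaves a 1.1 × 10⁻³ objective
(≈0.8% mean relative error over 16 targets) and lands the 2040 base-case
prevalence within 0.2 percentage points of the projected 74.9%.

Sensitivity draws are independent uniforms on each parameter range (±20%,
or the printed asymmetric endpoints for the sugar elasticity 0.4–0.72 and
reformulation percentage 0.5–0.9; the printed range for the 0.15 kg/litre
sugar content cannot bracket its central value and is replaced by ±20%),
with 2.5/97.5 empirical percentiles over 200 runs by default (the
published run count is unstated; intervals are reported alongside the
unperturbed central run).

## Known limitations

* The calibrated hazards (≈0.016/0.027/0.024 y⁻¹) differ from the
  published calibration (0.063/0.066/0.063 y⁻¹): with this package's
  synthetic demography and entrant distribution, the published hazards
  would overshoot the reference 2040 severity distribution. The hazards
  absorb whatever demographic detail the original inputs carried.
* Scenario effect sizes are smaller than the published projections: the
  simulated relative prevalence reduction by 2040 is ≈0.5% (SSB tax) and
  ≈7% (aggressive) versus the published 1% and 21%. The qualitative
  structure (ordering, direction, income gradient) is reproduced; the
  published magnitudes imply a stronger sugar→progression and
  treatment→severity coupling than the mechanisms specified here produce.
  Both links (power-law exponent, behavior modifier, uptake-as-hazard) are
  package design choices where no functional form was published.
* Untreated fractions drift from 91% toward the hazard-balance equilibria
  (≈85–90% by 2040 in the base case) rather than holding exactly, and the
  aggressive scenario's published untreated fractions (58/49/62%) are not
  reachable under the hazard interpretation of uptake.
* Two income groups and two age bands only; no cross-price substitution
  between SSB and non-SSB sugar; no revenue accounting.
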