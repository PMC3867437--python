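# Methods

## Model overview and assumptions

The package implements a large-population, infinite-horizon life-history
game. Fitness is the expected number of offspring surviving to breeding
adulthood over a mother's (or father's) lifetime. The core assumptions:

* **Geometric survival discounting.** A mother survives each year with
  probability `sf` independently, so a reproductive cycle of length `L`
  years is completed with probability `sf^L`. Lifetime fitness is the sum
  of per-cycle payoffs discounted by cumulative survival, which every
  closed form expresses as a renewal equation or small linear system.
* **Offspring-credit timing.** An offspring is credited at the start of a
  cycle; the mother must survive the cycle to begin the next. This fixes
  the Independent-Mother fitness at `S/(1 − sf^T)`. Crediting at cycle end
  instead would rescale all fitnesses by a common per-cycle factor and
  change no comparison; the start-of-cycle convention is the simpler one
  and is used throughout.
* **Two cycle lengths.** Independent caregiving takes the full interbirth
  interval `T`; mothers sharing the lactational load (a paired CM each
  cycle, an OM in the cycle she exploits) finish in `T − δ` years. The
  sucker's payoff costs a CM one `T − δ` allomothering period with zero
  own reproduction — delay is the entire cost.
* **Symmetric CM–CM pairs.** Both members of a cooperative pair get the
  shortened interval and the alloparental survival effect every cycle;
  the "who allomothers first" coin is absorbed by symmetry. The pair
  persists while both survive (independent `sf^(T−δ)` draws); a surviving
  partner returns to the search state. A no-re-search variant would only
  lower CM fitness; re-search is the behavior the search process implies.
* **Assortment.** Within each sex, like-with-like meeting probability is
  `r + (1 − r)·(own frequency)` — `r` is the probability of interacting
  with one's own strategy regardless of rarity, a standard reduced-form
  kin-selection device. Between the sexes, Cooperative Mothers pair with
  Coalition Males with probability `a + (1 − a)q`; OM and IM females split
  the residual Coalition-Male mass in proportion to their frequencies.
* **Expected-care convention.** A female's fitness is evaluated at her
  strategy's *expected* paternal-care increment (the mixture over mate
  type and his partnership status collapsed to its mean). Male fitness
  re-evaluates the paired female's fitness at the care level that male
  actually provides. The lifetime oracle follows the same convention by
  default, so both routes compute the same estimand; `care="draw"`
  samples a mate per lifetime instead, which differs only where the
  survival clamp at 1 is active between the two care levels.
* **Unpartnered Coalition Males act as Non-coalition Males** (care
  `b_noncoal`, extra-pair extent `e_noncoal`): coalition care needs the
  economy of scale and restraint needs a monitoring partner.
* **Population-level paternity certainty.** `Π` depends only on the male
  population's aggregate extra-pair activity; a male's type enters through
  his own branch weights and care, not through a private `Π`.

## Parameters

| Field | Meaning | Units | Default range |
|---|---|---|---|
| `s0` | baseline offspring survival to breeding adulthood | probability | 0.50–0.75 |
| `sf` | maternal annual survival | probability/yr | 0.90–0.99 |
| `b_allo` | alloparental effect on offspring survival | probability increment | −0.5–0.5 |
| `T_ibi` | interbirth interval, independent mothers | years | 5 (fixed) |
| `delta_ibi` | interbirth shortening from shared lactation | years | 0.5–2.0 |
| `e_noncoal` | lifetime extra-pair-mating extent, Non-coalition | dimensionless | 0–0.2 |
| `e_coal` | lifetime EPM extent, Coalition | dimensionless | 0–0.05 |
| `b_noncoal` | paternal-care survival increment, Non-coalition | probability increment | 0–0.05 |
| `b_coal` | paternal-care survival increment, partnered Coalition | probability increment | 0–0.1 |
| `r_kin` | within-sex like-with-like assortment | probability | 0–1 |
| `a_assort` | CM–Coalition-Male assortment | probability | 0–1 |

The survival ranges span chimpanzee-like to hunter-gatherer-like life
tables; the alloparental range deliberately includes net costs. The
interbirth shortening defaults to 0.5–2.0 years — up to a 40% reduction of
the chimpanzee-like 5-year interval, consistent with allo-nursing
shortening lactational amenorrhea while staying well below `T` — and is
config-exposed like every other range. Orderings `e_coal ≤ e_noncoal` and
`b_noncoal ≤ b_coal` are structural (monitoring and economies of scale).

## The Monte Carlo generator

`sample_params` draws each field independently and uniformly on its range
and enforces the two orderings by rejecting and redrawing the whole
vector, keeping marginals uniform on the accepted region (the acceptance
probability under the default ranges is above 0.8, checked empirically).
This generator *is* the study design: sweeps fix one parameter on a grid
and integrate the rest over their ranges. What it does not emulate: any
correlation structure between parameters (e.g. between male coalition
economies and paternity certainty), non-uniform priors, or
finite-population noise — passing sweep checks therefore says how the
*model* responds across its hypothesized parameter box, not how real
populations vary.

Unless a design targets them, `r_kin` and `a_assort` are fixed at 0 in the
sweep drivers (the conservative no-assortment baseline) and the
Coalition-Male frequency is drawn uniformly per draw. Draws are derived
from `(seed, grid-cell index)` only and reused across grid values and
(r, a) panels — common random numbers, so sweep orderings are paired
comparisons rather than noise contrasts, and every result is
bit-reproducible from `(config, seed)`.

## Numerical choices

* **Basin of attraction.** On the CM–OM edge (`z_im = 0`, the conservative
  setting), `w_cm − w_om` is pre-scanned at 200 points; a − to + sign
  change with increasing `x` brackets the unstable equilibrium, refined by
  bisection to `tol = 1e-6` in frequency. One-signed edges are the
  boundary cases (basin 1 or 0). With several sign changes the *largest*
  unstable crossing is reported (the smallest, most conservative CM basin)
  and flagged; a falling-only pattern (stable interior equilibrium) is
  reported with the same flag.
* **Replicator dynamics** are discrete-time proportional-fitness updates,
  renormalized each step to hold the simplex exactly; vertices are exact
  fixed points. Trajectories stop when the L1 step change drops below a
  tolerance or a step cap (flagged if truncated).
* **Clamping.** Offspring survival is clamped to [0, 1]; the residual
  Coalition-Male pairing probability and the pairing-table CM entry are
  clamped to keep proper distributions in extreme `(x_cm, a_assort)`
  corners. Every clamp emits a `ClampWarning` rather than failing or
  passing silently.
* **Degenerate corners.** With `x_cm = 1` the residual pairing probability
  is defined as `q`; a male type absent from the population (`q` = 0 or 1)
  gets the population female frequencies as its conditional mate
  distribution (the rare-mutant random-pairing limit).
* **Lifetime oracle.** The event-level simulator draws survival year by
  year (fractional remainders with probability `sf^frac`); the vectorized
  estimator draws one compound `Bernoulli(sf^L)` per cycle, which is
  distributionally identical under the constant annual hazard and lets
  10^5 lifetimes run in well under a second. Closed forms and oracle are
  compared on a 3-standard-error band at 10^5 lifetimes.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script in
the tens of seconds on one CPU: oracle agreement uses 20 random
(parameters, state) points × 3 strategies × 10^5 lifetimes; basin sweeps
200 draws per grid value; advantage surfaces 1000 draws over 8-point
grids; region grids 10×10 cells × 25 draws; exact identities 100 draws.
The drivers accept larger `n_draws` (the surface default is 10 000 when
invoked directly) without any other change.

## Design choices that were genuinely open

* **"Repeated interaction" axis.** The survival probability `sf` is the
  swept interaction-horizon variable: it alone controls the expected
  number of repeated cooperative interactions.
* **Uncertainty bands** are empirical 2.5/97.5 percentiles of the per-draw
  outcome (dispersion bands); standard-error bands are available via
  `band="sem"`. With degenerate ranges the band collapses to the
  deterministic value.
* **Surface slope comparison.** The care-difference and EPM-difference
  axes are compared on equal-count grids spanning each difference's
  feasible span under the default ranges (0–0.075 and 0–0.175 given the
  fixed offsets), i.e. per grid step, reflecting that the hypothesized
  care span is about half the EPM span.
* **Symmetry identity.** Equal care and EPM parameters make the male types
  payoff-identical *given no between-sex assortment*; with `a_assort > 0`
  the CM-preference attaches to the Coalition label itself, so the two
  "identical" types face different mate compositions and the advantage is
  generically non-zero. The symmetry tests therefore hold `a_assort = 0`.

## Known limitations

* No lactational physiology, no complementary feeding, no coalition sizes
  above two, and no feedback from births to strategy frequencies (the
  oracle simulates individuals, not populations).
* The model conditions on the male composition when evolving females;
  joint male-female dynamics are summarized only through the advantage
  sign over (x, q) grids.
* In the clamped high-`x_cm`, high-`a_assort` corner the pairing table
  assigns Coalition Males an exclusively-CM mate column; comparisons in
  that corner inherit this construction, which is one of several ways to
  normalize joint assortment.
* Detrimental alloparental care (`b_allo < 0`) applies fully to paired
  Cooperative Mothers every cycle, making Opportunists dominate the whole
  CM–OM edge for strongly negative draws at any survival level; dispersion
  bands of the basin therefore include zero across the survival sweep.
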