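# Model and methods

## Overview

`hscsoma` simulates a pool of hematopoietic stem cells (HSC) in weekly
discrete time over an 85-year (4,420-week) lifespan. Cell state is three
numbers: a fitness value (competitive weight, dimensionless, 1 at
birth), a Tier-3 passenger-mutation count (neutral marker of division
history), and a clone label. The model is a forward Monte Carlo
experiment: all dynamics are stochastic draws from configured
distributions, and every run is reproducible from a single integer seed
expanded into four independent streams (division, DFE, environment,
competition), so toggling one mechanism never shifts another's draws.

## Weekly update

Within one week the operations are applied in a fixed order (results are
order-sensitive, so the order is part of the model definition):

1. **Division.** Each cell divides with probability `d(t)`. A division
   produces the self-renewing daughter, which retains the mother's
   state, and a second daughter, appended to the pool, which receives
   one net fitness effect drawn from the mutation DFE and one Poisson
   Tier-3 increment. This "one net fitness change per division" update
   is the default; a `symmetric_division` toggle draws independent
   effects for both daughters. The asymmetric default was chosen
   because the symmetric scheme (i) degrades every lineage at every
   division, which at wide DFEs (σ ≥ 5×10⁻²) drives the whole pool to
   extinction rather than the observed buffered few-percent fitness
   drop, and (ii) doubles the realized per-lineage division rate to
   2d/(1+d), detaching the model from the published HSC division-rate
   estimates its schedules encode.
2. **Clone bookkeeping.** A new daughter whose fitness deviates from her
   clone founder's reference fitness by more than θ (default 0.05)
   founds a new clone. Founder references are carried forward along the
   *expected* environmental fitness trend (uniform drop plus the mean of
   the distributed environmental draw). Without this detrending, the
   shared ~0.7 lifetime environmental decline exceeds θ for every cell
   and late-life clone structure fragments at every division; divergence
   is meant to capture heritable differences *among* cells.
3. **Microenvironment** (composite model only). Every cell loses the
   uniform weekly drop ΔF(t) (the analytic derivative of the logistic
   decline curve, per one-week step) and gains a persistent per-cell
   perturbation drawn with spread ΔF(t)/2 — the environment re-valuing
   each cell's accumulated alterations. Draws accumulate across weeks
   (random walk); the spread is interpreted as a standard deviation
   (σ denotes SD throughout), with a `spread_is_variance` toggle.
4. **Viability culling.** Cells at fitness ≤ 0 leave the pool
   (loss of competitive viability; also keeps lottery weights positive).
5. **Niche competition.** If the pool exceeds the carrying capacity
   N(t), exactly the overflow is removed: survivors are drawn without
   replacement with weight proportional to fitness, floored at 10⁻⁶
   (implemented with exponential sort keys, `log(U)/w`). No departures
   occur below capacity.

## Distributions

**Mutation DFE.** A draw is `s·|Z|`, `Z ~ Normal(0, σ_eff)`, with sign
`s = +1` with probability `q` (the positive-tail fraction) and −1
otherwise — a sign-flipped half-normal mixture that is exactly a
zero-mean normal at `q = 0.5`. This is the minimal construction that is
both centred on zero and has an adjustable tail asymmetry.

**Mutation-rate ramp.** The relative rate m(t) ramps from 1 at birth to
a fold increase `f` at death; the default ramp is linear (the simplest
monotone choice; an exponential ramp is available). Because the net
per-division effect is a sum of m(t) unit contributions, variances add:
`σ_eff = σ·sqrt(m(t))`.

**Tier-3 passengers.** Poisson increments with mean `μ0·m(t)` per
division. The default μ0 anchors neutral accrual to the reference AML
slope: with the pool at capacity and neutral removal, the pool-mean
count rises by `μ0·d/(1+d)` per week under the default update, so
`μ0 = 0.09162 / (52·d_adult/(1+d_adult)) ≈ 0.0722` at the default adult
rate (recalibrated automatically in the slow-cycle preset). The exact
neutral expectation, `μ0·Σ_t m(t)·d(t)/(1+d(t))`, is asserted by a
property test against replicate simulations.

## Demography

Published curves motivate parametric schedules evaluated at integer
weeks:

- **Capacity N(t):** a logistic renormalised to start exactly at 300
  cells at birth, with midpoint at 9 years and 99% of the adult size by
  18 years. Presets: stable 11,000; large 25,000; growing 11,000→25,000
  linearly across adulthood.
- **Division rate d(t):** exponential decay from 0.4/week at birth to
  the adult plateau 1/40 per week (≈1.3/year) within 1% by age 20. The
  slow-cycle preset lowers the plateau to 0.6/52 ≈ 0.0115/week, the
  lowest published adult estimate. The schedule front-loads divisions:
  ≥40% (in fact ≈56%) of lifetime expected divisions occur before age
  20, consistent with early-life mutation accrual.

## Microenvironmental decline curve

F(A) = F_max − (F_max−F_min)/(1 + scale·e^(−rate·A)) with defaults
F_max = 1, F_min = 0.3, scale = 5200, rate = 0.0031/week: F(0) = 0.99987
(rounds to 1.00), fastest decline near age ~53, F(4420 weeks) ≈ 0.304.
The weekly uniform drop is the analytic |dF/dA|; summed over a lifetime
it telescopes to F(0) − F(4420) within 1%.

With a symmetric distributed component (tail 0.5, the default: the
perturbation is "centred on zero") the pool's mean fitness tracks F(A),
ending near 0.3. With tail 0% every draw is negative and the half-normal
mean (≈ 0.28 summed over life) adds to the uniform decline, driving mean
fitness toward ~0.03 by late life; the resulting late-life collapse of
absolute fitness makes small heritable differences relatively large and
fuels strong terminal selection. Whether the original distributed effect
was persistent or transient is not determinable; persistence is the
default here and the detrended clone references isolate its heritable
part.

## Metrics

- **Tier-3 slope:** ordinary least squares of pool-mean Tier-3 count
  against age in years over the full lifespan (matching the cross-age
  regression of the AML reference), with a t-based 95% CI
  (`scipy.stats.linregress`).
- **Clonal expansion:** share of the pool held by the largest clone;
  end-of-life expansion is that share at death, in percent.
- **Shape similarity:** both curves are resampled to the reference age
  grid (linear interpolation, yearly ages 0–85), 0–1 normalised
  (min–max; a constant series maps to zeros), and compared as
  `1 − RMSE`, clamped to [0, 1]. The statistic is symmetric and
  invariant to affine rescaling of either curve.
- **Reference incidence curve:** the package ships a *synthetic*
  parametric stand-in for a population leukemia-incidence curve:
  zero through reproductive ages, then `expm1(0.085·(age − 40))` — an
  exponential rise doubling roughly every 8 years, the canonical
  late-life pattern. Any two-column CSV (age_years, incidence) can be
  supplied instead.

## Parameter sweeps and the plausible range

`run_grid` runs R seeded replicates per cell of a (σ × fold) grid —
default 6 log-spaced σ in [5×10⁻⁶, 5×10⁻¹] × 8 folds in [1, 8] — and
records replicate means of slope, similarity, end-of-life expansion and
final fitness. Replicate seeds derive deterministically from the base
seed and grid coordinates, so surfaces are independent of execution
order. The plausible mask selects cells with slope inside the closed
reference interval [0.03759, 0.1457]; `overlap_percent(c)` is the share
of plausible cells at similarity ≥ c. Overlap on an empty plausible
range raises an explicit error rather than returning 0. Replicates are
aggregated by mean.

Desk-scale defaults (2,000-cell adult pool, R = 3) keep a full
two-model sweep around ten minutes on one CPU; competition intensity
depends on pool size, so scaled runs check directions and bounds rather
than exact full-scale surface values. A full-scale configuration
(11,000 cells) is a one-line override of `schedules.adult_size`.

## Driver probability

`driver_probability` evaluates `P(t) = D(t)·∫₀ᵗ Π p_i(τ) dτ` by the
composite trapezoid rule (O(h²)); it is a rate-like heuristic used for
relative reasoning about how clonal expansion multiplies the chance of
completing a driver set, deliberately not clamped at 1 and not coupled
into the simulator's dynamics.

## Interpretation of desk-scale results

Two regimes shape the largest-clone trajectory. Early in life the pool
grows from 300 founders under rapid cycling while the niche capacity
expands slowly, so turnover is high and founder lineages coalesce; the
largest founder lineage typically holds tens of percent of the pool by
maturity regardless of σ (a drift plateau). Late-life increases beyond
that plateau require selection. Because selection acts only through the
overflow lottery (effective adult generation ≈ 40 weeks), a clone with
relative advantage s grows only ≈ e^(s·generations); sweeps complete
within a lifetime only for s of order 10⁻² or larger. Consequently:

- with mutations alone and a near-neutral DFE, trajectories are
  drift-shaped and do not match the late-exponential incidence curve;
- clonal interference (suppression of the top clone by a larger
  beneficial tail) manifests at the wide end of the mid-σ range
  (σ ≈ 3×10⁻², where beneficial effects are strong enough to produce
  concurrent competing sweeps);
- under the composite model with an all-negative distributed component,
  mean absolute fitness collapses late in life, amplifying relative
  heritable differences and producing a terminal selection surge whose
  timing matches the late rise of the incidence curve.

## What the synthetic generator does and does not emulate

The simulator generates all of its own data. It emulates: age-dependent
pool growth and division slowdown, zero-centred mutation fitness
effects, neutral passenger accrual tied to division history, niche
competition, and an aging microenvironment with uniform and distributed
components. It does not emulate: progenitor/differentiated
compartments, explicit driver-mutation identities or leukemia onset,
spatial niche structure, per-site genomes, or real registry incidence
data (the shipped incidence curve is a documented synthetic stand-in).
Passing tests therefore demonstrate internal consistency and the
model's qualitative contrasts at desk scale, not quantitative agreement
with clinical data.

## Numerical and degenerate-case conventions

- Ages are integer weeks; 52 weeks/year converts to years.
- σ = 0 or a flat environment produce exactly zero draws (no RNG
  consumption changes — each mechanism has its own stream).
- Constant series normalise to all zeros; similarity is clamped to
  [0, 1]; the closed slope interval includes its endpoints.
- Competition weights are floored at 10⁻⁶; cells at fitness ≤ 0 are
  removed before the lottery.
- An extinct pool records NaN means (and is thereby excluded from
  plausible-range masks).

## Known limitations

- The desk-scale drift plateau (early founder coalescence) is a
  finite-size effect that is stronger at 2,000 than at 11,000 cells;
  overlap and similarity statistics at desk scale are noisy, and
  replicate means over R = 3 still carry visible seed-to-seed spread.
  Concretely, the maximum plausible-range shape similarity under the
  composite model at the 2,000-cell scale spans roughly 0.58–0.72
  across base seeds and exceeds the 0.7 stringency only occasionally,
  while single full-scale (11,000-cell) composite runs reach 0.66–0.83;
  the mutations-only overlap at 0.7 stringency is 0% at most seeds and
  at most one plausible grid cell (≈5.6%) otherwise.
- The competition scheme (linear fitness weighting, overflow-only
  removal) is the largest reconstruction gap; selection intensity and
  therefore expansion magnitudes depend on it.
- The clone threshold θ and the persistence of the distributed
  environmental effect are not empirically pinned; both are exposed in
  the configuration.
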