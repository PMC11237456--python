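# Methods

## Model structure and assumptions

Both model variants track six compartments — focal strain F, background
strain B, novel lysogens N, free virions P, and the committed
(induced or lytically infected) pools B̃ and F̃ — plus a nutrient R in the
resource-explicit variant.  Assumptions baked into the equations:

* **Superinfection exclusion is absolute**: virions adsorb to (and are
  removed by) susceptible B cells only; F, N, and the committed pools
  neither adsorb virions nor are reinfected.
* **Committed cells are dead ends**: once induced (rate κ) or lytically
  infected (probability π on adsorption), a cell stops dividing and lyses
  at rate λ, releasing β virions.  With probability 1 − π an infection
  instead converts the cell to a novel lysogen, which thereafter behaves
  like a lysogen of the focal phage.
* **Novel lysogens inherit the focal phage's traits** by default.  A
  per-run override of the novel induction rate (κ_N ≠ κ) is supported —
  the scenario where a freshly acquired prophage is poorly repressed and
  induces faster than in its long-term host.  Lysis rate and burst size of
  the shared committed pool always follow the focal phage.
* **Shared-capacity competition (gLV variant)**: every living strain grows
  at r + μS, with S summing F, B, N and (by default) the committed pools,
  and a single interaction coefficient μ < 0.  This is algebraically
  logistic growth toward the shared capacity K = −r/μ.  Excluding the
  committed pools from S is a configuration flag; across every scenario we
  probed it changes PEI by under 1e-4, so the conservative default
  (include: committed cells still occupy the niche until lysis) stands.
  An alternative reading — each strain self-limited by its own abundance
  only (growth r + μ·x_i) — was evaluated and rejected: without
  cross-strain competition all strains grow to their own capacity, control
  competitions drift to a 50:50 endpoint from any start, and phage killing
  confers almost no frequency advantage, flattening every effectivity
  surface.  The shared-capacity reading is the one under which the model
  family produces its characteristic predictions.
* **Resource-explicit variant**: growth is r·g with Monod uptake
  g = R/(R + k); there are no μ terms.  Nutrient is consumed in proportion
  to the growth of the replicating pools F, B, N (committed cells do not
  divide, hence consume nothing).  This variant exists to capture batch
  culture: susceptible cells that consume nutrient and are *then* lysed
  remove energy from the system, so populations seeded with rare lysogens
  finish at lower density — a signature the chemostat-flavored gLV variant
  cannot produce (its final densities vary < 1% across starting ratios).

Omitted on purpose: density-dependent induction, superinfection of
lysogens, de novo phage resistance, stochastic (agent-based) dynamics,
and evolutionary change in traits.

## Parameters

| Symbol | Meaning | Unit | Baseline | Explored range |
|---|---|---|---|---|
| π | probability of lysis on infection | – | 0.5 | 0.01–0.99 |
| κ | induction rate | h⁻¹ | 1e-4 | 1e-5–0.9 |
| λ | lysis rate of committed cells | h⁻¹ | 0.505 | 0.01–1 |
| α | adsorption rate | cell⁻¹·h⁻¹ | 1e-8 | 1e-10–1e-6 |
| δ | virion degradation rate | h⁻¹ | 0.05 | 1e-5–0.9 |
| β | burst size | virions/cell | 100 | 10–1010 |
| r | intrinsic growth rate | h⁻¹ | 0.9 | fixed |
| μ | interaction coefficient | cell⁻¹·h⁻¹ | −4e-10 | fixed |

Time is in hours throughout; a competition runs for 24 h from a total
inoculum of 1e6 cells, which comfortably reaches the capacity
K = −r/μ = 2.25e9.  The `phi2` / `phi4` presets differ from baseline in
π (0.91 / 0.72) and δ (0.01), matching two temperate phages of
*Pseudomonas aeruginosa* (LESB58 Phi2 and Phi4) whose lysogens differ
measurably only in their probability of lysis.

Nutrient-variant constants are not independently measured; the defaults
are chosen for consistency with the gLV capacity: yield 5e-9 resource
units per cell, R0 = yield·K = 11.25, and k = R0/10 = 1.125, which
qualitatively matches the growth curve of the phage-free strain.

## Simulation design

The phage-free control ("WT") run integrates the *same* six-compartment
system with κ forced to 0 and P(0) = 0, rather than a reduced model, so a
lysogen run and its control share solver, step selection, and output grid;
PEI differences cannot arise from numerics alone, and an inert phage
(κ = 0, P0 = 0) yields bit-identical paired runs — hence PEI exactly 0.

Integration uses LSODA (`scipy.integrate.odeint`) with a compiled
right-hand side and analytic Jacobian, relative tolerance 1e-8, absolute
tolerance 1e-10, and 241 evenly spaced output samples over 24 h (0.1-h
resolution, finer than a plate reader's 30-min cadence).  Reported states
are clipped at zero; the solver itself is not clipped.  Halving the
tolerances moves final frequencies by < 1e-6, and the solution matches an
independent fixed-step RK4 integration to better than 1e-4 per
compartment and the closed-form logistic (single-strain limit) to 1e-6.

## Effectivity metrics

The focal lineage counts F + F̃ and the background lineage B + B̃ + N
(novel lysogens are background-derived); counting only the uninduced
compartments is a switchable convention and changes no qualitative result.

* `pei_frequency` — final focal frequency, lysogen run minus control run;
  bounded in [−1, 1], zero for a neutral phage.
* `pei_relative_fitness` — v = ln(F_end/F_0) / ln(BG_end/BG_0) on the
  lysogen run (Malthusian ratio); the control run's v ≡ 1 is returned for
  reference.  Note that under this convention v increases monotonically
  with starting frequency at the baseline parameterization — it does not
  share the interior-peak shape of the frequency-difference index.
* `pei_log_fold_change` — ln(F_end/F_0), lysogen minus control; this
  variant is largest when the lysogen starts rare, because fold changes
  amplify small baselines.

Cumulative phage output is ∫βλ(B̃+F̃)dt by trapezoidal quadrature on the
output grid (O(h²) ≈ 1e-3 relative error at 0.1-h resolution), avoiding an
extra ODE state.

## Sweeps

Trait-by-frequency and trait-by-induction surfaces default to 25×25 cells:
linear grids for π, λ, δ, β; log grids for κ and α (their ranges span 4+
decades); starting frequencies on a log-symmetric grid over 0.01–0.99 so
both the invasion and defense regimes are resolved.  Control runs are
cached per frequency — they are independent of the swept trait — making a
full surface ~650 rather than 1250 solves (a few seconds each surface).
Zero contours are reported as sign changes along each column.

Characteristic behavior at the baseline: raising π always increases PEI;
raising κ always decreases it; δ is inconsequential (its full-range PEI
spread is ~3e-5 of the κ spread); α and λ matter little alone but can
rescue a high-induction phage (at f0 = 0.1, columns up to κ ≈ 0.56 switch
from negative to positive as α rises toward 1e-6, while no column is ever
rescued along δ).  The costly-when-rare / beneficial-when-common crossover
for induction sits near κ ≈ 0.2 at this parameterization.

## Rank-volatility analysis

100 sets of 100 random phages are drawn, each phage's PEI computed at 11
evenly spaced starting ratios (0.01–0.99), phages ranked per ratio
(rank 1 = highest PEI, ties broken by phage index with a stable sort), and
for each ratio after the first the number of phages whose rank changed is
counted.  The 100 × 10 (ratio, count) points are pooled into one OLS fit
of volatility on ratio (998 residual df).

**Sampling scheme.**  Traits are drawn uniformly on the *linear* scale
over their ranges.  Log-uniform draws for κ and α are available but are
not the default for a structural reason: they concentrate the sample on
weakly adsorbing, rarely inducing phages whose PEIs differ by < 1e-4 at
the frequency-compressed ends of the ratio grid.  Rankings there reorder
by micro-swaps among near-ties, volatility becomes U-shaped with a spike
at the highest ratio, and the fitted slope loses its sign.  Under linear
sampling the trait draws are dominated by phages with substantial
induction and adsorption, volatility declines monotonically from ~70 to
~15 rank changes across the ratio grid, and the pooled regression is
steeply negative (slope ≈ −52, intercept ≈ 61, R² ≈ 0.70, t(998) ≈ −48 at
seed 1) — small changes in starting frequency reshuffle the optimal-weapon
ordering when lysogens are rare, but barely at all once they dominate.
Note the slope t statistic is determined by R² through
t² = R²·df/(1 − R²), so its value tracks residual scatter, not effect
size.

## Trait estimators

Five estimators map assay counts to traits; each mirrors a standard
bench protocol:

* **Adsorption**: virion loss after 10 min co-incubation,
  |ΔPFU| / ((1/6 h)·PFU₀·CFU₀).  The 1/6 expresses the incubation in
  hours; a magnitude is returned because a titre *fall* is adsorption.
  A literal mode evaluating the signed expression with a bare 16 in the
  denominator is kept behind a flag.
* **Burst size**: (PFU gained)/(CFU lost) over an infection cycle.
* **Degradation**: titre loss per hour of a cell-free lysate over 24 h;
  the default is the absolute loss rate (PFU·h⁻¹), with a per-capita mode
  (dividing by PFU₀, h⁻¹) that is the dimensional match to the model's δ.
* **Induction proxy**: slope of a DNA-release (Sytox-type) fluorescence
  signal between 5 and 10 h.  This orders strains by spontaneous lysis but
  carries no absolute calibration onto κ.
* **Probability of lysis**: colonies on a phage-embedded lawn over
  colonies on a phage-free control.  The literal ratio is the default —
  it is the convention under which the shipped Phi2/Phi4 values (0.91,
  0.72) were calibrated — with the complement (1 − ratio, the
  survival-fraction reading) selectable.  The two conventions disagree
  about what "surviving colony" means biologically; the result object
  records which was used.

Every estimator is homogeneous in its counts exactly as its formula
dictates (degree 0 for the ratios, −1 for adsorption, +1 for absolute
degradation and the emission slope), which is property-tested.

## Synthetic data

The generators invert each estimator at fixed design constants
(10⁴ PFU and 10⁷ CFU inocula, 10⁸ PFU·mL⁻¹ lysate, 1000-colony control)
so that noise-free estimates reproduce the input traits exactly, then
perturb the single *response* measurement of each assay (final titre,
background-subtracted fluorescence, phage-lawn colony count) with mean-one
multiplicative log-normal noise; inocula and control counts are treated as
exact design constants.  Because every estimator is linear in its one
noisy measurement, the estimators stay exactly unbiased under this model —
verified by a 500-replicate Monte-Carlo check at CV = 0.2.  The invertible
domains are α ≤ 6e-7 (beyond which the design would adsorb every virion)
and δ < 1/24 (beyond which the 24-h lysate would be exhausted).

Competition observations are drawn from model trajectories: flow-cytometry
counts as a binomial split of a configurable number of analyzed cells at
the model's focal frequency; density curves at 30-min cadence proportional
to total bacterial abundance with additive Gaussian noise (no
optical-density calibration — only relative patterns are compared).
`fit_density_model` fits final density ~ strain × ratio by OLS (ratio
numeric) and reports the interaction F from a type-II ANOVA; it requires
two strains, two ratios, and ≥ 2 replicates per cell.  At a
plate-reader-realistic noise of ~1% of final density, a 3-replicate design
detects the nutrient-model lysogen's density-ratio slope against a flat
control in > 95% of seeds; the type-I error of the same test sits at the
nominal 5%.

What the generators deliberately do not emulate: plate-reader optics and
calibration, well-to-well and edge effects, spatial structure, counting
error in the "exact" design constants, and biological replicate variance
in the traits themselves.  Passing round-trip and power tests therefore
demonstrates the *pipeline's* correctness and sensitivity under its stated
observation model, not the field accuracy of the bench assays.

## Problem sizes and runtime

The shipped analyses are sized for a single CPU: the full rank-volatility
pipeline is ~1.1e5 ODE solves (~10 min; control runs are cached per
ratio), a 25×25 sweep surface is ~650 solves (seconds), and the
10-set smoke version of the volatility analysis runs in well under two
minutes.  All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give bit-identical outputs.

## Known limitations

* The gLV variant is a chemostat-flavored idealization; batch-culture
  density effects require the nutrient variant (the two agree closely on
  PEI itself).
* Relative fitness is defined as the Malthusian ratio; other conventions
  (selection coefficients, odds ratios) change the shape of its frequency
  dependence.
* The induction estimator is a proxy with arbitrary units; only trait
  *orderings* derived from it are meaningful.
* Trait draws for the ranking analysis are independent across traits;
  real phage life histories are correlated.
* With ranks defined on raw PEI values, near-ties (differences below
  solver precision) are broken by index; this matters only under sampling
  schemes that generate many effectively identical phages.
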