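# Methods

This note documents the models implemented in `fluxsel`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter.

## Chemostat model

State: vessel concentrations of ammonium sulfate `S_as` and glucose `S_g`
(µM) and cell density `X` (cells/ml). Dynamics:

```
dS_as/dt = D (R_as(t) − S_as) − (X / Y_as) u
dS_g/dt  = D (R_g(t)  − S_g)  − (X / Y_g)  u
dX/dt    = (u − D) X
u(S_as, S_g) = u_max / (1 + K_as/S_as + K_g/S_g)
```

The dual-substrate growth law multiplies two Monod saturation deficits into a
single interactive form; it reduces exactly to `u_max S/(S+K)` when the other
substrate saturates, and we define `u = 0` at zero substrate (the limit
value). `D` is the dilution rate (culture volumes/h, 0.12 by default), `Y`
the yield (cells·ml⁻¹ per µM nutrient), `R(t)` the reservoir (feed)
concentration.

**Feed schedules.** `static` holds `R` constant; `switch` alternates two
media as a square wave every `switch_half_period` hours (30 h default, i.e. a
60 h period) with instantaneous transitions; `pulse` keeps a static feed and
adds `pulse_bolus` µM directly to the vessel concentration every
`pulse_interval` hours (3 h default, 40 µM ammonium sulfate — 80 µM elemental
nitrogen). Switches and boluses are handled by splitting the integration at
the exact event times and restarting the solver (LSODA, rtol 1e-8,
atol 1e-10), never by smoothing the discontinuity; with no cells the model is
linear and the integration matches the closed-form piecewise exponential
`S(t) = R + (S₀ − R)e^{−Dt}` to better than 1e-6 relative error (tested).
States are clipped at zero with a warning if undershoot exceeds 10× the
absolute tolerance.

**Kinetic defaults.** `u_max = 0.4 h⁻¹`, `K_as = K_g = 5 µM`, and yields
7.5×10⁴ cells·ml⁻¹·µM⁻¹ so that a 400 µM nitrogen-limited feed supports
roughly 3×10⁷ cells/ml — the batch-end density of the study system. These are
order-of-magnitude choices for a glucose/ammonium yeast chemostat (measured
values for the study's strains are not available) and every one is
overridable via `ChemostatParams` or YAML config. The carbon-limited glucose
feed has two mutually inconsistent published readings (444.4 µM, and the
0.08% w/v recipe which works out to 4,444 µM); `CLIM_MEDIA` carries both and
no builder defaults to either — callers must choose.

**Steady state.** For a static feed with `u_max > D` the fixed point solves
`u(S*_as, S*_g) = D` together with the shared draw-down relation
`X* = Y_as(R_as − S*_as) = Y_g(R_g − S*_g)` (1-D root bracketing in `S_as`);
the single-substrate limit is the textbook `S* = K D/(u_max − D)`,
`X* = Y (R − S*)`. Feeds too dilute to sustain growth at `D` return the
cell-free washout state with a flag.

## Multi-genotype competition

The ensemble model follows the classical extension of two-genotype chemostat
competition: one limiting substrate, per-genotype Monod kinetics
`λ_i(S) = u_max,i/(1 + K_i/S)` with a shared `K` by default (heterogeneity
lives in `u_max,i`; per-genotype `K_i` is supported), shared yield, and

```
dx_i/dt = (λ_i(S) − D) x_i,    dS/dt = D(R − S) − Σ_i (x_i/Y) λ_i(S).
```

A single fitness axis keeps parameter-recovery tests interpretable; the
dual-substrate ensemble is intentionally out of scope. The right-hand side is
fully vectorized and integrated with an explicit solver (RK45): at several
thousand genotypes a stiff solver's dense Jacobian costs far more than the
mild stiffness of the substrate channel. 4,000 genotypes over 240 h run in
under a second.

The genotype with minimal break-even concentration `S*_i = K_i D/(u_max,i−D)`
excludes the others in a static environment (tested against long
integrations). During the sorting the population sits in *quasi steady
state*: the abundance-weighted mean growth rate stays within a fraction of a
percent of `D` while proportions change by orders of magnitude.

**Price decomposition.** For the simulated trajectory we evaluate
`λ̄ = Σ p_i λ_i`, the selection term `Var_p(λ)`, and the environmental term
`Σ p_i dλ_i/dt` (numerical gradient of `λ_i(S(t))`), and report the identity
residual `dλ̄/dt − Var − mean-change`. The left side is differentiated
numerically from the trajectory while the right side substitutes the
replicator identity `dp_i/dt = p_i(λ_i − λ̄)`, so the residual is a genuine
check of the decomposition (it sits at the `O(Δt²)` differencing level, not
at machine zero by construction). Near-cancellation of the two terms — the
variance pushes mean fitness up, the falling substrate pulls every `λ_i`
down — is exactly why `λ̄` stays pinned near `D`.

## Synthetic barseq generator

The generator emulates the study design: 4,000 genotypes, conditions
`clim`/`nlim`/`switch`, biological triplicate, samples at t = 0, 24, …, 240 h
(11 points; the design is sometimes described as 10 — with sampling every
24 h over 240 h both readings exist, and `times` is a parameter), target
depth 10⁶ reads/library.

Genotype dynamics are specified on the log-abundance scale per class:

* flat — constant;
* linear — slope ~ N(0, 3×10⁻³ /h), plus a 2% strongly-deleterious tail
  (slope U(−0.035, −0.015)) whose trajectories underflow sequencing depth
  before 240 h — this is how extinction manifests in barseq (no hard zeros
  are injected);
* quadratic / cubic — curvature scaled so the total log-swing over 240 h is
  ~1–3, giving accelerating or sign-reversing per-cell growth;
* periodic (switch only) — amplitude U(0.3, 0.8), uniform phase, period 60 h,
  a cohort of 17.5% of the library (700 of 4,000);
* one extreme-fitness genotype (slope +0.04/h) in each static condition and
  none in the switch — with a uniform start this genotype passes 50% of the
  population by 240 h, reproducing the static selective sweep.

Proportions are renormalized exponentials of the log-abundance curves
(computed with a stable per-time shift, so overflow cannot occur; non-finite
coefficients are rejected). Sequencing is multinomial at the library depth;
overdispersion multiplies each genotype's proportion by an independent
Gamma(1/φ, φ) factor before renormalization — the gamma-multinomial analogue
of negative-binomial noise with variance ≈ µ + φµ² — with a mild φ = 0.005 in
the scenario (≈7% extra CV per measurement) and 0 (off) as the `sample_counts`
default. Column sums always equal the design depth. Optional uptag/downtag
rows split each count binomially (p = 0.5).

**What the generator does not emulate:** PCR amplification bias, barcode
cross-mapping, batch effects between sequencing runs, de novo mutation, and
ecological interactions between genotypes (each trajectory is specified
marginally, so frequency-dependent selection exists only through the shared
normalization). Passing recovery tests on these data therefore demonstrates
estimator correctness under the stated noise model, not robustness to every
artifact of real barseq.

## Count processing

Pipeline order: drop libraries with fewer than 100,000 total reads (strictly
less than; the boundary library is kept) → sum uptag/downtag rows per
genotype (strict by default, `permissive` treats a missing tag as zero) →
drop genotypes with aggregate counts below 1,000 across all retained samples
→ median-of-ratios normalization. Size factors use the standard RNA-seq
estimator: reference = per-genotype geometric mean over samples, restricted
to genotypes positive in every sample; factor = median ratio to the
reference, rescaled to geometric mean exactly 1. If no genotype is positive
everywhere the code falls back to total-count scaling with a warning. An
independent implementation of the same estimator (pydeseq2) serves as a
cross-check oracle in the tests. Normalized abundances are defined up to one
global constant — rescaling any library's depth changes all entries by a
shared factor only — so every downstream statistic uses ratios or
differences of logs.

Log abundance is `ln(normalized + 0.5)`; zeros are kept, not dropped, so
extinction analysis can see them, and trajectory fits never receive −∞.

**Replicate QC.** Each replicate's log-abundance time-course (genotypes ×
matched times, flattened) is Pearson-correlated with every sibling replicate;
a replicate is flagged when its *best* sibling correlation falls below 0.8.
The best rather than the mean is used deliberately: with three replicates one
corrupted member drags both (mutually consistent) siblings' mean correlations
down, whereas the best-sibling rule isolates exactly the bad one. The report
carries both statistics; the threshold is a package default, configurable,
and the report is always emitted. Whether the original analyses computed such
correlations on counts, abundances or fitness is not recoverable; log
normalized abundance is used here.

## Diversity and fitness statistics

* Shannon `H = −Σ q ln q` (nats) over within-sample abundance proportions;
  richness = genotypes with nonzero raw count; evenness = `H/ln(richness)`.
  H from multinomial resamples of one composition varies by <1% across depths
  10⁵–10⁷ (tested), so depth does not confound diversity comparisons.
* Diversity rate: OLS slope of H vs time, replicates pooled with per-replicate
  intercepts, 95% CI from the t distribution on residual degrees of freedom.
* Relative fitness over (t₁, t₂), default (0, 240):
  `f_i = [ln n_i(t₂) − ln n_i(t₁)]/(t₂ − t₁)` on replicate-averaged log
  normalized abundance, centered by the **unweighted** arithmetic mean over
  genotypes (an abundance-weighted option exists). Time, not generations, is
  the denominator so static and fluctuating regimes compare directly.
  Genotypes with a zero raw count at either endpoint are NA.
* Piecewise fitness: the same estimator between consecutive samples, centered
  per interval; by preference computed on model-predicted log abundance
  (prediction smooths sampling noise), with raw abundances as the alternative
  source. The full-course fitness equals the time-weighted mean of raw
  piecewise rates exactly (telescoping; tested).
* DFE: histogram of fitness at a configurable bin width (0.002/h default)
  plus per-bin summed proportion change between t=0 and t=240 (sums to zero
  by conservation), with SD/IQR and tail extrema.
* Extinction: a genotype is extinct in a condition when its replicate-summed
  count is zero in ≥1 of the last k time points (k = 1 default; "terminal" is
  genuinely ambiguous and k is exposed).

## Trajectory model selection

Per genotype and condition, log normalized abundance from all samples
(replicates pooled) is fit by Gaussian least squares to a hierarchy sharing
per-replicate intercepts: constant; linear; quadratic; cubic; and periodic
`a_r + b t + p sin(2πt/T) + q cos(2πt/T)` at the environmental period
(T = 60 h default). The periodic model keeps the linear term so net selection
and oscillation are separable. All fits are batched across genotypes (one
least-squares solve per model class), so a full condition fits in about a
second.

**Selection procedure.** (1) An omnibus likelihood-ratio gate compares the
richest model (cubic + periodic terms when a period is defined) against the
constant model at level α = 0.05; failures are classified *nonsignificant*,
which makes the null classification rate exactly α (verified at 10,000
pure-noise genotypes). (2) Among significant genotypes, iterative
simplification walks cubic → quadratic → linear, stopping at the first
significant drop; the periodic terms are then tested against the shared
linear null, and the periodic class wins when significant with a likelihood
at least matching the retained polynomial's (periodic and cubic have equal
parameter counts, so this is an AIC comparison). Path tests run at
α/(number of path tests): a Bonferroni bound on the per-genotype
false-upgrade rate, without which ~14% of truly linear genotypes would be
promoted to spurious higher classes (the class-recovery tests require ≤10%).
(3) p-values use the exact finite-sample F distribution of the Gaussian
likelihood-ratio statistic by default; the large-sample χ² version
(`calibration="chisq"`) is anti-conservative at 33 observations (measured
type-I ≈ 0.094 at nominal 0.05) and is provided for comparison only.
Benjamini–Hochberg adjustment of the gate p-values across genotypes is
available and off by default; α, calibration and BH choices are recorded in
the output metadata.

**Sign classification.** Non-periodic classes take the sign of the fitted
change in log abundance between t = 0 and t = 240 (equivalently of the
average growth-rate change). Periodic fits are signed by phase: positive when
the oscillation is rising at the start of the first feed phase (sin
coefficient > 0), so two genotypes 180° apart always receive opposite signs.
Exact ties (measure zero) break to positive with a warning.

**Period scan.** The profile log-likelihood over a period grid (default
{30, 40, 50, 60, 70, 80} h) is reported in full, but the argmax excludes
periods at or below twice the sampling interval: they are beyond the grid's
Nyquist limit and alias exactly onto longer periods (on a 24 h grid a 40 h
sinusoid is indistinguishable from a 60 h one, since 1/24 − 1/40 = 1/60).
With the exclusion the 60 h selection is deterministic at the tested
signal-to-noise level.

## Oscillation clustering

Piecewise-fitness profiles of the periodic-class genotypes are z-scored per
genotype across intervals (constant profiles become zero rows and are
flagged) and clustered by Ward-linkage agglomerative clustering on Euclidean
distance, cut at k = 4 — the method and k are package choices (the grouping
they reproduce is visual), so k is configurable and a silhouette score is
always reported. Labels are renumbered by the centroid's peak interval,
making the numbering stable across runs. Four synthetic phase archetypes
(n = 50 each, noise SD 0.25) are recovered with adjusted Rand index ≥ 0.9
(tested at ARI = 1.0).

## Problem sizes and determinism

Default problem sizes are the study-scale ones — 4,000 genotypes, 99
libraries, 10⁶ reads — because the whole pipeline (generation, processing,
12,000 model fits) completes in a few seconds; tests that need calibration
accuracy use 10,000 pure-noise genotypes or 500 genotypes per class. All
randomness flows through explicit `numpy.random.default_rng` seeds;
`scripts/acceptance.py` derives every stochastic input from its `--seed`
argument.

## Known limitations

* Kinetic constants (`u_max`, `K`, `Y`) are plausible defaults, not fitted to
  measured nutrient assays; quantitative vessel concentrations should not be
  read as predictions for any particular strain.
* The ensemble model uses one limiting substrate; switching between two
  limitations is represented in the bulk model but genotype competition under
  dual limitation is not modeled.
* Trajectory models are Gaussian on log-transformed counts with a fixed
  pseudocount; there is no count-level (negative-binomial) likelihood, no
  random-slope hierarchy, and low-count genotypes near extinction violate the
  homoskedasticity assumption most.
* The synthetic generator specifies genotype trajectories marginally;
  apparent interactions arise only through compositional renormalization.
* Gene-function annotation (GO/GSEA) of selected genotypes or clusters is out
  of scope.
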