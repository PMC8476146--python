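# fluxsel

Selection dynamics in static and fluctuating chemostat environments: Monod
competition models, synthetic barcode-sequencing (barseq) data, and the
statistics that connect them — diversity erosion, the distribution of fitness
effects, and per-genotype trajectory model selection.

## The problem

A chemostat feeds fresh medium into a culture and removes culture at the same
dilution rate *D*, so at steady state the population's mean exponential growth
rate is pinned at *D*. Growing a pooled library of thousands of barcoded
genotypes (e.g. the *S. cerevisiae* haploid deletion collection) in such a
device and sequencing barcodes over time turns the chemostat into a massively
parallel fitness assay. The scientific question this package addresses is how
*temporally fluctuating* selection — a feed that switches between
carbon-limiting and nitrogen-limiting media with a 60 h period, or a static
feed perturbed by small nutrient boluses — reshapes the distribution of
fitness effects (DFE) and the maintenance of genetic diversity, compared with
static nutrient limitation.

The package has three layers:

1. **Mechanistic models** (`chemostat`, `ensemble`). Vessel nutrient and
   cell-density dynamics under dual-substrate Monod kinetics,

   dS/dt = D(R(t) − S) − (X/Y)·u,  dX/dt = (u − D)X,
   u = u_max / (1 + K_as/S_as + K_g/S_g),

   with square-wave (switch) and impulsive (pulse) feed schedules handled as
   exact events; an N-genotype single-substrate competition model
   dx_i/dt = (λ_i(S) − D)x_i scaling to thousands of genotypes; and the
   continuous-form Price equation dλ̄/dt = Var_p(λ) + Σ p_i dλ_i/dt as a
   diagnostic of quasi-steady-state selection.

2. **Synthetic data** (`synthetic`). Barseq count tables with the experimental
   structure of the study design: ~4,000 genotypes × 3 conditions × 3
   replicates × 11 samples over 240 h at 10⁵–10⁷ reads/library, genotype
   log-abundance trajectories drawn from five classes (flat, linear,
   quadratic, cubic, periodic), multinomial sequencing noise with optional
   gamma overdispersion, and ground truth returned for recovery testing.

3. **Analysis** (`processing`, `diversity`, `fitness`, `trajectory_models`,
   `clustering`). Library/genotype filters (100,000-read and 1,000-count
   thresholds), uptag/downtag summing, median-of-ratios normalization,
   replicate-correlation QC; Shannon diversity H = −Σ q ln q and its rate of
   change; relative fitness f_i = Δln(abundance)/Δt centered on the
   arithmetic mean across genotypes, full-course and piecewise; nested
   Gaussian trajectory models (constant → linear → quadratic → cubic, plus a
   sinusoid at the environmental period) selected per genotype by iterative
   likelihood-ratio simplification with exact finite-sample calibration; and
   Ward clustering of z-scored piecewise-fitness profiles of the oscillatory
   class.

Note the pipeline starts from count tables: matching raw reads to barcodes
(and discarding reads with any mismatch) happens upstream and is out of scope.

## Worked example

`examples/04_diversity_dfe.py` generates the full synthetic study
(seed 42), normalizes it, and prints:

```
condition   H(t=0)  H(t=240)  slope (nats/h)      top share(240h)
clim        8.285   3.098   -0.01823 [-0.02298, -0.01349]   0.665
nlim        8.284   2.579   -0.02058 [-0.02566, -0.01551]   0.748
switch      8.270   7.916   -0.00137 [-0.00160, -0.00115]   0.004
clim: DFE sd = 0.0037 /h, max = +0.0397 /h, min = -0.0129 /h over 3976 genotypes
switch: DFE sd = 0.0033 /h, max = +0.0133 /h, min = -0.0203 /h over 3987 genotypes
```

Reading: all three conditions start near the uniform maximum
H = ln 4000 ≈ 8.29 nats. Under static limitation a single extreme-fitness
genotype (+0.04/h, the DFE's beneficial tail) sweeps to ~70% of the
population and diversity collapses at ~0.02 nats/h; under the switching feed
the best genotype never exceeds ~0.4% and diversity barely moves, even though
the bulk DFE dispersions are similar. `examples/05_model_selection.py` then
shows the switching condition uniquely enriched for the periodic trajectory
class (~18% of genotypes vs ~1% in static conditions, with the true 700-member
oscillatory cohort recovered at recall 1.0, split between the two opposite
phases), and `examples/06_oscillation_clusters.py` clusters those genotypes
into four phase groups.

Each example script is a narrative entry point for one capability; the
`fluxsel` CLI (`simulate`, `generate`, `process`, `stats`, `fit`, `cluster`)
exposes the same pipeline for shell use.

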