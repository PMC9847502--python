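# Methods

This note documents the models implemented in `kirscreen`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Population kinetics

A well is described by the live-nucleus count `N(t)` and the cumulative
dead-cell count `M(t)`. Per-capita rates are defined by
`dN/dt = p(t) N` and `dM/dt = d(t) N`, with the birth rate
`b(t) = p(t) + d(t)`. Three estimators are provided.

**Endpoint estimators** (`estimate_rates`). `kP = ΔN/(N̄ Δt)`,
`kD = ΔM/(N̄ Δt)`, `kB = kP + kD`, with `N̄` the *endpoint mean*
`(N(t0)+N(tend))/2`. On exact exponential data with rate `r` this returns
`(2/Δt)·tanh(rΔt/2)`; the relative bias is bounded by `(rΔt)²/12`
(≈ 2% at `rΔt = 0.5`), so the estimator is consistent with the
exponential model. An alternative `endpoint_sum` convention (dividing by
`N(t0)+N(tend)` without the ½) is kept behind a flag for comparison with
legacy analyses; it converges to `r/2` and halves every reported rate.
The additivity `kB = kP + kD` holds identically for any input, as does
invariance to rescaling both counts (per-capita property). The default
window is the full imaging span, which in the simulator begins at
growth-factor addition; both are configurable. Replicate wells are
combined by averaging per-well rates (not by pooling counts).

**Exponential fit** (`fit_exponential`). Ordinary least squares of
`log N` on `t`; requires positive counts and ≥ 3 points. This is the
summary used for screen wells, where the constant-rate approximation is
deliberate: time-dependent parameters (e.g. peak birth rate) need many
more replicates than a screen affords.

**Instantaneous rates** (`instantaneous_rates`). Counts are smoothed with
a local quadratic (Savitzky–Golay) filter — default window 10 h, i.e. 5
samples at the 2 h imaging cadence, mirror-padded ends — and derivatives
taken by central differences on the smoothed series. Points where the
smoothed `N` is nonpositive are masked as NaN rather than raised, since
they occur legitimately in dying wells. Smoothing can shift apparent
event times by up to about half the window; wave-timing checks therefore
use a ±4 h acceptance band around the expected peak.

**Phenotypes.** The screen phenotype of an (inhibitor, dose) condition is
`Δk_p`: the well's `k_p` minus the mean `k_p` of the vehicle-control
(DMSO) wells *for the same growth factor on the same plate*, then
averaged over replicate wells. Dead-cell counts are not used in the
screen phenotype: at high death rates the dead-cell dye undercounts, so
only the nucleus-derived `k_p` is trusted.

## Dose mapping of inhibition profiles

Biochemical profiles give the fractional residual activity `r` of each
(inhibitor, kinase) pair at one reference concentration (default 1 µM).
Screen doses are mapped by single-site binding: `Kd = c_ref · r/(1−r)`
(infinite when `r ≈ 1`), `inhibition(dose) = dose/(dose + Kd)`. This is
parameter-free, monotone in dose, zero at zero dose, and exactly
reproduces `1−r` at the reference concentration. It ignores cooperative
binding and ATP-competition effects, which single-point profiling cannot
constrain anyway.

## Kinome regression

- **Features:** fractional inhibition (`1 − residual`, dose-mapped) of
  each *expressed* kinase; expression filter at ≥ 1.5 arbitrary units
  (boundary values kept). Using inhibition rather than residual activity
  makes pro-proliferative kinases carry negative coefficients; ranking is
  by |coefficient| so both signs are retained.
- **Model:** glmnet-convention elastic net,
  `(1/2n)||y − b0 − Xβ||² + λ(α||β||₁ + (1−α)/2||β||²)`, α = 0.15,
  features standardized to unit variance for fitting (coefficients
  reported on the original scale; intercept unpenalized). All doses are
  pooled into one model per growth factor (6 rows per inhibitor).
- **λ selection:** 100 log-spaced values from `λ_max` (the smallest λ
  that zeroes all coefficients) down four decades; 10-fold
  cross-validation with seeded shuffled folds; λ at minimum mean CV
  squared error; refit on all rows at that λ. Standardization is computed
  once on the full design (a standard shortcut; with 348 rows the
  fold-wise scale difference is negligible). The CV path runs at
  coordinate-descent tolerance 1e-4 with a precomputed Gram matrix; the
  final refit uses 1e-8.
- **Ranking and intersection:** non-zero coefficients sorted by
  decreasing |β|, ties broken lexicographically by kinase id (documented,
  deterministic). The cross-growth-factor intersection keeps kinases
  selected under every growth factor, ordered by ascending rank sum with
  the same lexicographic tie-break.

The solver is coordinate descent (scikit-learn). Its correctness is
checked in the test suite against an independent oracle: direct L-BFGS-B
minimization of the penalized objective via the positive/negative-part
split of β, with coefficient-wise agreement to 1e-4 on small instances,
plus the ridge/OLS and null-model limits.

## siRNA validation statistics

Effects are normalized to the plate's no-siRNA control (`effect = 1`
means no phenotype) and averaged over the three siRNAs per gene; the
s.e.m. is taken across siRNA-level means. The *siRNA mean* — not the
individual well — is the unit of analysis (three independent sequences
per gene guard against off-target artifacts; wells within one siRNA are
technical replicates). Significance per growth factor: one-way ANOVA
across gene groups plus control, then Dunnett's many-to-one comparison of
each gene against control at adjusted p < 0.05 (`scipy.stats.dunnett`).
A Holm-adjusted Welch fallback is available and recorded in the output.
Note Dunnett uses a pooled-variance statistic, so its adjusted p-values
dominate raw p-values in distribution (verified by simulation) but not
necessarily pointwise against Welch p-values. A receptor knockdown is
called *specific* when it is significant (and below 1) under the cognate
growth factor and significant under no other.

## The synthetic screen generator

The generator produces the statistical structure the analysis assumes,
with planted ground truth for recovery testing.

**States and events.** Each well starts with 255 cells. A pre-imaging
attachment period (24 h) in basal medium thins them at the basal
apoptotic rate. Time zero is growth-factor addition; counts are read on a
2 h grid for 48 h. Each surviving cell independently commits to the cycle
with probability `Emax·c/(c+EC50)` (Emax = 0.45, EC50 = 0.5 ng/ml — at
saturating dose roughly 40% of cells divide, matching the observed
320 → 450 wave), exits G0 after a lognormal delay (mean 8 h, sd 3 h) and
divides once after a further normal cycle time (21 ± 2.5 h, the measured
doubling time in full medium). The resulting population birth rate rises
near 20 h and peaks near 29 h post stimulation. Daughters stay quiescent
within the assay horizon. Death is exponential at
`basal·(1 − 0.9·c/(c+EC50))` per hour (basal 0.002/h), zeroed by a
caspase-inhibitor flag; inhibitor wells multiply the commitment
probability by `max(0, 1 − Σ_k w_k·inhibition_k(dose))` and add a
toxicity death term above a weighted-inhibition threshold of 0.8. The
linear commitment model is intentional: it makes the screen phenotype
linear in weighted inhibition, i.e. recovery by the regression is
well-posed, which is the property the planted-truth tests need.

Implementation: per-cell event times are sampled exactly (exponential
death, lognormal+normal division) and read out on the imaging grid — the
same per-cell granularity as a tau-leap at the imaging interval, without
step-discretization error; a full 4,608-well screen simulates in ~1 s.

**Observation model.** Detection thins cells persistently (each cell
carries one Bernoulli(0.97) detection flag, mirroring ~97% labelling
efficiency), so observed `M` stays non-decreasing and observed
`N(t)+M(t)−N(0)` equals the observed cumulative births — the
conservation law asserted in the tests. An optional 3% multiplicative
count error on `N` is off by default and breaks conservation when on.

**Biochemistry.** The kinase panel assigns expression so that exactly the
requested number of kinases clears the 1.5-unit cutoff. Each inhibitor
gets a dealt hit set (residual 0.02–0.2) over shuffled decks of the
kinase list — guaranteeing panel coverage when
`n_inhibitors × hits ≥ n_kinases` — and weak background elsewhere
(residual 0.85–1.0). The weak background is informative: mapped through
single-site binding it produces small but systematic inhibition at the
top doses, which is what lets the regression distinguish a true driver
from kinases that merely share its strong-hit inhibitor.

**Screen design.** One 384-well plate per (growth factor, replicate):
58 inhibitors × 6 doses (5 µM top, 3-fold serial dilution) plus 36 DMSO
control wells fills a plate exactly; 4 replicates × 3 growth factors
(working doses FGF2 1.25, VEGFA 20, HGF 20 ng/ml, the concentrations used
for the validation experiments; the screen's own concentrations are an
assumption). Ground truth plants 5 effect kinases per growth factor, 3
shared, weights uniform in [0.5, 1], all drawn from the expressed subset.

**What is not emulated.** No imaging artifacts, cell motility, contact
inhibition, density effects, plate-edge effects, or batch drift; no
receptor-level signaling detail beyond the commitment dose response; no
knockdown-efficiency variation beyond a single efficiency constant.
Passing recovery tests therefore demonstrates the *analysis* is correct
under the assay's assumed statistical structure — not that real screens,
with their unmodelled artifacts, will reach the same recovery rates.

## Problem sizes and tolerances

Tests and the acceptance script use: 200 simulated wells for wave-timing
calibration (peak within 26–34 h); the full-scale synthetic regression
(348 rows × 200 expressed kinases per growth factor, phenotype noise sd
20% of the maximal planted effect, generated directly from the linear
effect model) for recovery; 1000 null families for the family-wise error
rate (bound 0.05 plus two Monte-Carlo standard errors) and 300 repeats
for power. Elastic-net oracle agreement is asserted at 1e-4, estimator
closed forms at 1e-9, exponential-fit recovery at 1e-6 relative.

## Known limitations

- The endpoint estimator is biased on strongly non-constant rate
  profiles (it summarises the wave, not its shape); this is by design.
- KIR cannot separate kinases with identical inhibition profiles across
  the whole panel; ranking resolution degrades as profiles become
  collinear (fewer inhibitors, fewer hits per kinase).
- Dunnett p-values from scipy are themselves computed by randomized
  quadrature and carry small Monte-Carlo noise; a seed is passed for
  reproducibility.
- The dose-response stage reports descriptive per-dose summaries only;
  no sigmoid fitting (EC50 estimation) is attempted.
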