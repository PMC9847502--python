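# kirscreen

Analysis tools for quantitative endothelial-cell proliferation screens:
birth/death-rate kinetics from time-lapse counts, kinome-regression (KIR)
target deconvolution from kinase-inhibitor panels, rank aggregation across
growth factors, and siRNA validation statistics — plus a seeded synthetic
screen generator with planted ground truth so every stage can be tested
end-to-end without any external data.

## The problem

Endothelial cells proliferate in response to several pro-angiogenic growth
factors (FGF2, VEGFA, HGF), which makes receptor-level anti-angiogenic
blockade leaky: block one receptor and another growth factor substitutes.
A complementary strategy is to look *downstream* for kinases required for
proliferation regardless of which growth factor provides the stimulus. The
package implements the analytical side of that search for users analysing
(or prototyping) 384-well time-lapse proliferation screens:

1. **Kinetics.** A well yields nucleus counts `N(t)` and cumulative
   dead-cell counts `M(t)`. The per-capita rates are

   ```
   p(t) = (dN/dt)/N      death  d(t) = (dM/dt)/N      birth  b(t) = p + d
   ```

   and each well is summarised by endpoint estimators

   ```
   kP = ΔN / (N̄ Δt),   kD = ΔM / (N̄ Δt),   kB = kP + kD,
   N̄ = (N(t0)+N(tend))/2
   ```

   On exact exponential data the estimator returns `(2/Δt)·tanh(kΔt/2)`,
   i.e. it is consistent with relative bias ≤ `(kΔt)²/12`. Exponential
   fits (`N(t)=N0·e^{kP t}`) and smoothed instantaneous rate curves are
   also provided.

2. **Kinome regression (KIR).** Each kinase inhibitor hits many kinases
   with a profiled fractional inhibition. Across inhibitors × doses, the
   proliferation deficit `Δk_p` versus plate-matched vehicle control is
   modelled as linear in the fractional inhibition of each expressed
   kinase, fit by elastic net (glmnet convention)

   ```
   (1/2n)·||y − b0 − Xβ||² + λ·( α||β||₁ + (1−α)/2·||β||² ),   α = 0.15
   ```

   with λ chosen at minimum 10-fold cross-validated MSE. The non-zero
   coefficients, ranked by |β|, are the implicated kinases; kinases
   selected under *every* growth factor are intersected and ordered by the
   sum of their per-growth-factor ranks.

3. **siRNA validation.** Knockdown effects (three siRNAs per gene,
   normalized to the no-siRNA control, siRNA means as the unit of
   analysis) are tested per growth factor by one-way ANOVA followed by
   Dunnett many-to-one comparison against the control; receptor knockdowns
   additionally get a cognate-versus-non-cognate specificity call.

4. **Synthetic screens.** A stochastic per-cell simulator reproduces the
   assay's structure — ~255 quiescent cells per well, growth-factor-dosed
   cycle commitment, a semi-synchronous division wave peaking ~30 h after
   stimulation, low basal apoptosis suppressed by growth factor, inhibitor
   effects acting through planted kinase weights, detection noise — so the
   whole pipeline can be validated against known answers.

## Worked example

`examples/03_kinome_regression.py` plants 4 driver kinases per growth
factor (3 shared) in a 45-inhibitor × 6-dose synthetic screen and runs the
full KIR step:

```
90 expressed kinases enter the regression

FGF2: lambda = 3.56e-03, 15 kinases selected
    1. K0014 * coef = -0.01124
    2. K0038 * coef = -0.00972
    3. K0113 * coef = -0.00578
    4. K0032 * coef = -0.00548
...
rank-sum intersection (selected under every growth factor):
   K0014 * rank sum 6 (per-GF ranks (1, 2, 3))
   K0032 * rank sum 6 (per-GF ranks (4, 1, 1))
   K0038 * rank sum 10 (per-GF ranks (2, 4, 4))

all planted shared kinases recovered: True
```

Stars mark planted drivers; a negative coefficient means inhibiting that
kinase lowers the proliferation rate (units: per-hour rate loss at full
inhibition). The intersection recovers exactly the three kinases planted
in all growth factors. The other examples cover dose-dependent rate
estimation (`01`), the division-wave timing (`02`), siRNA statistics with
receptor specificity (`04`) and the end-to-end pipeline (`05`).

There is also a thin CLI over the pipeline:

```
kirscreen all --seed 5 --outdir out/          # or: simulate / rates / kir /
kirscreen kir --config cfg.yaml --outdir out/ # sirna / dose-response
```

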