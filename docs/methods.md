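# Methods

## Model

Blade length and blade width (mm) of successive main-culm leaves are
described by a three-phase expolinear-logistic curve of leaf position
`x` (1-based from the bottom; the flag leaf is position TLN):

* **expolinear rise** for `x < xs`:
  `y = L1 + (cm/rm) * ln(1 + exp(rm*(x - tb - 1)))`.
  The curve tends to `L1` (first-leaf size) far below `tb` and to the line
  with slope `cm` far above it; `rm` controls how sharp the transition is.
* **logistic decay** for `x >= xs`:
  `y = Ymax*Ys / (Ymax + (Ys - Ymax)*exp(dr*(x - xs)))` with
  `Ymax` the expolinear value at `xs` and `Ys = Ymax + dsl`.
  The value at `xs` is exactly `Ymax`, so the two branches are continuous
  by construction.

Leaf area is `length * width * shape_factor`, with 0.71 for all leaves and
0.635 for the flag leaf. The classic one-equation bell curve of area versus
position (`Y0*exp(a*(x-x0)^2 + b*(x-x0)^3)`) is provided as a comparison
baseline only.

Within a species, `xs` and `dr` are driven by the total leaf number:

* `xs(TLN)`: linear (maize, pearl millet) or continuous segmented with one
  intercept, two slopes and a breakpoint (sorghum, break at TLN 20.5). Only
  the continuous form is identifiable from that parameterization, so
  continuity at the breakpoint is imposed.
* `dr(TLN)`: declining line up to a species breakpoint, constant beyond.
  The plateau value is defined as the line evaluated at the breakpoint
  (again, continuity), since no separate plateau constant is published.

`L1, cm, rm, tb, dsl` are fixed per species and trait. The packaged generic
sets for the three species (values and standard errors) are stored in
`src/leafsize/data/default_parameters.yaml` and loaded at run time.

Two documented quirks of the parameterization are accepted as-is: the
expolinear value at `x = 1` slightly exceeds `L1` (L1 is the lower
asymptote, not the literal value at position 1), and the pearl-millet
blade-width set has `tb + 1 > xs`, i.e. its peak falls on the curved part
of the expolinear term. Both are mathematically well-defined; the package
therefore validates only sign constraints (`L1, cm, rm > 0`;
`dr, dsl >= 0`) and treats an `xs` outside `(1, TLN)` as a warning, not an
error.

## Numerics

The expolinear term is evaluated through `logaddexp` (softplus), and the
logistic term in log space, so exponent arguments of any magnitude stay
finite. Degenerate settings `dsl = 0` or `dr = 0` yield a flat post-peak
profile rather than an error. All internal units are millimetres; any
centimetre display is presentation-level rescaling only.

## Calibration pipeline

1. **Grouping.** Observations are grouped by genotype and TLN per trait;
   groups with fewer than `min_obs = 8` observations are skipped (logged).
2. **Per-group curve fit.** Levenberg-Marquardt nonlinear least squares
   (lmfit `leastsq`; bounds via MINPACK-style transforms) on the seven
   parameters, standard errors from the Jacobian-based covariance. The
   objective is rugged in `xs` because observations switch branch as `xs`
   crosses them, so the fit is multistart: `xs` is profiled on a 0.25-step
   grid around the empirical peak (offset off integer positions), the
   expolinear rise (4 parameters) and the decay (`dr`, `dsl` given `Ymax`)
   are fitted separately per candidate — both well-behaved subproblems on
   per-position means — and the best four assemblies are polished by full
   LM, together with a small deterministic ladder of `rm`/`tb` starts.
   Observations are canonically sorted by position, making results
   invariant to input order. Non-convergence is reported via a flag, never
   an exception.
3. **Identifiability screening.** A group contributes its `xs`, `dr` and
   `dsl` estimates only if at least `min_decay_points = 3` observations lie
   beyond the fitted `xs`: low-TLN groups observe essentially no decay
   phase and return arbitrary decay parameters at near-zero residual.
   (Empirically, aberrant decay-rate estimates are concentrated at low
   TLN.) `L1, cm, rm, tb` are pooled from all converged groups.
4. **TLN regressions.** `xs` on TLN by OLS (linear) or by profiling the
   residual sum of squares over a 0.1-resolution breakpoint grid followed
   by bounded scalar polishing (segmented; breakpoint free by default,
   fixable at 20.5). `dr` on TLN by the same profiling approach with the
   decline-plateau design, after outlier removal (below).
5. **dr outlier rule.** Robust Mahalanobis distances of the (TLN, dr)
   pairs from a minimum-covariance-determinant location/scatter estimate,
   thresholded at the chi-square(2) quantile (default 0.975). Because the
   clean point cloud is bilinear rather than elliptical, a candidate is
   confirmed only if it also deviates from a preliminary decline-plateau
   fit by more than the matching normal quantile of the robust (MAD)
   residual scale, floored at 1e-6 of the data range. A genuinely clean
   trend therefore never loses points, while a grossly inflated value is
   flagged alone. This is one admissible reading of an under-specified
   published rule; the quantile is a configuration knob.
6. **Pooling.** The fixed parameters are the unweighted mean of the
   per-group estimates (inverse-variance weighting available behind
   `pooling="ivw"`), after a median ± 5·MAD trim that removes estimates a
   group simply did not constrain (e.g. `cm` when the linear phase is never
   reached within the group's positions). Their standard errors are
   standard errors of the pooled mean; rule coefficients carry their
   regression standard errors.

Parameter–TLN association is reported through each regression's slope and
standard error; mixed-effects significance screening is out of scope.

## Synthetic data generator

`generate_dataset` emulates the structure of the multi-experiment training
tables: several genotypes per species, a spread of TLN values
(maize 11–25, sorghum 9–44, pearl millet 11–27 in the `table1_style_panel`
presets), and one length/width value per leaf per plant. Values are exact
model predictions under a known truth set plus independent measurement
noise — additive Gaussian by default (sd 20 mm length, 3 mm width, loosely
matched to the dispersion of the published training tables) or proportional
(CV). Results are truncated at a 1 mm physical floor, and values can be
deleted at a configurable missing rate. Optional genotype variation
perturbs `cm` and `L1` multiplicatively (lognormal). A seed is mandatory
and fully determines the output.

What the generator does **not** emulate: within-plant error correlation,
environment effects, tillers, senescence, or genotype differences beyond
the `cm`/`L1` perturbation. Passing recovery tests therefore show that the
pipeline inverts its own model family under realistic noise — not that the
model is correct for any particular field dataset.

## Recovery experiments and problem sizes

The acceptance-level checks use: per-group noiseless recovery at TLN 17–21
(maize length) and 16–20 (sorghum length and width); rule recovery from
noiseless points at TLN 14–30 (sorghum segmented xs), 10–22 (maize dr
plateau) and 11–25 (maize linear xs); end-to-end noiseless calibration on
one-genotype panels spanning each species' full TLN range; and a noisy
end-to-end run with 5% proportional noise, three genotypes and 10 plants
per TLN at a fixed seed, judged against the published standard-error bands
(at least 80% of parameters inside). The width-trait `L1` bands (±0.06 mm)
are a fraction of the pooled estimator's standard deviation at that noise
level, so a few parameters are expected to fall outside; the 80% margin
absorbs them.

## Known limitations

* Standard errors come from local covariances; no bootstrap or profile
  intervals.
* Per-group fits are independent; no parameter sharing across groups prior
  to pooling, and no hierarchical (mixed-effects) estimation.
* The breakpoints of the TLN rules are reported without standard errors.
* Thermal-time leaf appearance, senescence, tillering and LAI simulation
  are out of scope.
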