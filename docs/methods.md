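# Methods

## Model and hypotheses

The data for one subject (or simulation replicate) are a real `d × T` matrix:
`d` variables — typically ROI-averaged BOLD signals — observed at `T` time
points.  The working model is a piecewise-constant covariance: under the null
hypothesis `Cov(y_1) = … = Cov(y_T)`; under the single-change alternative the
covariance is constant up to an unknown `τ` (the last index of the first
regime) and constant but different afterwards.  `θ = τ/T` expresses the
change location as a fraction of the series.  The test statistic is built
from Gaussian–Wishart theory, but inference never uses Gaussian quantiles:
critical values come from block permutation, so the procedure is usable for
non-Gaussian, serially dependent data (the Wishart theory then acts as a
variance-stabilizing standardization rather than an exact null law).

## The greatest-root change process

For a split at `t`, the segment scatter matrices `A_t` (observations `1..t`
about their segment mean) and `B_t` (the rest) are Wishart with `t` and
`T − t` degrees of freedom under the null.  All information about a
covariance discrepancy between the segments is carried by the eigenvalues of
the pencil `(A_t + B_t)^{-1} A_t`, which are invariant to any common linear
transformation of the variables — the population covariance scale drops out.
The largest eigenvalue `ϕ` (the greatest-root statistic, equivalently the
largest root of `det[A − ϕ(A+B)] = 0`) is computed by a symmetric
generalized eigenproblem after Cholesky-whitening `A + B`; `A + B` is never
inverted explicitly, which matters for `d = 20` with short segments.

Johnstone's Tracy–Widom approximation for the greatest root states that
`logit(ϕ) = log(ϕ/(1−ϕ))`, centered and scaled by

    μ = 2 log tan((φ+γ)/2),
    σ³ = 16/(m+n−1)² · 1/[sin²(φ+γ) sin φ sin γ],
    sin²(γ/2) = (min(d,m)−½)/(m+n−1),  sin²(φ/2) = (max(d,m)−½)/(m+n−1),

is approximately TW₁ for a `W_d(Σ, m)` numerator and `W_d(Σ, n)` denominator.
The change process standardizes both extreme roots:

    G_t = [logit ϕ_A − μ(d,t,T−t)]/σ(d,t,T−t) − [logit ϕ_B − μ(d,T−t,t)]/σ(d,T−t,t),

with `ϕ_A = λ₁[(A+B)⁻¹A]` and `ϕ_B = λ₁[(A+B)⁻¹B] = 1 − λ_d[(A+B)⁻¹A]`
(computed through that complementarity, so one eigendecomposition serves
both terms).  `E[G_t] = 0` under the null for every `t`; a covariance change
at `τ` skews the two standardized roots in opposite directions, and
`Λ_T = max G_t²` with `τ̂ = argmax G_t²` locates it.

### Numerical and convention choices

* **Angle relations.**  The squared form `sin²(·/2) = argument` is the
  default (`tw_form="squared"`).  The package also exposes a literal variant
  `tw_form="literal"` with `sin(·/2) = argument`, retained for comparison: in
  simulation it produces a heavily biased estimator (mean `θ̂ ≈ 0.34` for a
  true 0.5), while the squared form reproduces the benchmark tables, and the
  `σ³` expression is exactly the one that accompanies the squared
  parameterization.
* **B-term centering.**  The full `(dim, df_num, df_den)` triple is swapped
  for the B-term, i.e. the B-root is treated as the greatest root of the
  reversed Wishart pair.  Reusing the A-term centering for both roots was
  evaluated and collapses the estimator entirely (`θ̂ ≈ 0.15` under a true
  0.5), so the swap is not configurable.
* **Degrees of freedom.**  Defaults are `t` and `T − t` (the Wishart
  statement for the segment scatters); `df_correction="mean_corrected"`
  subtracts one from each for the estimated segment means.  The two differ
  negligibly at `T = 200`.
* **Admissible range.**  `t_min = max(d + 2, 30)` by default; splits run over
  `t_min ≤ t ≤ T − t_min`.  The floor of 30 keeps enough degrees of freedom
  in the smaller Wishart segment for the TW approximation to be usable; the
  `d + 2` part guards conditioning for larger `d`.
* **Ties and boundaries.**  `argmax` ties resolve to the smallest `t`
  (determinism).  Roots outside `(ε, 1−ε)` with `ε = 1e−12` are clamped
  before the logit and counted (`n_clamped`); clamping can be disabled, in
  which case a boundary root raises.
* **Singular splits.**  If the batched Cholesky of `A + B` fails, the
  computation falls back to per-split generalized solves, skipping singular
  splits; only if every admissible split is singular does the analysis
  error out.

Under very strong changes `G_t²` forms a broad plateau around `τ` (both
standardized roots saturate), so occasional localization misses of 10–20
points occur even when the change is obvious; this is a property of the
statistic, not of the implementation.

## Block-permutation inference

Exchangeability fails for serially dependent data, so permutation operates on
contiguous time blocks: the axis is cut into blocks of `K` consecutive points
(default `K = 5`, final short block retained), block order is drawn uniformly,
within-block order is preserved.  The threshold is the order statistic at
rank `⌈(1−α)(n_perm+1)⌉` of the permuted statistics and the p-value is the
add-one estimate `(1 + #{permuted ≥ observed})/(1 + n_perm)`, which is never
zero and consistent with the threshold rule.  Thresholds are computed
independently per series, matching subject-wise testing.  Blocks are
non-overlapping and non-circular; moving-block and stationary-bootstrap
variants are deliberately out of scope.

Multiple change-points: binary segmentation re-applies the permutation test
within each sub-segment (fresh permutations per segment, seeds derived from
the top-level seed), stopping at non-rejection or when a segment is shorter
than `2 t_min`.  No multiplicity correction is applied across the recursion —
a known caveat: the family-wise error of the full segmentation exceeds `α`.

## The vech-CUSUM comparator

The comparator summarizes second moments by `v_j = vech[y_j y_j′]` (lower
triangle, column-major) and forms the CUSUM bridge
`S_t = (Σ_{j≤t} v_j − (t/T) Σ_j v_j)/√T`, studentized by the sample
covariance `Σ̂` of the `v_j` sequence and maximized over the same admissible
range as the greatest-root detector.  Raw outer products are used (no mean
subtraction; a global demeaning flag exists).  When `d(d+1)/2 ≥ T` the
moment covariance cannot be full rank; a Moore–Penrose pseudo-inverse
(relative cutoff `1e−10`) is applied with a warning.  No long-run (HAC)
covariance correction is used by default.  Inference and admissible-range
conventions are shared with the main detector for comparability.

## Synthetic data: MVAR scenarios

The generator emulates per-subject ROI series as stationary vector
autoregressions with a single regime switch, the standard benchmark design
for covariance change detection:

    y_u = Σ_{k=1..p} B_k y_{u−k} + ε_u,   ε_u ~ N(0, Σ₁) for u ≤ τ, N(0, Σ₂) after.

Cases `i`/`ii` are MVAR(1) with base coefficient loading 0.2; cases
`iii`/`iv` are MVAR(2) with loadings 0.2 and 0.1.  After `τ`, `0.1·I` is
added to every coefficient matrix and the innovation covariance switches
between `0.5·I`-type and "diagonal 1.0 / off-diagonal 0.1"-type matrices
(`i`/`iii` increase the covariance, `ii`/`iv` decrease it; the MVAR(2) small
covariance has off-diagonal 0.01).  The printed form of the base coefficient
matrix is a bracketed vector `[(0.2)𝟙, 0, …, 0]`, which admits several
readings; the package defaults to the scalar reading — the vector
`(0.2, 0, …, 0)` as first column, i.e. a single nonzero entry at (1,1) —
which reproduces the published benchmark cells best, and exposes
`psi_form ∈ {scalar, ones-column, ones-row}` for the alternatives (the
ones-column reading couples every variable to the first and visibly degrades
the tabled localization proportions).  `switch_coefficients=False` gives a
covariance-only change.

Defaults: `τ = round(θT)`; burn-in of 200 samples generated under the
pre-change regime from zero initial values and discarded; both regimes are
validated for stationarity via the companion-matrix spectral radius, and the
innovation covariances for symmetric positive definiteness.  Multi-subject
panels draw per-subject generators by seed-sequence spawning, so panels are
reproducible and independent of execution order, and support subject-varying
`τ`.

What the generator does **not** emulate: hemodynamic-response convolution,
scanner drift and physiological noise, spatial correlation between ROI
parcels beyond the innovation covariance, non-Gaussian innovations, and
gradual (non-abrupt) connectivity changes.  Passing the simulation benchmarks
therefore demonstrates correct behaviour for abrupt covariance breaks in
short-memory linear series — not performance on real fMRI.

## Benchmark harness

`run_benchmark` simulates `n_reps` independent replicates (replicate seeds
spawned from the master seed by index), estimates `τ̂` with each requested
estimator — estimation only, no permutation testing inside the loop — and
aggregates: mean and median of `θ̂`, root mean squared error of `θ̂` about
`θ` (reported under the row label "MSE" in the table layout), and `p5`, the
proportion of replicates with `|τ̂ − τ| < 5` (strict, on the time-point
scale).  Replicate-level estimates are returned for audit.  The test suite
exercises the harness at a 200-replicate quick profile with tolerances
widened to roughly twice the Monte-Carlo standard error; the acceptance
script runs the full 1000-replicate profile (≈ 30 s total for the eight
tabled cells on one CPU: the `d = 20` scenarios dominate at ≈ 10 s each).

## Known limitations

* The TW standardization assumes `t, T − t ≥ d`; the method is not designed
  for the high-dimensional regime `d > T`, and no eigenvalue de-biasing
  beyond the logit correction is applied.
* Localization precision saturates for very strong changes (plateau effect
  above) and degrades near the admissible-range boundary.
* Binary segmentation inherits the single-test level only per segment.
* The comparator's behaviour under rank-deficient `Σ̂` depends on the
  pseudo-inverse cutoff; with `d = 20`, `T = 200` its studentization is
  effectively projected onto a data-driven subspace.
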