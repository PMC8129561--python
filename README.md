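# rmtcpt

Change-point detection for the covariance (functional-connectivity) structure
of multivariate time series, built on random-matrix-theory greatest-root
statistics.

Dynamic functional connectivity analyses of fMRI ask *when* the dependence
structure among a set of brain regions (ROIs) reorganizes.  Given a `d × T`
ROI-by-time matrix for one subject, `rmtcpt` tests the constancy of the
covariance over time and estimates the time point `τ` at which it changes,
without sliding windows and without parametric assumptions on the critical
values.  The same machinery applies to any multivariate series with a
suspected covariance break.

## Method

For each admissible split `t`, form the within-segment scatter matrices

    A_t = Σ_{u ≤ t} (y_u − ȳ_t)(y_u − ȳ_t)′,
    B_t = Σ_{u > t} (y_u − ȳ*_t)(y_u − ȳ*_t)′,

which are Wishart `W_d(Σ, t)` and `W_d(Σ, T−t)` under a constant Gaussian
covariance.  The greatest root `ϕ_t = λ₁[(A_t+B_t)⁻¹A_t]` compares the
segments; its logit `W = log(ϕ/(1−ϕ))`, centered by `μ_t` and scaled by
`σ_t` from Johnstone's Tracy–Widom approximation for the largest root of a
Wishart pair, is approximately `TW₁`-distributed.  The change process

    G_t = TW-standardized logit λ₁[(A+B)⁻¹A] − TW-standardized logit λ₁[(A+B)⁻¹B]

has mean zero under the null; the test statistic and estimator are

    Λ_T = max_t G_t²,     τ̂ = argmax_t G_t²  (θ̂ = τ̂/T).

Critical values come from block permutation (contiguous time blocks, default
size 5, shuffled), which remains valid under short-range serial dependence.
Multiple change-points are found by binary segmentation.  The vech-CUSUM
covariance break statistic (`S_t' Σ̂⁻¹ S_t` over the cumulated half-vectorized
outer products) is included as a comparator, and an MVAR(1)/MVAR(2) scenario
generator plus a Monte-Carlo harness reproduce the estimator's benchmark
study.

## Worked example

```bash
rmtcpt simulate --case i --d 5 --T 200 --theta 0.5 --seed 42 -o series.tsv
rmtcpt detect series.tsv --permute --n-perm 199 --seed 7
```

which prints

```json
{
  "tau_hat": 102,
  "theta_hat": 0.51,
  "lambda_T": 216.20517476457192,
  "threshold": 56.15558174534284,
  "p_value": 0.005,
  "rejected": true,
  "config": { "method": "rmt", "...": "..." }
}
```

The simulated scenario is a 5-dimensional MVAR(1) whose innovation covariance
jumps from `0.5 I` to diagonal 1.0 / off-diagonal 0.1 after `τ = 100`; the
detector localizes the break at `τ̂ = 102` and the block-permutation test
rejects covariance constancy at the 5% level (`Λ_T` far above the permutation
threshold, p ≈ 0.005).  The same series analysed with the comparator
(`--method aue`) gives `τ̂ = 106`.

From Python:

```python
from rmtcpt import build_scenario, simulate_mvar, detect_change_point

y = simulate_mvar(build_scenario("i", d=5, T=200, theta=0.5), seed=42)
res = detect_change_point(y)
print(res.tau_hat, res.lambda_T)   # 102 216.20517475375442
```

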