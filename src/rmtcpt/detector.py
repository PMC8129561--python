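"""Greatest-root change-point detection for the covariance structure of a
multivariate time series.

The observed series is a ``d x T`` matrix (variables/ROIs by time points).
Under the null hypothesis the covariance of the observations is constant in
time; under the alternative there is a single change-point ``tau`` — the last
time index of the first covariance regime.  For every admissible split ``t``
the series is divided into segments ``1..t`` and ``t+1..T`` with within-segment
scatter matrices ``A_t`` and ``B_t``.  The greatest root

    phi_t = lambda_max[(A_t + B_t)^{-1} A_t]

compares the two segments; its logit, centered and scaled by the Tracy-Widom
(Johnstone) constants for the corresponding Wishart pair, is approximately
Tracy-Widom distributed under the null.  The change process

    G_t = TW[lambda_max of the A-pencil] - TW[lambda_max of the B-pencil]

has mean zero under the null; the test statistic is ``Lambda_T = max_t G_t^2``
and the change-point estimate is the (smallest) maximizing ``t``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

#: Default floor for the admissible split range; splits run over
#: ``t_min <= t <= T - t_min`` so both Wishart segments keep enough degrees
#: of freedom.
DEFAULT_T_MIN_FLOOR = 30

#: Greatest roots are clamped into (CLAMP_EPS, 1 - CLAMP_EPS) before the logit.
CLAMP_EPS = 1e-12

TWForm = Literal["squared", "literal"]
DFCorrection = Literal["plain", "mean_corrected"]


class SingularScatterError(np.linalg.LinAlgError):
    """Pooled scatter matrix is singular (or too ill-conditioned) at a split."""

    def __init__(self, t: int, detail: str = ""):
        self.t = t
        super().__init__(
            f"singular pooled scatter matrix at split t={t}" + (f": {detail}" if detail else "")
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A ``d x T`` observation matrix for one subject or replicate.

    Rows are variables (e.g. ROI signals), columns are time points.  Requires
    ``T > 2 d`` so that both Wishart segments can be non-degenerate somewhere,
    and all entries finite.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={v.ndim}")
        d, T = v.shape
        if d < 1 or T < 1:
            raise ValueError(f"empty matrix of shape {v.shape}")
        if T <= 2 * d:
            raise ValueError(
                f"series too short: T={T} must exceed 2*d={2 * d} "
                "for both covariance segments to be non-degenerate"
            )
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(f"non-finite entry at (row={bad[0]}, col={bad[1]})")
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScatterPair:
    """Within-segment scatter matrices for the split after time point ``t``.

    ``a`` sums outer products of the first ``t`` observations about their
    segment mean ``mean_left``; ``b`` does the same for the remaining
    ``T - t`` observations about ``mean_right``.  Time indices are 1-based.
    """

    a: np.ndarray
    b: np.ndarray
    t: int
    mean_left: np.ndarray
    mean_right: np.ndarray


@dataclass(frozen=True)
class TWCentering:
    """Johnstone centering/scaling for the logit of a greatest root.

    For a Wishart pair with ``dim`` variables and ``(df_numerator,
    df_denominator)`` degrees of freedom, the angles gamma and phi are defined
    through arcsine relations in the arguments ``(min(dim, m) - 1/2)/(m+n-1)``
    and ``(max(dim, m) - 1/2)/(m+n-1)``; then

        mu      = 2 log tan((phi + gamma)/2)
        sigma^3 = 16 / (m+n-1)^2 / [sin^2(phi+gamma) sin(phi) sin(gamma)]
    """

    mu: float
    sigma: float
    phi_angle: float
    gamma_angle: float
    dim: int
    df_numerator: float
    df_denominator: float


@dataclass(frozen=True)
class ChangeProcess:
    """The change process over the admissible split range.

    ``g[i]`` is ``G_t`` at ``t = t_values[i]``; ``lambda_T = max G_t^2``;
    ``tau_hat`` is the smallest maximizing split; ``theta_hat = tau_hat / T``.
    """

    t_values: np.ndarray
    g: np.ndarray
    lambda_T: float
    tau_hat: int
    theta_hat: float
    n_clamped: int = 0


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a change-point analysis on one series."""

    tau_hat: int
    theta_hat: float
    lambda_T: float
    threshold: float | None = None
    p_value: float | None = None
    rejected: bool | None = None
    process: ChangeProcess | None = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# Scatter matrices
# ---------------------------------------------------------------------------


def compute_scatter_pair(y: TimeSeriesMatrix, t: int) -> ScatterPair:
    """Segment scatter matrices ``(A_t, B_t)`` for the split after time ``t``.

    Direct two-pass computation; `iter_scatter_pairs` provides the equivalent
    incremental route used by `change_process`.
    """
    v = y.values
    T = y.T
    if not 1 <= t <= T - 1:
        raise ValueError(f"split index t={t} outside valid range [1, {T - 1}]")
    left = v[:, :t]
    right = v[:, t:]
    m_l = left.mean(axis=1)
    m_r = right.mean(axis=1)
    cl = left - m_l[:, None]
    cr = right - m_r[:, None]
    return ScatterPair(a=cl @ cl.T, b=cr @ cr.T, t=t, mean_left=m_l, mean_right=m_r)


def iter_scatter_pairs(y: TimeSeriesMatrix, t_values: Sequence[int]) -> Iterator[ScatterPair]:
    """Yield scatter pairs at increasing splits by incremental update.

    Running first/second moment sums are advanced one observation at a time;
    each emitted pair agrees with :func:`compute_scatter_pair` to numerical
    tolerance.
    """
    v = y.values
    d, T = v.shape
    t_values = list(t_values)
    if any(t2 <= t1 for t1, t2 in zip(t_values, t_values[1:])):
        raise ValueError("t_values must be strictly increasing")
    if t_values and not (1 <= t_values[0] and t_values[-1] <= T - 1):
        raise ValueError(f"split indices must lie in [1, {T - 1}]")
    s_tot = v.sum(axis=1)
    o_tot = v @ v.T
    s = np.zeros(d)
    o = np.zeros((d, d))
    t_cur = 0
    for t in t_values:
        while t_cur < t:
            col = v[:, t_cur]
            s += col
            o += np.outer(col, col)
            t_cur += 1
        m_l = s / t
        m_r = (s_tot - s) / (T - t)
        a = o - t * np.outer(m_l, m_l)
        b = (o_tot - o) - (T - t) * np.outer(m_r, m_r)
        yield ScatterPair(a=a, b=b, t=t, mean_left=m_l, mean_right=m_r)


# ---------------------------------------------------------------------------
# Greatest root and Tracy-Widom standardization
# ---------------------------------------------------------------------------


def greatest_root(pair: ScatterPair, cond_max: float = 1e12) -> float:
    """Largest eigenvalue ``phi`` of ``(A+B)^{-1} A``, in ``[0, 1]``.

    Solved as the symmetric generalized eigenproblem ``A x = phi (A+B) x``
    (Cholesky-whitened internally); ``A + B`` is never explicitly inverted.
    """
    pooled = pair.a + pair.b
    if np.linalg.cond(pooled) > cond_max:
        raise SingularScatterError(pair.t, f"condition number exceeds {cond_max:g}")
    try:
        w = scipy.linalg.eigh(pair.a, pooled, eigvals_only=True)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as e:  # pragma: no cover
        raise SingularScatterError(pair.t, str(e)) from e
    return float(w[-1])


def tw_centering(
    dim: int,
    df_num: float,
    df_den: float,
    form: TWForm = "squared",
    strict: bool = False,
) -> TWCentering:
    """Tracy-Widom centering/scaling for the logit greatest root.

    ``form='squared'`` applies the arcsine relations as ``sin^2(angle/2) =
    argument`` (the standard greatest-root approximation); ``form='literal'``
    uses the literal ``sin(angle/2) = argument``.  With ``strict=True`` a
    degrees-of-freedom deficit (``df < dim``) raises instead of warning.
    """
    if min(df_num, df_den) < dim:
        msg = f"degrees of freedom ({df_num}, {df_den}) below dimension {dim}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    denom = df_num + df_den - 1.0
    arg_gamma = (min(dim, df_num) - 0.5) / denom
    arg_phi = (max(dim, df_num) - 0.5) / denom
    for name, a in (("gamma", arg_gamma), ("phi", arg_phi)):
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"arcsine argument for {name} outside [0, 1]: {a}")
    if form == "squared":
        gamma = 2.0 * math.asin(math.sqrt(arg_gamma))
        phi = 2.0 * math.asin(math.sqrt(arg_phi))
    elif form == "literal":
        gamma = 2.0 * math.asin(arg_gamma)
        phi = 2.0 * math.asin(arg_phi)
    else:
        raise ValueError(f"unknown tw form {form!r}")
    mu = 2.0 * math.log(math.tan((phi + gamma) / 2.0))
    sigma3 = 16.0 / denom**2 / (math.sin(phi + gamma) ** 2 * math.sin(phi) * math.sin(gamma))
    return TWCentering(
        mu=mu,
        sigma=sigma3 ** (1.0 / 3.0),
        phi_angle=phi,
        gamma_angle=gamma,
        dim=dim,
        df_numerator=df_num,
        df_denominator=df_den,
    )


def standardized_logit(phi: float, centering: TWCentering, clamp: bool = True) -> float:
    """``(logit(phi) - mu) / sigma`` for a greatest root ``phi`` in (0, 1)."""
    if not CLAMP_EPS < phi < 1.0 - CLAMP_EPS:
        if not clamp:
            raise ValueError(f"greatest root {phi} at the boundary of (0, 1)")
        logger.debug("clamping greatest root %s into (0, 1)", phi)
        phi = min(max(phi, CLAMP_EPS), 1.0 - CLAMP_EPS)
    return (math.log(phi / (1.0 - phi)) - centering.mu) / centering.sigma


# ---------------------------------------------------------------------------
# Change process
# ---------------------------------------------------------------------------


def admissible_range(d: int, T: int, t_min: int | None = None) -> np.ndarray:
    """Admissible split indices ``t_min .. T - t_min`` (inclusive, 1-based)."""
    if t_min is None:
        t_min = max(d + 2, DEFAULT_T_MIN_FLOOR)
    if t_min < d + 2:
        raise ValueError(f"t_min={t_min} below floor d+2={d + 2}")
    if T - t_min < t_min:
        raise ValueError(f"series of length T={T} leaves no admissible splits at t_min={t_min}")
    return np.arange(t_min, T - t_min + 1)


def _argmax_smallest(t_values: np.ndarray, g2: np.ndarray) -> int:
    """Index of the maximum of ``g2``; ties resolved to the smallest split."""
    return int(t_values[int(np.argmax(g2))])


def _tw_mu_sigma_vec(d: int, m: np.ndarray, n: np.ndarray, form: TWForm):
    """Vectorized (mu, sigma) over arrays of numerator/denominator dfs."""
    denom = m + n - 1.0
    arg_g = (np.minimum(d, m) - 0.5) / denom
    arg_p = (np.maximum(d, m) - 0.5) / denom
    if form == "squared":
        gamma = 2.0 * np.arcsin(np.sqrt(arg_g))
        phi = 2.0 * np.arcsin(np.sqrt(arg_p))
    elif form == "literal":
        if np.any(arg_p > 1.0):
            raise ValueError("arcsine argument exceeds 1 under the literal form")
        gamma = 2.0 * np.arcsin(arg_g)
        phi = 2.0 * np.arcsin(arg_p)
    else:
        raise ValueError(f"unknown tw form {form!r}")
    mu = 2.0 * np.log(np.tan((phi + gamma) / 2.0))
    sigma3 = 16.0 / denom**2 / (np.sin(phi + gamma) ** 2 * np.sin(phi) * np.sin(gamma))
    return mu, np.cbrt(sigma3)


def _pencil_extremes(a_stack: np.ndarray, b_stack: np.ndarray, t_values: np.ndarray):
    """Smallest and largest eigenvalues of the pencils ``(A+B)^{-1} A``.

    Batched Cholesky whitening of the pooled scatter; falls back to per-split
    generalized solves when some pooled matrix is not positive definite.
    """
    pooled = a_stack + b_stack
    try:
        chol = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        lo = np.full(len(t_values), np.nan)
        hi = np.full(len(t_values), np.nan)
        for i in range(len(t_values)):
            try:
                w = scipy.linalg.eigh(a_stack[i], pooled[i], eigvals_only=True)
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
                continue
            lo[i], hi[i] = w[0], w[-1]
        if np.all(np.isnan(lo)):
            raise SingularScatterError(
                int(t_values[0]), "pooled scatter singular at every admissible split"
            )
        return lo, hi
    x = np.linalg.solve(chol, a_stack)
    m = np.linalg.solve(chol, np.transpose(x, (0, 2, 1)))
    m = 0.5 * (m + np.transpose(m, (0, 2, 1)))
    w = np.linalg.eigvalsh(m)
    return w[:, 0], w[:, -1]


def change_process(
    y: TimeSeriesMatrix,
    t_min: int | None = None,
    tw_form: TWForm = "squared",
    df_correction: DFCorrection = "plain",
    clamp: bool = True,
) -> ChangeProcess:
    """Compute ``G_t`` over the admissible range, ``Lambda_T`` and ``tau_hat``.

    For each split, ``G_t`` is the TW-standardized logit of the largest
    eigenvalue of the A-pencil minus the TW-standardized logit of the largest
    eigenvalue of the B-pencil (obtained as ``1 - lambda_min`` of the
    A-pencil); the A-term uses numerator degrees of freedom ``t``, the B-term
    ``T - t`` (``df_correction='mean_corrected'`` subtracts one from each for
    the estimated segment means).
    """
    v = y.values
    d, T = y.d, y.T
    ts = admissible_range(d, T, t_min)

    # incremental (cumulative-sum) scatter construction over all splits
    cum_s = np.cumsum(v, axis=1)
    cum_o = np.cumsum(np.einsum("it,jt->tij", v, v), axis=0)
    s_l = cum_s[:, ts - 1].T
    a_stack = cum_o[ts - 1] - np.einsum("ti,tj->tij", s_l, s_l) / ts[:, None, None]
    s_r = cum_s[:, -1][None, :] - s_l
    b_stack = (cum_o[-1] - cum_o[ts - 1]) - np.einsum("ti,tj->tij", s_r, s_r) / (T - ts)[
        :, None, None
    ]

    lo, hi = _pencil_extremes(a_stack, b_stack, ts)
    phi_a = hi
    phi_b = 1.0 - lo

    n_clamped = int(
        np.sum(~np.isnan(phi_a) & ((phi_a <= CLAMP_EPS) | (phi_a >= 1 - CLAMP_EPS)))
        + np.sum(~np.isnan(phi_b) & ((phi_b <= CLAMP_EPS) | (phi_b >= 1 - CLAMP_EPS)))
    )
    if n_clamped and not clamp:
        raise ValueError("greatest root at the boundary of (0, 1) and clamping disabled")
    if n_clamped:
        logger.warning("clamped %d greatest roots into (0, 1)", n_clamped)
    phi_a = np.clip(phi_a, CLAMP_EPS, 1.0 - CLAMP_EPS)
    phi_b = np.clip(phi_b, CLAMP_EPS, 1.0 - CLAMP_EPS)

    corr = 1.0 if df_correction == "mean_corrected" else 0.0
    if df_correction not in ("plain", "mean_corrected"):
        raise ValueError(f"unknown df correction {df_correction!r}")
    m_a = ts.astype(float) - corr
    n_a = (T - ts).astype(float) - corr
    mu_a, sig_a = _tw_mu_sigma_vec(d, m_a, n_a, tw_form)
    mu_b, sig_b = _tw_mu_sigma_vec(d, n_a, m_a, tw_form)

    g = (np.log(phi_a / (1 - phi_a)) - mu_a) / sig_a - (np.log(phi_b / (1 - phi_b)) - mu_b) / sig_b
    g = np.where(np.isnan(g), -np.inf, g)  # skipped singular splits
    g2 = g**2
    tau_hat = _argmax_smallest(ts, g2)
    lam = float(np.max(g2))
    return ChangeProcess(
        t_values=ts,
        g=g,
        lambda_T=lam,
        tau_hat=tau_hat,
        theta_hat=tau_hat / T,
        n_clamped=n_clamped,
    )


def uncorrected_change_process(y: TimeSeriesMatrix, t_min: int | None = None) -> np.ndarray:
    """Diagnostic: raw eigenvalue difference ``phi_A - phi_B`` per split,
    without Tracy-Widom standardization."""
    v = y.values
    d, T = y.d, y.T
    ts = admissible_range(d, T, t_min)
    out = np.empty(len(ts))
    for i, pair in enumerate(iter_scatter_pairs(y, ts)):
        pooled = pair.a + pair.b
        w = scipy.linalg.eigh(pair.a, pooled, eigvals_only=True)
        out[i] = w[-1] - (1.0 - w[0])
    return out


# ---------------------------------------------------------------------------
# Detection and segmentation
# ---------------------------------------------------------------------------


def detect_change_point(
    y: TimeSeriesMatrix,
    t_min: int | None = None,
    tw_form: TWForm = "squared",
    df_correction: DFCorrection = "plain",
    permutation: "PermutationConfig | None" = None,
    keep_process: bool = False,
) -> DetectionResult:
    """Estimate the change-point; optionally attach block-permutation inference.

    When a :class:`~rmtcpt.permutation.PermutationConfig` is supplied, the
    threshold, p-value and reject decision at its ``alpha`` are computed from
    block-permuted copies of the series.
    """
    proc = change_process(y, t_min=t_min, tw_form=tw_form, df_correction=df_correction)
    threshold = p_value = rejected = None
    if permutation is not None:
        from .permutation import permutation_distribution, permutation_pvalue

        def statistic(z: TimeSeriesMatrix) -> float:
            return change_process(
                z, t_min=t_min, tw_form=tw_form, df_correction=df_correction
            ).lambda_T

        dist = permutation_distribution(y, statistic, permutation)
        k = math.ceil((1.0 - permutation.alpha) * (permutation.n_perm + 1))
        k = min(k, permutation.n_perm)
        threshold = float(np.sort(dist)[k - 1])
        p_value = permutation_pvalue(proc.lambda_T, dist)
        rejected = bool(proc.lambda_T > threshold)
    return DetectionResult(
        tau_hat=proc.tau_hat,
        theta_hat=proc.theta_hat,
        lambda_T=proc.lambda_T,
        threshold=threshold,
        p_value=p_value,
        rejected=rejected,
        process=proc if keep_process else None,
    )


def binary_segmentation(
    y: TimeSeriesMatrix,
    permutation: "PermutationConfig",
    t_min: int | None = None,
    tw_form: TWForm = "squared",
    df_correction: DFCorrection = "plain",
    _rng: np.random.Generator | None = None,
) -> list[int]:
    """Multiple change-points by recursive application of the single test.

    Each segment is tested with fresh block permutations; recursion stops when
    the test fails to reject or the segment is shorter than ``2 * t_min``.
    Returns sorted global 1-based change-point indices.  No multiplicity
    correction is applied across the recursion.
    """
    from .permutation import PermutationConfig

    d = y.d
    eff_t_min = t_min if t_min is not None else max(d + 2, DEFAULT_T_MIN_FLOOR)
    rng = _rng if _rng is not None else np.random.default_rng(permutation.seed)

    found: list[int] = []

    def recurse(values: np.ndarray, offset: int) -> None:
        T_seg = values.shape[1]
        if T_seg < 2 * eff_t_min or T_seg <= 2 * d:
            return
        seg = TimeSeriesMatrix(values)
        cfg = PermutationConfig(
            block_size=permutation.block_size,
            n_perm=permutation.n_perm,
            alpha=permutation.alpha,
            seed=int(rng.integers(2**31)),
        )
        res = detect_change_point(
            seg, t_min=eff_t_min, tw_form=tw_form, df_correction=df_correction, permutation=cfg
        )
        if not res.rejected:
            return
        found.append(offset + res.tau_hat)
        recurse(values[:, : res.tau_hat], offset)
        recurse(values[:, res.tau_hat :], offset + res.tau_hat)

    recurse(y.values, 0)
    return sorted(found)
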