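"""Vech-CUSUM covariance break detection (Aue-style comparator).

The half-vectorized outer products ``vech[y_j y_j']`` summarize the
instantaneous second-moment structure; their CUSUM bridge

    S_t = (1/sqrt(T)) ( sum_{j<=t} vech[y_j y_j'] - (t/T) sum_{j<=T} vech[y_j y_j'] )

is studentized with the sample covariance of the vech sequence and maximized
over the admissible split range.  Serves as the reference comparator for the
greatest-root detector; inference uses the same block-permutation machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detector import (
    DetectionResult,
    TimeSeriesMatrix,
    _argmax_smallest,
    admissible_range,
)

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8


def vech(m: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """Half-vectorization: stack the lower triangle (including the diagonal)
    of a symmetric matrix in column-major lower-triangular order."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if np.max(np.abs(m - m.T), initial=0.0) > tol:
        raise ValueError("matrix is asymmetric beyond tolerance")
    rows, cols = _vech_indices(m.shape[0])
    return m[rows, cols]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the symmetric matrix."""
    v = np.asarray(v, dtype=float)
    d = (math.isqrt(8 * v.size + 1) - 1) // 2
    if d * (d + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number")
    out = np.zeros((d, d))
    rows, cols = _vech_indices(d)
    out[rows, cols] = v
    out[cols, rows] = v
    return out


def _vech_indices(d: int):
    # column-major over the lower triangle: (0,0),(1,0)..(d-1,0),(1,1),..
    cols, rows = np.triu_indices(d)  # upper triangle row-major == lower col-major transposed
    return rows, cols


@dataclass(frozen=True)
class AueProcess:
    """The vech-CUSUM process and its studentized quadratic forms.

    ``s[j]`` is the bridge vector at time ``j + 1`` for every ``t = 1..T``
    (the bridge telescopes to the zero vector at ``t = T``); ``q`` holds the
    quadratic forms ``S' Sigma^{-1} S`` aligned to the admissible
    ``t_values``; ``lambda_A = max q``; ``tau_hat_A`` the smallest maximizing
    split.
    """

    t_values: np.ndarray
    s: np.ndarray = field(repr=False)
    sigma_hat: np.ndarray = field(repr=False)
    q: np.ndarray
    lambda_A: float
    tau_hat_A: int


def aue_process(
    y: TimeSeriesMatrix,
    t_min: int | None = None,
    allow_pinv: bool = True,
    rcond: float = 1e-10,
) -> AueProcess:
    """Compute the vech-CUSUM process over the shared admissible split range.

    ``Sigma_hat`` is the plain sample covariance of the sequence
    ``vech[y_j y_j']`` (no long-run correction); when it is rank deficient —
    unavoidable once ``d(d+1)/2 >= T`` — a Moore-Penrose pseudo-inverse is
    used unless ``allow_pinv`` is disabled.
    """
    v = y.values
    d, T = y.d, y.T
    ts = admissible_range(d, T, t_min)
    p = d * (d + 1) // 2
    if T <= p:
        msg = f"vech dimension {p} >= T={T}: moment covariance cannot be full rank"
        if not allow_pinv:
            raise np.linalg.LinAlgError(msg)
        logger.warning("%s; using pseudo-inverse", msg)

    rows, cols = _vech_indices(d)
    vseq = (v[rows] * v[cols]).T  # T x p, vech of outer products
    sigma_hat = np.cov(vseq.T, bias=False)
    cum = np.cumsum(vseq, axis=0)
    t_full = np.arange(1, T + 1)
    s_full = (cum - np.outer(t_full / T, cum[-1])) / np.sqrt(T)
    s = s_full[ts - 1]

    if allow_pinv:
        sigma_inv = np.linalg.pinv(sigma_hat, rcond=rcond)
    else:
        try:
            sigma_inv = np.linalg.inv(sigma_hat)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular moment covariance and pseudo-inverse disabled: {e}"
            ) from e
    q = np.einsum("ti,ij,tj->t", s, sigma_inv, s)
    tau_hat = _argmax_smallest(ts, q)
    return AueProcess(
        t_values=ts,
        s=s_full,
        sigma_hat=sigma_hat,
        q=q,
        lambda_A=float(np.max(q)),
        tau_hat_A=tau_hat,
    )


def aue_detect(
    y: TimeSeriesMatrix,
    t_min: int | None = None,
    allow_pinv: bool = True,
    demean: bool = False,
    permutation: "PermutationConfig | None" = None,
) -> DetectionResult:
    """Change-point detection with the vech-CUSUM statistic.

    ``demean`` subtracts the global mean of each variable first; by default
    raw outer products are used.  Permutation inference mirrors
    :func:`rmtcpt.detector.detect_change_point`.
    """
    if demean:
        y = TimeSeriesMatrix(y.values - y.values.mean(axis=1, keepdims=True))
    proc = aue_process(y, t_min=t_min, allow_pinv=allow_pinv)
    threshold = p_value = rejected = None
    if permutation is not None:
        from .permutation import permutation_distribution, permutation_pvalue

        def statistic(z: TimeSeriesMatrix) -> float:
            return aue_process(z, t_min=t_min, allow_pinv=allow_pinv).lambda_A

        dist = permutation_distribution(y, statistic, permutation)
        k = math.ceil((1.0 - permutation.alpha) * (permutation.n_perm + 1))
        k = min(k, permutation.n_perm)
        threshold = float(np.sort(dist)[k - 1])
        p_value = permutation_pvalue(proc.lambda_A, dist)
        rejected = bool(proc.lambda_A > threshold)
    return DetectionResult(
        tau_hat=proc.tau_hat_A,
        theta_hat=proc.tau_hat_A / y.T,
        lambda_T=proc.lambda_A,
        threshold=threshold,
        p_value=p_value,
        rejected=rejected,
    )
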