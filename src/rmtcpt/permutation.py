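"""Block-permutation null distributions for change statistics.

Time-series observations are not exchangeable, so plain permutation tests are
invalid in the presence of serial dependence.  Block permutation shuffles
contiguous blocks of time points instead: short-range dependence is preserved
within blocks while any global change structure is destroyed, yielding an
approximate null distribution for a change statistic evaluated on the permuted
series.  Critical values are empirical upper quantiles of that distribution,
computed independently per series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .detector import TimeSeriesMatrix

Statistic = Callable[[TimeSeriesMatrix], float]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for a block-permutation test.

    ``block_size`` is the number of consecutive time points per block (the
    final block may be shorter); ``n_perm`` the number of permuted copies;
    ``alpha`` the test level; ``seed`` feeds the permutation generator.
    """

    block_size: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def block_permute(y: TimeSeriesMatrix, block_size: int, rng: np.random.Generator) -> TimeSeriesMatrix:
    """Randomly reorder contiguous time blocks of length ``block_size``.

    The time axis is partitioned into ``ceil(T / block_size)`` contiguous
    blocks (the last possibly shorter); block order is drawn uniformly at
    random while the within-block order is preserved, so the output holds the
    same multiset of columns.
    """
    T = y.T
    if not 1 <= block_size <= T:
        raise ValueError(f"block size {block_size} outside [1, {T}]")
    n_blocks = math.ceil(T / block_size)
    order = rng.permutation(n_blocks)
    cols = np.concatenate(
        [np.arange(b * block_size, min((b + 1) * block_size, T)) for b in order]
    )
    return TimeSeriesMatrix(y.values[:, cols])


def permutation_distribution(
    y: TimeSeriesMatrix, statistic: Statistic, config: PermutationConfig
) -> np.ndarray:
    """Statistic values over ``n_perm`` block-permuted copies of ``y``."""
    rng = np.random.default_rng(config.seed)
    out = np.empty(config.n_perm)
    for i in range(config.n_perm):
        z = block_permute(y, config.block_size, rng)
        try:
            out[i] = statistic(z)
        except Exception as e:
            raise RuntimeError(f"statistic failed on permutation {i}: {e}") from e
    return out


def permutation_threshold(
    y: TimeSeriesMatrix, statistic: Statistic, config: PermutationConfig
) -> float:
    """Empirical ``(1 - alpha)`` critical value of ``statistic`` under block
    permutation.

    Uses the order statistic at rank ``ceil((1 - alpha) * (n_perm + 1))``
    (capped at ``n_perm``), so that exceeding the threshold corresponds to an
    add-one permutation p-value below ``alpha``.
    """
    dist = permutation_distribution(y, statistic, config)
    k = math.ceil((1.0 - config.alpha) * (config.n_perm + 1))
    k = min(k, config.n_perm)
    return float(np.sort(dist)[k - 1])


def permutation_pvalue(observed: float, permuted: Sequence[float]) -> float:
    """Add-one permutation p-value ``(1 + #{permuted >= observed}) / (1 + n)``."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("empty permutation distribution")
    return float((1 + np.sum(permuted >= observed)) / (1 + permuted.size))
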