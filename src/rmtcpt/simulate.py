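"""MVAR(p) scenario generation with a covariance/coefficient change-point.

The simulation scenarios emulate multi-subject ROI time series: a stationary
vector autoregression whose innovation covariance (and, in the standard cases,
autoregressive coefficients) switches at the change-point ``tau``.  Four named
cases are provided:

* ``i``   — MVAR(1), innovation covariance increasing after ``tau``;
* ``ii``  — MVAR(1), innovation covariance decreasing after ``tau``;
* ``iii`` — MVAR(2), innovation covariance increasing;
* ``iv``  — MVAR(2), innovation covariance decreasing.

Innovation covariances are of the form ``a I + b (J - I)`` (``J`` the all-ones
matrix), i.e. constant diagonal ``a`` and constant off-diagonal ``b``.  The
coefficient matrices carry a single loading in their first column whose exact
shape is selected by ``psi_form`` (see :func:`coefficient_matrix`); after the
change-point ``0.1 I`` is added to every coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .detector import TimeSeriesMatrix

PsiForm = Literal["scalar", "ones-column", "ones-row"]

CASES = ("i", "ii", "iii", "iv")

#: Burn-in samples generated under the pre-change regime and discarded.
DEFAULT_BURN_IN = 200


def coefficient_matrix(d: int, loading: float, psi_form: PsiForm = "scalar") -> np.ndarray:
    """Base MVAR coefficient matrix with loading concentrated up front.

    ``scalar`` places ``loading`` at entry (1, 1) only (first column is the
    vector ``(loading, 0, ..., 0)``); ``ones-column`` fills the whole first
    column with ``loading``; ``ones-row`` fills the first row.
    """
    m = np.zeros((d, d))
    if psi_form == "scalar":
        m[0, 0] = loading
    elif psi_form == "ones-column":
        m[:, 0] = loading
    elif psi_form == "ones-row":
        m[0, :] = loading
    else:
        raise ValueError(f"unknown psi form {psi_form!r}")
    return m


def _uniform_cov(d: int, diag: float, off: float) -> np.ndarray:
    """Covariance ``diag * I + off * (J - I)``."""
    return off * np.ones((d, d)) + (diag - off) * np.eye(d)


def companion_spectral_radius(coeffs: Sequence[np.ndarray]) -> float:
    """Spectral radius of the companion matrix of an MVAR(p) coefficient set."""
    coeffs = [np.asarray(c, dtype=float) for c in coeffs]
    d = coeffs[0].shape[0]
    p = len(coeffs)
    comp = np.zeros((d * p, d * p))
    comp[:d] = np.hstack(coeffs)
    if p > 1:
        comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass(frozen=True)
class MVARScenario:
    """One simulation scenario: MVAR(p) with a single change-point.

    ``coeff_pre``/``coeff_post`` hold the ``p`` coefficient matrices before
    and after ``tau``; ``sigma_pre``/``sigma_post`` the innovation
    covariances.  Both regimes must be stationary (companion spectral radius
    below one) and the covariances symmetric positive definite.
    """

    case_label: str
    order: int
    coeff_pre: tuple[np.ndarray, ...]
    coeff_post: tuple[np.ndarray, ...]
    sigma_pre: np.ndarray
    sigma_post: np.ndarray
    d: int
    T: int
    tau: int
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self):
        object.__setattr__(self, "coeff_pre", tuple(np.asarray(c, float) for c in self.coeff_pre))
        object.__setattr__(self, "coeff_post", tuple(np.asarray(c, float) for c in self.coeff_post))
        object.__setattr__(self, "sigma_pre", np.asarray(self.sigma_pre, float))
        object.__setattr__(self, "sigma_post", np.asarray(self.sigma_post, float))
        if len(self.coeff_pre) != self.order or len(self.coeff_post) != self.order:
            raise ValueError("coefficient list length must equal the model order")
        if not 1 <= self.tau < self.T:
            raise ValueError(f"tau={self.tau} outside [1, T-1]")
        for name, sig in (("sigma_pre", self.sigma_pre), ("sigma_post", self.sigma_post)):
            if sig.shape != (self.d, self.d):
                raise ValueError(f"{name} has shape {sig.shape}, expected ({self.d}, {self.d})")
            if np.max(np.abs(sig - sig.T)) > 1e-10:
                raise ValueError(f"{name} is not symmetric")
            if np.min(np.linalg.eigvalsh(sig)) <= 0:
                raise ValueError(f"{name} is not positive definite")
        for name, coeffs in (("pre", self.coeff_pre), ("post", self.coeff_post)):
            rho = companion_spectral_radius(coeffs)
            if rho >= 1.0:
                raise ValueError(
                    f"nonstationary {name}-change regime: companion spectral radius {rho:.4f} >= 1"
                )

    @property
    def theta(self) -> float:
        return self.tau / self.T


def build_scenario(
    case: str,
    d: int = 5,
    T: int = 200,
    theta: float = 0.5,
    psi_form: PsiForm = "scalar",
    switch_coefficients: bool = True,
    burn_in: int = DEFAULT_BURN_IN,
) -> MVARScenario:
    """Construct one of the named scenarios at dimension ``d``, length ``T``
    and change fraction ``theta`` (``tau = round(theta * T)``).

    ``switch_coefficients=False`` freezes the coefficients at the pre-change
    matrices so that only the innovation covariance changes.
    """
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    tau = round(theta * T)

    sigma_up_pre = _uniform_cov(d, 0.5, 0.0)          # (0.5) I
    sigma_up_post = _uniform_cov(d, 1.0, 0.1)         # (1.0) I + (0.1) J - (0.1) I
    sigma2_up_pre = _uniform_cov(d, 0.5, 0.01)        # (0.5) I + (0.01) J - (0.01) I

    if case in ("i", "ii"):
        order = 1
        pre = (coefficient_matrix(d, 0.2, psi_form),)
        post = tuple(c + 0.1 * np.eye(d) for c in pre)
        if case == "i":
            s1, s2 = sigma_up_pre, sigma_up_post
        else:
            s1, s2 = sigma_up_post, sigma_up_pre
    else:
        order = 2
        pre = (coefficient_matrix(d, 0.2, psi_form), coefficient_matrix(d, 0.1, psi_form))
        post = tuple(c + 0.1 * np.eye(d) for c in pre)
        if case == "iii":
            s1, s2 = sigma2_up_pre, sigma_up_post
        else:
            s1, s2 = sigma_up_post, sigma2_up_pre
    if not switch_coefficients:
        post = pre
    return MVARScenario(
        case_label=case,
        order=order,
        coeff_pre=pre,
        coeff_post=post,
        sigma_pre=s1,
        sigma_post=s2,
        d=d,
        T=T,
        tau=tau,
        burn_in=burn_in,
    )


def simulate_mvar(
    scenario: MVARScenario, seed: int | np.random.Generator | None = None
) -> TimeSeriesMatrix:
    """Simulate one ``d x T`` series from the scenario.

    Gaussian innovations with covariance ``sigma_pre`` up to ``tau`` and
    ``sigma_post`` after; coefficients switch at the same point.  ``burn_in``
    initial samples are generated under the pre-change regime from zero
    initial values and discarded.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d, T, tau, burn = scenario.d, scenario.T, scenario.tau, scenario.burn_in
    p = scenario.order
    n = burn + T
    chol_pre = np.linalg.cholesky(scenario.sigma_pre)
    chol_post = np.linalg.cholesky(scenario.sigma_post)
    z = rng.standard_normal((d, n))
    n_pre = burn + tau  # output positions 1..tau (1-based) are pre-change
    eps = np.empty((d, n))
    eps[:, :n_pre] = chol_pre @ z[:, :n_pre]
    eps[:, n_pre:] = chol_post @ z[:, n_pre:]
    y = np.zeros((d, n))
    for u in range(n):
        coeffs = scenario.coeff_pre if u < n_pre else scenario.coeff_post
        acc = eps[:, u]
        for k in range(1, p + 1):
            if u - k >= 0:
                acc = acc + coeffs[k - 1] @ y[:, u - k]
        y[:, u] = acc
    return TimeSeriesMatrix(y[:, burn:])


def simulate_subject_panel(
    n_subjects: int,
    scenario: MVARScenario | Sequence[MVARScenario],
    seed: int | None = None,
) -> list[TimeSeriesMatrix]:
    """Independent per-subject series from a shared or per-subject scenario.

    Subject seeds are derived from the master ``seed`` by seed-sequence
    spawning, so the panel is reproducible and subjects are independent.  A
    sequence of scenarios (e.g. with subject-varying ``tau``) is matched by
    position.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    if isinstance(scenario, MVARScenario):
        scenarios = [scenario] * n_subjects
    else:
        scenarios = list(scenario)
        if len(scenarios) != n_subjects:
            raise ValueError(
                f"got {len(scenarios)} scenarios for {n_subjects} subjects"
            )
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        simulate_mvar(sc, np.random.default_rng(child))
        for sc, child in zip(scenarios, children)
    ]
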