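"""Kinship construction and one-shot (P3D-style) variance-component estimation.

The null model per study is ``y ~ N(0, sigma_u^2 * K + sigma_v^2 * I)``:
a polygenic/relatedness component with covariance proportional to the
kinship matrix plus an iid component absorbing data-collection noise.
Both scalars are estimated once by maximum likelihood via a single
eigendecomposition of K and a 1-D search over the variance ratio, then
held fixed for all downstream coupled fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from cmm.plink_io import GenotypeStudy


@dataclass
class KinshipMatrix:
    """Sample-by-sample genetic similarity ``K = X X^T / p`` (standardized X)."""

    K: np.ndarray
    scale_note: str = "XX^T/p"

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.K))


@dataclass
class VarianceComponents:
    """The four confounder variance scalars, one (u, v) pair per study."""

    sigma_u1_sq: float
    sigma_v1_sq: float
    sigma_u2_sq: float
    sigma_v2_sq: float
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("sigma_u1_sq", "sigma_v1_sq", "sigma_u2_sq", "sigma_v2_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def compute_kinship(X: np.ndarray) -> KinshipMatrix:
    """``K = X X^T / p`` for a standardized n x p dosage matrix.

    The 1/p scaling keeps ``trace(K) ~ n`` regardless of panel size; it is
    recorded in ``scale_note`` so trace terms stay consistent downstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    p = X.shape[1]
    K = (X @ X.T) / p
    K = 0.5 * (K + K.T)  # kill asymmetric round-off
    return KinshipMatrix(K=K)


def _profile_loglik(log_delta: float, eigvals: np.ndarray, y_rot_sq: np.ndarray) -> float:
    """Profile log-likelihood of delta = sigma_v^2 / sigma_u^2 (up to const)."""
    delta = np.exp(log_delta)
    d = eigvals + delta
    n = eigvals.shape[0]
    sigma_u_sq = np.sum(y_rot_sq / d) / n
    if sigma_u_sq <= 0:
        return -np.inf
    return -0.5 * (n * np.log(sigma_u_sq) + np.sum(np.log(d)))


DELTA_GRID = np.logspace(-5, 5, 100)


def estimate_components(
    study: GenotypeStudy | None,
    K: KinshipMatrix,
    y: np.ndarray | None = None,
    delta_grid: np.ndarray = DELTA_GRID,
) -> tuple[float, float]:
    """ML estimates of ``(sigma_u^2, sigma_v^2)`` for ``y ~ N(0, su*K + sv*I)``.

    ``y`` defaults to the study phenotype; it is centered internally.  The
    variance ratio ``delta = sv/su`` is scanned on a log grid and refined by
    bounded scalar minimization; one eigendecomposition of K suffices.

    A near-identity K (eigenvalue spread below 1% of the mean) makes the two
    scalars unidentifiable; ``(0, var(y))`` is returned with a warning.
    """
    if y is None:
        if study is None:
            raise ValueError("either a study or an explicit y is required")
        y = study.y
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    y = y - y.mean()
    n = y.shape[0]
    if K.n_samples != n:
        raise ValueError(f"kinship is {K.n_samples}x{K.n_samples} but y has length {n}")
    var_y = float(y @ y) / n
    if var_y == 0.0:
        raise ValueError("phenotype has zero variance")

    eigvals, eigvecs = np.linalg.eigh(K.K)
    eigvals = np.maximum(eigvals, 0.0)

    spread = eigvals.std() / max(eigvals.mean(), 1e-30)
    if spread < 0.01:
        warnings.warn("kinship is numerically proportional to identity; sigma_u^2 and sigma_v^2 are not separately identifiable")
        return 0.0, var_y

    y_rot_sq = (eigvecs.T @ y) ** 2

    log_grid = np.log(delta_grid)
    ll = np.array([_profile_loglik(ld, eigvals, y_rot_sq) for ld in log_grid])
    best = int(np.argmax(ll))

    lo = log_grid[max(best - 1, 0)]
    hi = log_grid[min(best + 1, len(log_grid) - 1)]
    res = minimize_scalar(
        lambda ld: -_profile_loglik(ld, eigvals, y_rot_sq),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if -res.fun >= ll[best] else log_grid[best]

    if best in (0, len(log_grid) - 1):
        warnings.warn(f"variance-ratio optimum at grid boundary (delta={np.exp(log_delta):.3g})")

    delta = np.exp(log_delta)
    sigma_u_sq = float(np.sum(y_rot_sq / (eigvals + delta)) / n)
    sigma_v_sq = float(delta * sigma_u_sq)
    return sigma_u_sq, sigma_v_sq


def estimate_all_components(study1: GenotypeStudy, K1: KinshipMatrix, study2: GenotypeStudy, K2: KinshipMatrix) -> VarianceComponents:
    """Run :func:`estimate_components` on both studies (P3D: done once)."""
    collected: list = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        su1, sv1 = estimate_components(study1, K1)
        su2, sv2 = estimate_components(study2, K2)
        collected = [str(w.message) for w in caught]
    return VarianceComponents(sigma_u1_sq=su1, sigma_v1_sq=sv1, sigma_u2_sq=su2, sigma_v2_sq=sv2, warnings=collected)
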