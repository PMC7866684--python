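"""Baseline association methods and the common-SNP ROC evaluation harness.

Univariate baselines score each SNP with a p-value (plain Wald regression,
its mixed-model whitened variant, and the merged-cohort pseudo-phenotype
test); multivariate baselines trace a coefficient path (consensus joint
lasso, per-study l1-logistic regression).  A SNP counts as jointly called
at a threshold only if it is called in BOTH studies; ROC curves and AUC for
recovering the truly shared causal SNPs are computed against that rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cmm.cmm_core import CmmProblem, SolverConfig, solve_betas_admm
from cmm.plink_io import GenotypeStudy, PairedStudy
from cmm.variance_components import KinshipMatrix


@dataclass
class MethodOutput:
    """Per-SNP scores for both phenotypes plus the comparison convention."""

    scores1: np.ndarray
    scores2: np.ndarray
    kind: str  # "pvalue" (smaller is stronger) or "coefficient" (larger)
    label: str = ""

    def __post_init__(self):
        self.scores1 = np.asarray(self.scores1, float)
        self.scores2 = np.asarray(self.scores2, float)
        if self.scores1.shape != self.scores2.shape:
            raise ValueError("score vectors must have equal length")
        if not (np.all(np.isfinite(self.scores1)) and np.all(np.isfinite(self.scores2))):
            raise ValueError("scores must be finite")
        if self.kind not in ("pvalue", "coefficient"):
            raise ValueError("kind must be 'pvalue' or 'coefficient'")


def wald_univariate(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided per-SNP Wald p-values from simple linear regression.

    Assumes centered y and column-standardized X; monomorphic (all-zero)
    columns get p = 1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float) - np.mean(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a Wald test")
    xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    mono = sxx == 0.0
    sxx_safe = np.where(mono, 1.0, sxx)
    bhat = (xc.T @ y) / sxx_safe
    # residual SS per SNP: ||y||^2 - bhat^2 * sxx
    rss = np.maximum(y @ y - bhat**2 * sxx, 0.0)
    df = n - 2
    se = np.sqrt(np.maximum(rss / df, 1e-300) / sxx_safe)
    tstat = bhat / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[mono] = 1.0
    return np.clip(pvals, 0.0, 1.0)


def lmm_univariate(X: np.ndarray, y: np.ndarray, K: KinshipMatrix, sigma_u_sq: float, sigma_v_sq: float) -> np.ndarray:
    """Mixed-model Wald p-values: whiten by V^{-1/2}, V = su*K + sv*I, then test.

    The whitening transform is computed once from the eigendecomposition of
    K (P3D-style: the variance scalars come from a prior null fit).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float) - np.mean(y)
    vals, vecs = np.linalg.eigh(K.K)
    w = sigma_u_sq * np.maximum(vals, 0.0) + sigma_v_sq
    if np.min(w) <= 0.0:
        raise ValueError("V = su*K + sv*I is not positive definite")
    half_inv = vecs * (1.0 / np.sqrt(w))
    Xt = half_inv.T @ X
    yt = half_inv.T @ y
    return wald_univariate(Xt, yt)


def bh_procedure(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: indices of rejected hypotheses."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    pvals = np.asarray(pvals, float)
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    if not below.any():
        return np.array([], dtype=int)
    k = int(np.max(np.nonzero(below)[0])) + 1
    return np.sort(order[:k])


def hypergeometric_overlap(p_total: int, k1: int, k2: int, m: int) -> float:
    """Upper-tail probability of >= m overlaps between two random draws.

    Two sets of sizes k1 and k2 drawn without replacement from p_total
    items; the overlap is hypergeometric with k1 draws from k2 successes.
    """
    if not (0 <= m <= min(k1, k2) and 0 <= k1 <= p_total and 0 <= k2 <= p_total):
        raise ValueError(f"invalid counts: p_total={p_total}, k1={k1}, k2={k2}, m={m}")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, p_total, k2, k1))


def cd_merge_test(study1: GenotypeStudy, study2: GenotypeStudy) -> np.ndarray:
    """Merged-cohort baseline: stack genotypes, pseudo-phenotype = own-study case.

    Requires binary phenotypes and a shared SNP panel; returns per-SNP Wald
    p-values on the stacked data (n1 + n2 samples).
    """
    if study1.snp_ids != study2.snp_ids:
        raise ValueError("studies must share the SNP panel")
    for s in (study1, study2):
        if not np.all(np.isin(s.y, (0.0, 1.0))):
            raise ValueError("cd_merge_test needs binary 0/1 phenotypes")
    X = np.vstack([study1.X, study2.X])
    y = np.concatenate([study1.y, study2.y])
    if np.all(y == y[0]):
        return np.ones(X.shape[1])
    return wald_univariate(X, y)


def joint_lasso(
    paired_or_problem: PairedStudy | CmmProblem,
    lam: float,
    rho: float = 1.0,
    config: SolverConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint lasso: unit-weight consensus ADMM driven to a common coefficient.

    Equivalent to the lasso on the stacked data with penalty 2*lam; the
    consensus variable is returned for both phenotypes, so
    ``beta1 == beta2`` exactly.  This is the coupled model with the
    confounder-aware covariance weighting stripped out.
    """
    base = config or SolverConfig()
    if isinstance(paired_or_problem, CmmProblem):
        problem = paired_or_problem
    else:
        p = paired_or_problem
        problem = CmmProblem(p.study1.X, p.study1.y, p.study2.X, p.study2.y, None, float(p.study1.n_samples), float(p.study2.n_samples))
    cfg = SolverConfig(
        lambda1=lam,
        lambda2=lam,
        rho=rho if rho > 0 else 1.0,
        admm_tol=1e-6,
        max_admm=max(base.max_admm, 2000),
        cd_tol=base.cd_tol,
        cd_max_sweeps=max(base.cd_max_sweeps, 100),
    )
    _, _, state = solve_betas_admm(problem, (1.0, 1.0), cfg, track_best=False)
    z = state["z"].copy()
    z[np.abs(z) < 1e-8] = 0.0
    return z, z.copy()


def l1_logistic_scores(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """|coefficients| of an l1-penalized logistic regression (LR baseline)."""
    from sklearn.linear_model import LogisticRegression

    model = LogisticRegression(penalty="l1", C=C, solver="liblinear", max_iter=200, tol=1e-5)
    model.fit(X, y)
    return np.abs(model.coef_.ravel())


def _roc_from_points(points: list, n_common: int, n_null: int) -> tuple[np.ndarray, np.ndarray, float]:
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([a for a, _ in pts])
    tpr = np.array([b for _, b in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_from_scores(output: MethodOutput, common_truth: np.ndarray, thresholds: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over a shared threshold applied to both studies' scores.

    A SNP is called when it passes the threshold in BOTH studies, i.e. the
    joint statistic is ``max(p1, p2)`` for p-values and ``min(|b1|, |b2|)``
    for coefficients; sweeping every observed value of that statistic gives
    the full curve.
    """
    common_truth = np.asarray(common_truth, int)
    if common_truth.size == 0:
        raise ValueError("truth.common is empty")
    p = output.scores1.size
    if output.kind == "pvalue":
        joint = np.maximum(output.scores1, output.scores2)
        call = lambda thr: joint <= thr
    else:
        joint = np.minimum(np.abs(output.scores1), np.abs(output.scores2))
        call = lambda thr: joint >= thr
    if thresholds is None:
        thresholds = np.unique(joint)
    is_common = np.zeros(p, dtype=bool)
    is_common[common_truth] = True
    n_common = int(is_common.sum())
    n_null = p - n_common

    points = []
    for thr in np.atleast_1d(thresholds):
        called = call(thr)
        tp = int(np.sum(called & is_common))
        fp = int(np.sum(called & ~is_common))
        points.append((fp / max(n_null, 1), tp / n_common))
    return _roc_from_points(points, n_common, n_null)


def roc_from_path(supports: list, common_truth: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC from a hyperparameter path of per-study support sets.

    ``supports`` is a list of ``(set1, set2)`` index collections, one per
    hyperparameter value; the joint call at each path point is their
    intersection.
    """
    common_truth = np.asarray(common_truth, int)
    if common_truth.size == 0:
        raise ValueError("truth.common is empty")
    is_common = np.zeros(p, dtype=bool)
    is_common[common_truth] = True
    n_common = int(is_common.sum())
    n_null = p - n_common
    points = []
    for s1, s2 in supports:
        called = np.array(sorted(set(s1) & set(s2)), dtype=int)
        tp = int(is_common[called].sum()) if called.size else 0
        fp = called.size - tp
        points.append((fp / max(n_null, 1), tp / n_common))
    return _roc_from_points(points, n_common, n_null)


def roc_for_common_snps(output_or_supports, truth_common: np.ndarray, p: int | None = None, thresholds: np.ndarray | None = None):
    """Dispatch to score-based or path-based ROC computation."""
    if isinstance(output_or_supports, MethodOutput):
        return roc_from_scores(output_or_supports, truth_common, thresholds)
    if p is None:
        raise ValueError("p is required for path-based ROC")
    return roc_from_path(output_or_supports, truth_common, p)


def hyperparameter_path(n_points: int = 200, low: float = 1e-5, high: float = 1e5) -> np.ndarray:
    """Log-spaced hyperparameter grid (200 points by default)."""
    return np.logspace(np.log10(low), np.log10(high), n_points)
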