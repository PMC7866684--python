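"""The coupled sparse mixed-model objective and its alternating ADMM solver.

Two studies observe one phenotype each.  Both coefficient vectors enter a
single likelihood through a 2x2 covariance summary whose entries mix the
observed phenotypes, the cross-study linear predictors and the confounder
variance components.  The solver alternates between (i) freezing that
summary and (ii) minimizing the resulting pair of weighted lasso problems,
coupled by an ADMM consensus penalty that realizes the
"coefficients of the two phenotypes stay close" constraint without an
explicit tolerance parameter.  The block iterates (not the consensus
average) are returned, so per-phenotype rankings remain distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from cmm._cd import cd_lasso
from cmm.plink_io import PairedStudy
from cmm.variance_components import KinshipMatrix, VarianceComponents

T_MIN_FACTOR = 1e-8


@dataclass
class CovarianceSummary:
    """Entries of the 2x2 phenotype covariance summary and its determinant.

    ``t`` is the determinant ``s11*s22 - s12**2`` floored at
    ``t_min = T_MIN_FACTOR * s11 * s22`` so that ``log t`` stays defined;
    ``clamped`` records whether the floor was hit.
    """

    s11: float
    s22: float
    s12: float
    t: float
    clamped: bool = False

    @property
    def s21(self) -> float:
        return self.s12

    @property
    def raw_det(self) -> float:
        return self.s11 * self.s22 - self.s12**2


@dataclass
class SolverConfig:
    """Penalties, ADMM controls and stopping rules for the coupled solver."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    rho: float = 1.0
    admm_tol: float = 1e-5
    outer_tol: float = 1e-5
    max_outer: int = 50
    max_admm: int = 200
    t_min_factor: float = T_MIN_FACTOR
    cd_tol: float = 1e-8
    # ADMM beta-updates are solved inexactly (few warm-started sweeps);
    # uncoupled rho=0 solves ignore this cap and run to convergence.
    cd_max_sweeps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.rho < 0:
            raise ValueError("penalty weights must be nonnegative")
        if min(self.admm_tol, self.outer_tol, self.cd_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.max_outer, self.max_admm, self.cd_max_sweeps) < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class CoupledEstimate:
    beta1: np.ndarray
    beta2: np.ndarray
    summary: CovarianceSummary
    objective_trace: list
    converged: bool
    n_outer: int
    n_admm_total: int
    events: list = field(default_factory=list)
    admm_state: dict | None = field(default=None, repr=False)  # warm-start handle

    @property
    def n_selected(self) -> tuple[int, int]:
        return int(np.sum(np.abs(self.beta1) > 0)), int(np.sum(np.abs(self.beta2) > 0))


class CmmProblem:
    """Preprocessed data shared across solves (Gram matrices, traces, vc).

    Building this once and reusing it across a regularization path avoids
    recomputing the p x p Gram matrices, which dominate set-up cost.
    """

    def __init__(self, X1, y1, X2, y2, vc: VarianceComponents, trK1: float, trK2: float):
        self.X1 = np.asarray(X1, float)
        self.X2 = np.asarray(X2, float)
        if self.X1.shape[1] != self.X2.shape[1]:
            raise ValueError("the two studies must share the SNP panel")
        self.y1 = np.asarray(y1, float) - np.mean(y1)
        self.y2 = np.asarray(y2, float) - np.mean(y2)
        if self.y1.shape[0] != self.X1.shape[0] or self.y2.shape[0] != self.X2.shape[0]:
            raise ValueError("phenotype/genotype sample counts disagree")
        self.vc = vc
        self.trK1 = float(trK1)
        self.trK2 = float(trK2)
        self.p = self.X1.shape[1]
        self.G1 = self.X1.T @ self.X1
        self.G2 = self.X2.T @ self.X2
        self.cy1 = self.X1.T @ self.y1
        self.cy2 = self.X2.T @ self.y2
        self.y1y1 = float(self.y1 @ self.y1)
        self.y2y2 = float(self.y2 @ self.y2)

    @classmethod
    def from_paired(cls, paired: PairedStudy, vc: VarianceComponents, K1: KinshipMatrix, K2: KinshipMatrix) -> "CmmProblem":
        return cls(
            paired.study1.X,
            paired.study1.y,
            paired.study2.X,
            paired.study2.y,
            vc,
            K1.trace,
            K2.trace,
        )


def covariance_summary(
    beta1: np.ndarray,
    beta2: np.ndarray,
    problem: CmmProblem,
    t_min_factor: float = T_MIN_FACTOR,
) -> CovarianceSummary:
    """Evaluate the covariance summary entries at the given coefficients.

    s11 = y1'y1 + b1'X2'X2 b1 + 2 tr(K1) su1 + sv1 + sv2
    s22 = y2'y2 + b2'X1'X1 b2 + 2 tr(K2) su2 + sv1 + sv2
    s12 = y1'X1 b2 + b1'X2'y2 + tr(K1) su1 + tr(K2) su2 + sv1 + sv2
    t   = max(s11*s22 - s12^2, t_min)
    """
    beta1 = np.asarray(beta1, float)
    beta2 = np.asarray(beta2, float)
    if beta1.shape[0] != problem.p or beta2.shape[0] != problem.p:
        raise ValueError(f"coefficient length must be {problem.p}")
    vc = problem.vc
    sv = vc.sigma_v1_sq + vc.sigma_v2_sq
    tr1 = problem.trK1 * vc.sigma_u1_sq
    tr2 = problem.trK2 * vc.sigma_u2_sq

    s11 = float(problem.y1 @ problem.y1 + beta1 @ problem.G2 @ beta1 + 2.0 * tr1 + sv)
    s22 = float(problem.y2 @ problem.y2 + beta2 @ problem.G1 @ beta2 + 2.0 * tr2 + sv)
    s12 = float(problem.cy1 @ beta2 + beta1 @ problem.cy2 + tr1 + tr2 + sv)

    det = s11 * s22 - s12**2
    t_min = t_min_factor * s11 * s22
    clamped = det < t_min
    t = max(det, t_min)
    return CovarianceSummary(s11=s11, s22=s22, s12=s12, t=t, clamped=clamped)


def objective(
    beta1: np.ndarray,
    beta2: np.ndarray,
    t: float,
    problem: CmmProblem,
    config: SolverConfig,
    summary_fixed: CovarianceSummary,
) -> float:
    """Coupled negative log-likelihood with the summary weights held fixed.

    (s22/2t)||y1 - X1 b1||^2 + (s11/2t)||y2 - X2 b2||^2 + (1/2) log t
      + lam1 ||b1||_1 + lam2 ||b2||_1
    """
    if t <= 0:
        raise ValueError("t must be positive (clamp upstream)")
    r1 = problem.y1 - problem.X1 @ beta1
    r2 = problem.y2 - problem.X2 @ beta2
    return float(
        (summary_fixed.s22 / (2.0 * t)) * (r1 @ r1)
        + (summary_fixed.s11 / (2.0 * t)) * (r2 @ r2)
        + 0.5 * math.log(t)
        + config.lambda1 * np.abs(beta1).sum()
        + config.lambda2 * np.abs(beta2).sum()
    )


def _full_objective(beta1, beta2, problem, config) -> tuple[float, CovarianceSummary]:
    """Objective with the summary re-evaluated at (beta1, beta2)."""
    summary = covariance_summary(beta1, beta2, problem, config.t_min_factor)
    return objective(beta1, beta2, summary.t, problem, config, summary), summary


def solve_betas_admm(
    problem: CmmProblem,
    weights: tuple[float, float],
    config: SolverConfig,
    init: dict | None = None,
    track_best: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Consensus-ADMM minimization of the decoupled weighted lasso pair.

    minimizes ``w1 ||y1 - X1 b1||^2 + w2 ||y2 - X2 b2||^2
    + lam1 ||b1||_1 + lam2 ||b2||_1`` with the coupling ``b1 ~ b2``
    enforced through an auxiliary consensus variable z and scaled duals.
    Returns the block iterates (b1, b2) — which may differ at finite
    tolerance — plus a state dict usable for warm starts.

    ``rho = 0`` disables the coupling: each lasso is solved independently.
    """
    w1, w2 = weights
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be nonnegative")
    p = problem.p
    rho = config.rho

    if init is None:
        beta1, beta2 = np.zeros(p), np.zeros(p)
        z = np.zeros(p)
        u1, u2 = np.zeros(p), np.zeros(p)
        g1, g2 = np.zeros(p), np.zeros(p)
    else:
        beta1 = init["beta1"].copy()
        beta2 = init["beta2"].copy()
        z = init["z"].copy()
        u1 = init["u1"].copy()
        u2 = init["u2"].copy()
        g1 = problem.G1 @ beta1
        g2 = problem.G2 @ beta2

    n_admm = 0
    if rho == 0.0:
        zero = np.zeros(p)
        # uncoupled solves run to convergence; degenerate p >> n designs can
        # need many sweeps, which stay cheap at the sizes this mode serves
        full = max(config.cd_max_sweeps, 50000)
        beta1, g1, _ = cd_lasso(problem.G1, problem.cy1, zero, w1, 0.0, config.lambda1, beta1, g1, full, config.cd_tol)
        beta2, g2, _ = cd_lasso(problem.G2, problem.cy2, zero, w2, 0.0, config.lambda2, beta2, g2, full, config.cd_tol)
        n_admm = 1
    else:
        # the block iterates of an inexact consensus ADMM need not improve
        # monotonically (and can diverge when the beta-updates are solved
        # very loosely), so score every iterate on the uncoupled subproblem
        # objective and hand back the best pair seen
        def loss(b1, b2, gg1, gg2):
            rss1 = problem.y1y1 - 2.0 * float(problem.cy1 @ b1) + float(b1 @ gg1)
            rss2 = problem.y2y2 - 2.0 * float(problem.cy2 @ b2) + float(b2 @ gg2)
            return w1 * rss1 + w2 * rss2 + config.lambda1 * float(np.abs(b1).sum()) + config.lambda2 * float(np.abs(b2).sum())

        best = (loss(beta1, beta2, g1, g2), beta1.copy(), beta2.copy(), z.copy(), u1.copy(), u2.copy())
        for it in range(config.max_admm):
            n_admm = it + 1
            beta1, g1, _ = cd_lasso(problem.G1, problem.cy1, z - u1, w1, rho, config.lambda1, beta1, g1, config.cd_max_sweeps, config.cd_tol)
            beta2, g2, _ = cd_lasso(problem.G2, problem.cy2, z - u2, w2, rho, config.lambda2, beta2, g2, config.cd_max_sweeps, config.cd_tol)
            z_old = z
            z = 0.5 * (beta1 + u1 + beta2 + u2)
            u1 = u1 + beta1 - z
            u2 = u2 + beta2 - z

            cur = loss(beta1, beta2, g1, g2)
            if cur < best[0]:
                best = (cur, beta1.copy(), beta2.copy(), z.copy(), u1.copy(), u2.copy())
            elif not np.isfinite(cur) or cur > 10.0 * abs(best[0]) + 1e3:
                if track_best:
                    break  # diverging; keep the best iterate

            r_pri = math.sqrt(float(np.sum((beta1 - z) ** 2) + np.sum((beta2 - z) ** 2)))
            r_dual = rho * math.sqrt(2.0) * float(np.linalg.norm(z - z_old))
            scale = math.sqrt(2 * p)
            eps_pri = scale * config.admm_tol + config.admm_tol * max(
                math.sqrt(float(beta1 @ beta1 + beta2 @ beta2)), math.sqrt(2.0) * float(np.linalg.norm(z))
            )
            eps_dual = scale * config.admm_tol + config.admm_tol * rho * math.sqrt(float(u1 @ u1 + u2 @ u2))
            if r_pri <= eps_pri and r_dual <= eps_dual:
                break
        if track_best:
            _, beta1, beta2, z, u1, u2 = best

    if not (np.all(np.isfinite(beta1)) and np.all(np.isfinite(beta2))):
        raise FloatingPointError(f"non-finite coefficients at ADMM iteration {n_admm}")
    state = {"beta1": beta1, "beta2": beta2, "z": z, "u1": u1, "u2": u2, "n_admm": n_admm}
    return beta1, beta2, state


def solve_cmm(
    paired_or_problem: PairedStudy | CmmProblem,
    vc: VarianceComponents | None = None,
    lambda1: float | None = None,
    lambda2: float | None = None,
    config: SolverConfig | None = None,
    K1: KinshipMatrix | None = None,
    K2: KinshipMatrix | None = None,
    init: dict | None = None,
) -> CoupledEstimate:
    """Alternating solver: freeze the covariance summary, update the betas.

    Each outer iteration (i) evaluates the covariance summary at the current
    coefficients, fixing the loss weights ``w1 = s22/2t, w2 = s11/2t``, then
    (ii) runs the consensus ADMM on the weighted lasso pair.  The recorded
    trace is the full objective (summary re-evaluated at the iterate); an
    update that would increase it beyond tolerance is rejected and the
    solver stops there, so the trace is non-increasing by construction.
    """
    config = config or SolverConfig()
    if lambda1 is not None or lambda2 is not None:
        config = replace(config, lambda1=config.lambda1 if lambda1 is None else lambda1, lambda2=config.lambda2 if lambda2 is None else lambda2)

    if isinstance(paired_or_problem, CmmProblem):
        problem = paired_or_problem
    else:
        paired = paired_or_problem
        if vc is None:
            raise ValueError("variance components are required when passing a PairedStudy")
        if K1 is None or K2 is None:
            # standardized X => tr(XX'/p) = n exactly; avoids forming K
            trK1 = float(paired.study1.n_samples)
            trK2 = float(paired.study2.n_samples)
            problem = CmmProblem(paired.study1.X, paired.study1.y, paired.study2.X, paired.study2.y, vc, trK1, trK2)
        else:
            problem = CmmProblem.from_paired(paired, vc, K1, K2)

    p = problem.p
    beta1, beta2 = np.zeros(p), np.zeros(p)
    state = init
    events: list = []

    obj, summary = _full_objective(beta1, beta2, problem, config)
    trace = [obj]
    if summary.clamped:
        events.append("t clamped at initialization")

    converged = False
    n_admm_total = 0
    n_outer = 0
    for outer in range(config.max_outer):
        n_outer = outer + 1
        w1 = summary.s22 / (2.0 * summary.t)
        w2 = summary.s11 / (2.0 * summary.t)
        cand1, cand2, state = solve_betas_admm(problem, (w1, w2), config, init=state)
        n_admm_total += state["n_admm"]

        new_obj, new_summary = _full_objective(cand1, cand2, problem, config)
        if new_obj > obj + 1e-6:
            # determinant feedback can blow the full objective up even though
            # the fixed-weight subproblem improved; damp the step instead of
            # discarding it, and stop only if no damping helps
            accepted = False
            for theta in (0.5**k for k in range(1, 15)):
                d1 = beta1 + theta * (cand1 - beta1)
                d2 = beta2 + theta * (cand2 - beta2)
                d_obj, d_summary = _full_objective(d1, d2, problem, config)
                if d_obj < obj:
                    cand1, cand2, new_obj, new_summary = d1, d2, d_obj, d_summary
                    events.append(f"outer iteration {n_outer}: step damped by {theta}")
                    accepted = True
                    break
            if not accepted:
                events.append(f"outer iteration {n_outer}: objective would increase by {new_obj - obj:.3e}; update rejected, stopping")
                converged = True
                break
        rel_change = abs(obj - new_obj) / max(1.0, abs(obj))
        beta1, beta2 = cand1, cand2
        obj, summary = new_obj, new_summary
        trace.append(obj)
        if new_summary.clamped:
            events.append(f"outer iteration {n_outer}: t clamped at floor")
        if rel_change < config.outer_tol:
            converged = True
            break

    return CoupledEstimate(
        beta1=beta1,
        beta2=beta2,
        summary=summary,
        objective_trace=trace,
        converged=converged,
        n_outer=n_outer,
        n_admm_total=n_admm_total,
        events=events,
        admm_state=state,
    )


def predict_cross(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Impute the unobserved phenotype of a study as ``X @ beta``.

    For binary traits the caller thresholds the linear predictor at 0.
    """
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but beta has length {beta.shape[0]}")
    return X @ beta
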