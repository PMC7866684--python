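"""Simulation-sweep harness: run all in-scope methods, collect common-SNP AUCs.

One sweep cell = (frac_causal, frac_common, seed).  For each cell a paired
study is generated, every method produces either per-SNP p-values or a
regularization path of support sets, and the ROC/AUC for recovering the
jointly associated SNPs is recorded.  Output is a tidy TSV plus optional
ROC point files and a grid plot.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from cmm.baselines_eval import (
    MethodOutput,
    cd_merge_test,
    joint_lasso,
    l1_logistic_scores,
    lmm_univariate,
    roc_from_path,
    roc_from_scores,
    wald_univariate,
)
from cmm.cmm_core import CmmProblem, SolverConfig, solve_cmm
from cmm.plink_io import PairedStudy, standardize
from cmm.synthetic_data import SimulationConfig, simulate_paired_study
from cmm.variance_components import compute_kinship, estimate_all_components

DEFAULT_METHODS = ("HG(W)", "HG(L)", "CD", "LR", "JL", "CMM")


def prepare_paired(paired: PairedStudy):
    """Standardize, build kinships and estimate variance components (P3D)."""
    st1 = standardize(paired.study1)
    st2 = standardize(paired.study2)
    paired = PairedStudy(study1=st1, study2=st2, common_snp_ids=paired.common_snp_ids)
    K1 = compute_kinship(st1.X)
    K2 = compute_kinship(st2.X)
    vc = estimate_all_components(st1, K1, st2, K2)
    return paired, K1, K2, vc


# path points whose joint support already covers this fraction of the panel
# sit in the far ROC corner; stop there and let the (1,1) endpoint close the
# curve (applied identically to all path methods)
MAX_SUPPORT_FRAC = 0.35


def _support_path_cmm(problem: CmmProblem, lambdas: np.ndarray, config: SolverConfig) -> list:
    supports = []
    state = None
    for lam in np.sort(lambdas)[::-1]:  # sparse-to-dense so warm starts grow supports
        est = solve_cmm(problem, config=replace(config, lambda1=float(lam), lambda2=float(lam)), init=state)
        state = est.admm_state
        s1, s2 = np.nonzero(est.beta1)[0], np.nonzero(est.beta2)[0]
        supports.append((s1, s2))
        if min(s1.size, s2.size) > MAX_SUPPORT_FRAC * problem.p:
            break
    return supports


def _support_path_jl(problem: CmmProblem, lambdas: np.ndarray, config: SolverConfig) -> list:
    from cmm.cmm_core import solve_betas_admm

    supports = []
    state = None
    for lam in np.sort(lambdas)[::-1]:
        cfg = replace(config, lambda1=float(lam), lambda2=float(lam), rho=max(config.rho, 1.0))
        _, _, state = solve_betas_admm(problem, (1.0, 1.0), cfg, init=state, track_best=False)
        z = state["z"].copy()
        z[np.abs(z) < 1e-8] = 0.0
        supp = np.nonzero(z)[0]
        supports.append((supp, supp.copy()))
        if supp.size > MAX_SUPPORT_FRAC * problem.p:
            break
    return supports


def _support_path_lr(X1, y1, X2, y2, c_grid: np.ndarray) -> list:
    supports = []
    for c in c_grid:
        s1 = np.nonzero(l1_logistic_scores(X1, y1, float(c)) > 0)[0]
        s2 = np.nonzero(l1_logistic_scores(X2, y2, float(c)) > 0)[0]
        supports.append((s1, s2))
    return supports


def evaluate_cell(
    sim_config: SimulationConfig,
    methods: tuple = DEFAULT_METHODS,
    n_path: int = 30,
    solver_config: SolverConfig | None = None,
) -> dict:
    """Run the requested methods on one simulated cell; returns label -> (fpr, tpr, auc)."""
    paired_raw, truth = simulate_paired_study(sim_config)
    paired, K1, K2, vc = prepare_paired(paired_raw)
    st1, st2 = paired.study1, paired.study2
    y1c = st1.y - st1.y.mean()
    y2c = st2.y - st2.y.mean()
    common = truth.common
    p = paired.n_snps

    solver_config = solver_config or SolverConfig(max_outer=4, max_admm=30, admm_tol=1e-4, cd_max_sweeps=6)
    lambdas = np.logspace(-5, 5, n_path)

    results = {}
    problem = None
    for label in methods:
        if label == "HG(W)":
            out = MethodOutput(wald_univariate(st1.X, y1c), wald_univariate(st2.X, y2c), "pvalue", label)
            results[label] = roc_from_scores(out, common)
        elif label == "HG(L)":
            p1 = lmm_univariate(st1.X, y1c, K1, vc.sigma_u1_sq, vc.sigma_v1_sq)
            p2 = lmm_univariate(st2.X, y2c, K2, vc.sigma_u2_sq, vc.sigma_v2_sq)
            results[label] = roc_from_scores(MethodOutput(p1, p2, "pvalue", label), common)
        elif label == "CD":
            pv = cd_merge_test(st1, st2)
            results[label] = roc_from_scores(MethodOutput(pv, pv, "pvalue", label), common)
        elif label == "LR":
            c_grid = np.logspace(-2, 2, min(n_path, 12))
            results[label] = roc_from_path(_support_path_lr(st1.X, st1.y, st2.X, st2.y, c_grid), common, p)
        elif label in ("JL", "CMM"):
            if problem is None:
                problem = CmmProblem(st1.X, y1c, st2.X, y2c, vc, K1.trace, K2.trace)
            if label == "JL":
                results[label] = roc_from_path(_support_path_jl(problem, lambdas, solver_config), common, p)
            else:
                results[label] = roc_from_path(_support_path_cmm(problem, lambdas, solver_config), common, p)
        else:
            raise ValueError(f"unknown method label: {label}")
    return results


def run_sweep(raw: dict, outdir: Path) -> pd.DataFrame:
    """Execute the full grid described by a YAML-derived dict.

    Recognized keys (all optional): n, p, n_pop, fst, sigma_u_sq, sigma_v_sq,
    target_snr, frac_causal (list), frac_common (list), seeds (list),
    methods (list), n_path, plot (bool).
    """
    frac_causal = raw.get("frac_causal", [0.001, 0.005, 0.01])
    frac_common = raw.get("frac_common", [0.2, 0.5, 0.8])
    seeds = raw.get("seeds", list(range(1, 11)))
    methods = tuple(raw.get("methods", DEFAULT_METHODS))
    n_path = int(raw.get("n_path", 30))

    base = {
        k: raw[k]
        for k in ("n", "p", "n_pop", "fst", "sigma_u_sq", "sigma_v_sq", "target_snr", "binary")
        if k in raw
    }

    rows = []
    roc_rows = []
    for fc in frac_causal:
        for fcm in frac_common:
            for seed in seeds:
                cfg = SimulationConfig(frac_causal=fc, frac_common=fcm, seed=int(seed), **base)
                try:
                    results = evaluate_cell(cfg, methods=methods, n_path=n_path)
                except Exception as exc:  # record and continue the sweep
                    rows.append({"frac_causal": fc, "frac_common": fcm, "seed": seed, "method": "ERROR", "auc": np.nan, "error": str(exc)})
                    continue
                for label, (fpr, tpr, auc) in results.items():
                    rows.append({"frac_causal": fc, "frac_common": fcm, "seed": seed, "method": label, "auc": auc, "error": ""})
                    for a, b in zip(fpr, tpr):
                        roc_rows.append({"frac_causal": fc, "frac_common": fcm, "seed": seed, "method": label, "fpr": a, "tpr": b})

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "auc_table.tsv", sep="\t", index=False)
    pd.DataFrame(roc_rows).to_csv(outdir / "roc_points.csv", index=False)
    if raw.get("plot", False):
        try:
            plot_sweep(table, pd.DataFrame(roc_rows), outdir)
        except ImportError:
            pass
    return table


def plot_sweep(table: pd.DataFrame, roc_points: pd.DataFrame, outdir: Path) -> None:
    """Grid of mean ROC curves, one panel per (frac_causal, frac_common) cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fcs = sorted(table["frac_causal"].unique())
    fcms = sorted(table["frac_common"].unique())
    fig, axes = plt.subplots(len(fcs), len(fcms), figsize=(4 * len(fcms), 3.5 * len(fcs)), squeeze=False)
    for i, fc in enumerate(fcs):
        for j, fcm in enumerate(fcms):
            ax = axes[i][j]
            cell = roc_points[(roc_points["frac_causal"] == fc) & (roc_points["frac_common"] == fcm)]
            for label, grp in cell.groupby("method"):
                mean_curve = grp.groupby("fpr")["tpr"].mean()
                ax.plot(mean_curve.index, mean_curve.values, label=label, lw=1.2)
            ax.plot([0, 1], [0, 1], "k--", lw=0.5)
            ax.set_title(f"causal={fc}, common={fcm}", fontsize=9)
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "roc_grid.png", dpi=150)
    plt.close(fig)
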