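"""Synthetic paired GWAS studies with structure, confounders and planted signal.

Genotypes follow a Balding-Nichols scheme: each SNP has an ancestral
frequency, each subpopulation perturbs it with a Beta draw whose spread is
controlled by the differentiation parameter ``fst``, and dosages are
binomial in the subpopulation frequency.  The two studies sample different
subpopulation mixtures, emulating independent collection.  Phenotypes are
liabilities ``X b + u + v`` with a kinship-driven confounder u and an iid
collection confounder v; a scalar multiplier on the effect vectors
calibrates the realized signal-to-noise ratio Var(Xb)/Var(u+v) to a target
(0.25 by default).  Binary traits are obtained by median thresholding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cmm.plink_io import GenotypeStudy, PairedStudy, write_plink


@dataclass
class SimulationConfig:
    n: int = 500
    p: int = 5000
    n_pop: int = 3
    fst: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    frac_causal: float = 0.005
    frac_common: float = 0.5
    target_snr: float = 0.25
    sigma_u_sq: float = 1.0
    sigma_v_sq: float = 1.0
    binary: bool = True
    prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if round(self.frac_causal * self.p) < 1:
            raise ValueError("frac_causal * p must allow at least one causal SNP")
        if not (0.0 <= self.frac_common <= 1.0):
            raise ValueError("frac_common must lie in [0, 1]")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if self.sigma_u_sq == 0.0 and self.sigma_v_sq == 0.0:
            raise ValueError("confounder-free data makes the SNR target undefined; set sigma_u_sq or sigma_v_sq > 0")
        if self.frac_common > 0 and self.frac_common * self.frac_causal * self.p < 1:
            raise ValueError("frac_common * frac_causal * p < 1: no common SNP representable")


@dataclass
class SimulationTruth:
    """Ground truth of one paired simulation (never exposed to the solver)."""

    causal1: np.ndarray
    causal2: np.ndarray
    common: np.ndarray
    effects1: np.ndarray
    effects2: np.ndarray
    realized_snr1: float
    realized_snr2: float
    latent_y1_pheno2: np.ndarray = field(default=None, repr=False)
    latent_y2_pheno1: np.ndarray = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal1": self.causal1.tolist(),
                "causal2": self.causal2.tolist(),
                "common": self.common.tolist(),
                "effects1": self.effects1.tolist(),
                "effects2": self.effects2.tolist(),
                "realized_snr1": self.realized_snr1,
                "realized_snr2": self.realized_snr2,
            }
        )


def _mixture_weights(n_pop: int, which: int) -> np.ndarray:
    """Subpopulation mixture per study: uniform for study 1, skewed for 2."""
    if which == 1:
        w = np.ones(n_pop)
    else:
        w = np.arange(1, n_pop + 1, dtype=float)
    return w / w.sum()


def _assign_pops(n: int, weights: np.ndarray) -> np.ndarray:
    counts = np.floor(weights * n).astype(int)
    counts[: n - counts.sum()] += 1
    return np.repeat(np.arange(len(weights)), counts)


def simulate_genotypes(config: SimulationConfig, return_info: bool = False):
    """Draw the two studies' dosage matrices under the Balding-Nichols model.

    Returns ``(X1, X2)`` of shape (n, p) with entries in {0, 1, 2}; with
    ``return_info=True`` a dict with ancestral/subpopulation frequencies and
    the per-sample subpopulation labels is appended.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_x1, rng_x2 = [np.random.default_rng(s) for s in ss.spawn(3)]

    lo, hi = config.maf_range
    f = rng_freq.uniform(lo, hi, size=config.p)
    ratio = (1.0 - config.fst) / config.fst
    # Beta(f*c, (1-f)*c) has mean f and variance fst*f*(1-f)
    pop_freq = rng_freq.beta(f * ratio, (1.0 - f) * ratio, size=(config.n_pop, config.p))
    pop_freq = np.clip(pop_freq, 1e-6, 1.0 - 1e-6)

    pops1 = _assign_pops(config.n, _mixture_weights(config.n_pop, 1))
    pops2 = _assign_pops(config.n, _mixture_weights(config.n_pop, 2))

    def draw(rng, pops):
        X = rng.binomial(2, pop_freq[pops, :]).astype(float)
        mono = X.std(axis=0) == 0.0
        if mono.any():
            X[:, mono] = rng.binomial(2, pop_freq[pops, :][:, mono]).astype(float)
            still = X.std(axis=0) == 0.0
            if still.any():
                warnings.warn(f"{int(still.sum())} SNP(s) remain monomorphic after one resample")
        return X

    X1 = draw(rng_x1, pops1)
    X2 = draw(rng_x2, pops2)
    if return_info:
        info = {"ancestral_freq": f, "pop_freq": pop_freq, "pops1": pops1, "pops2": pops2}
        return X1, X2, info
    return X1, X2


def _standardize_matrix(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (X - mean) / sd


def _variant_table(p: int) -> pd.DataFrame:
    width = len(str(p))
    return pd.DataFrame(
        {
            "snp_id": [f"snp{str(i + 1).zfill(width)}" for i in range(p)],
            "chrom": "1",
            "pos": np.arange(1, p + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )


def simulate_paired_study(config: SimulationConfig) -> tuple[PairedStudy, SimulationTruth]:
    """Generate one paired study plus its ground truth.

    The returned studies carry raw 0/1/2 dosages (so they can round-trip
    through Plink files) and only the observed phenotypes; causal indices,
    true effects and the latent cross-phenotypes live in the truth object.
    """
    ss = np.random.SeedSequence(config.seed)
    _, rng_eff, rng_conf = [np.random.default_rng(s) for s in ss.spawn(3)]

    X1, X2 = simulate_genotypes(config)
    Xs1 = _standardize_matrix(X1)
    Xs2 = _standardize_matrix(X2)
    n, p = X1.shape

    # round-half-up, so frac_common = 0.5 of 25 causal gives 13 common
    n_causal = int(np.floor(config.frac_causal * p + 0.5))
    n_common = int(np.floor(config.frac_common * n_causal + 0.5))
    perm = rng_eff.permutation(p)
    common = np.sort(perm[:n_common])
    own1 = perm[n_common : n_common + (n_causal - n_common)]
    own2 = perm[n_common + (n_causal - n_common) : n_common + 2 * (n_causal - n_common)]
    causal1 = np.sort(np.concatenate([common, own1]))
    causal2 = np.sort(np.concatenate([common, own2]))

    raw1 = np.zeros(p)
    raw2 = np.zeros(p)
    raw1[causal1] = rng_eff.standard_normal(n_causal)
    raw2[causal2] = rng_eff.standard_normal(n_causal)
    raw2[common] = raw1[common]  # shared effects for jointly associated SNPs

    su, sv = config.sigma_u_sq, config.sigma_v_sq

    def confounders(Xs, rng):
        # u ~ N(0, su * K) with K = Xs Xs'/p, sampled as Xs w * sqrt(su/p)
        u = Xs @ rng.standard_normal(p) * np.sqrt(su / p)
        v = rng.standard_normal(n) * np.sqrt(sv)
        return u, v

    u1_p1, v1 = confounders(Xs1, rng_conf)
    u1_p2, _ = confounders(Xs1, rng_conf)
    u2_p1, v2 = confounders(Xs2, rng_conf)
    u2_p2, _ = confounders(Xs2, rng_conf)

    noise1 = u1_p1 + v1
    noise2 = u2_p2 + v2
    g1 = Xs1 @ raw1
    g2 = Xs2 @ raw2
    c1 = np.sqrt(config.target_snr * noise1.var() / g1.var())
    c2 = np.sqrt(config.target_snr * noise2.var() / g2.var())
    c = float(np.sqrt(c1 * c2))  # one shared multiplier keeps common effects identical
    effects1 = c * raw1
    effects2 = c * raw2

    y1_p1 = Xs1 @ effects1 + u1_p1 + v1  # observed: study 1, phenotype 1
    y2_p2 = Xs2 @ effects2 + u2_p2 + v2  # observed: study 2, phenotype 2
    y1_p2 = Xs1 @ effects2 + u1_p2 + v1  # latent
    y2_p1 = Xs2 @ effects1 + u2_p1 + v2  # latent

    realized_snr1 = float((Xs1 @ effects1).var() / noise1.var())
    realized_snr2 = float((Xs2 @ effects2).var() / noise2.var())

    if config.binary:
        q = 1.0 - config.prevalence
        y1 = (y1_p1 > np.quantile(y1_p1, q)).astype(float)
        y2 = (y2_p2 > np.quantile(y2_p2, q)).astype(float)
    else:
        y1, y2 = y1_p1, y2_p2

    variants = _variant_table(p)
    study1 = GenotypeStudy(X=X1, sample_ids=[f"s1_{i}" for i in range(n)], variants=variants.copy(), y=y1, phenotype_name="pheno1")
    study2 = GenotypeStudy(X=X2, sample_ids=[f"s2_{i}" for i in range(n)], variants=variants.copy(), y=y2, phenotype_name="pheno2")
    paired = PairedStudy(study1=study1, study2=study2, common_snp_ids=variants["snp_id"].tolist())

    truth = SimulationTruth(
        causal1=causal1,
        causal2=causal2,
        common=common,
        effects1=effects1,
        effects2=effects2,
        realized_snr1=realized_snr1,
        realized_snr2=realized_snr2,
        latent_y1_pheno2=y1_p2,
        latent_y2_pheno1=y2_p1,
    )
    return paired, truth


def write_simulation(paired: PairedStudy, truth: SimulationTruth, outdir: str | Path, config: SimulationConfig | None = None) -> None:
    """Write the pair as two Plink triples plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(paired.study1, outdir / "study1")
    write_plink(paired.study2, outdir / "study2")
    payload = json.loads(truth.to_json())
    if config is not None:
        payload["config"] = asdict(config)
        payload["snr_definition"] = "Var(X beta) / Var(u + v), liability scale, per observed phenotype"
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
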