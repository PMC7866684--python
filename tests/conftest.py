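import numpy as np
import pandas as pd
import pytest

from cmm.plink_io import GenotypeStudy, PairedStudy
from cmm.synthetic_data import SimulationConfig, simulate_paired_study


def make_study(X, y, ids=None, chrom="1", prefix="snp"):
    """Hand-build a GenotypeStudy from arrays."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    variants = pd.DataFrame(
        {
            "snp_id": [f"{prefix}{j + 1}" for j in range(p)],
            "chrom": chrom,
            "pos": np.arange(1, p + 1) * 100,
            "allele1": "A",
            "allele2": "G",
        }
    )
    if ids is None:
        ids = [f"f{i}_i{i}" for i in range(n)]
    return GenotypeStudy(X=X, sample_ids=ids, variants=variants, y=np.asarray(y, float))


@pytest.fixture
def tiny_study():
    return make_study([[0, 1], [2, 0], [1, 1]], [0, 1, 1])


@pytest.fixture(scope="session")
def small_paired():
    """A modest structured paired study reused across solver tests."""
    cfg = SimulationConfig(n=120, p=250, seed=11, frac_causal=0.02, frac_common=0.5)
    paired, truth = simulate_paired_study(cfg)
    return paired, truth


@pytest.fixture(scope="session")
def prepared_problem(small_paired):
    from cmm.cmm_core import CmmProblem
    from cmm.evaluation import prepare_paired

    paired, truth = small_paired
    std, K1, K2, vc = prepare_paired(paired)
    problem = CmmProblem(
        std.study1.X, std.study1.y, std.study2.X, std.study2.y, vc, K1.trace, K2.trace
    )
    return problem, std, K1, K2, vc, truth
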