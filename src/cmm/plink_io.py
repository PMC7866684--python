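"""Reading, harmonizing and standardizing Plink 1.9 binary genotype studies.

A study is a BED/BIM/FAM triple.  The BED decoder works on the SNP-major
layout (magic bytes ``0x6c 0x1b 0x01``) and returns allele-1 dosages in
``{0, 1, 2}``; missing calls are mean-imputed per SNP.  Two studies are
harmonized onto their common SNP panel by variant id, with dosage flipping
when the allele pair is recorded in swapped order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit Plink codes per sample: 00 hom A1 (dosage 2), 01 missing,
# 10 het (dosage 1), 11 hom A2 (dosage 0).
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "allele1", "allele2"]
_FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


@dataclass
class GenotypeStudy:
    """One cohort: dosage matrix, variant metadata and the observed phenotype.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Allele-1 dosages (0/1/2 before standardization; floats after).
    sample_ids : list of str
        Unique sample identifiers (``fid_iid``), FAM order.
    variants : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos``,
        ``allele1``, ``allele2``.
    y : ndarray of shape (n,)
        Phenotype vector; case/control is coded 0/1.
    phenotype_name : str
    standardized : bool
        True once :func:`standardize` has been applied.
    monomorphic : ndarray of bool or None
        Per-SNP flag for zero-variance columns, set by :func:`standardize`.
    """

    X: np.ndarray
    sample_ids: list
    variants: pd.DataFrame
    y: np.ndarray
    phenotype_name: str = "phenotype"
    standardized: bool = False
    monomorphic: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"sample_ids length {len(self.sample_ids)} != {n} rows of X")
        if len(self.y) != n:
            raise ValueError(f"phenotype length {len(self.y)} != {n} rows of X")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records for {p} SNP columns")
        ids = self.variants["snp_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids within study: {dups[:5]}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @property
    def snp_ids(self) -> list:
        return self.variants["snp_id"].tolist()


@dataclass
class PairedStudy:
    """Two studies restricted to their common SNP panel, column-aligned."""

    study1: GenotypeStudy
    study2: GenotypeStudy
    common_snp_ids: list = field(default_factory=list)

    def __post_init__(self):
        ids1 = self.study1.snp_ids
        ids2 = self.study2.snp_ids
        if ids1 != ids2 or ids1 != list(self.common_snp_ids):
            raise ValueError("paired studies must share an identical, ordered SNP panel")
        if len(self.common_snp_ids) < 1:
            raise ValueError("paired study needs at least one common SNP")

    @property
    def n_snps(self) -> int:
        return len(self.common_snp_ids)


def _decode_bed(path: Path, n_samples: int, n_snps: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{path}: not a Plink BED file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{path}: only SNP-major BED files are supported")
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    expected = bytes_per_snp * n_snps
    if body.size != expected:
        raise ValueError(f"{path}: expected {expected} data bytes for {n_samples}x{n_snps}, found {body.size}")
    blocks = body.reshape(n_snps, bytes_per_snp)
    # unpack the four 2-bit codes of every byte, little-endian within byte
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = blocks & 0b11
    codes[:, 1::4] = (blocks >> 2) & 0b11
    codes[:, 2::4] = (blocks >> 4) & 0b11
    codes[:, 3::4] = (blocks >> 6) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T  # (n, p)


def read_plink(prefix: str | Path, phenotype_name: str = "phenotype") -> GenotypeStudy:
    """Load a BED/BIM/FAM triple into a :class:`GenotypeStudy`.

    FAM phenotype codes 1/2 map to 0/1 (control/case); -9 and 0 are treated
    as missing.  Missing genotype calls are imputed to the per-SNP mean
    dosage; SNPs missing in every sample are dropped with a warning.

    Raises
    ------
    FileNotFoundError
        If any of the three files is absent (the message names the file).
    ValueError
        On malformed BED contents or a non-numeric phenotype column.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(prefix.suffix + "." + ext) for ext in ("bed", "bim", "fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing Plink {ext.upper()} file: {path}")

    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None, names=_BIM_COLUMNS, dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str})
    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, names=_FAM_COLUMNS, dtype={"fid": str, "iid": str})

    try:
        pheno_raw = fam["phenotype"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{paths['fam']}: non-numeric phenotype column") from exc
    y = np.where(np.isin(pheno_raw, (-9.0, 0.0)), np.nan, pheno_raw)
    # case/control recoding 1/2 -> 0/1; quantitative values pass through
    if np.all(np.isin(y[~np.isnan(y)], (1.0, 2.0))):
        y = y - 1.0

    X = _decode_bed(paths["bed"], len(fam), len(bim))

    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        dropped = bim.loc[all_missing, "snp_id"].tolist()
        warnings.warn(f"dropping {len(dropped)} SNP(s) with no genotype calls: {dropped[:5]}")
        X = X[:, ~all_missing]
        bim = bim.loc[~all_missing].reset_index(drop=True)

    # mean-impute remaining missing calls per SNP
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]

    sample_ids = (fam["fid"].astype(str) + "_" + fam["iid"].astype(str)).tolist()
    variants = bim[["snp_id", "chrom", "pos", "allele1", "allele2"]].reset_index(drop=True)
    return GenotypeStudy(X=X, sample_ids=sample_ids, variants=variants, y=y, phenotype_name=phenotype_name)


def write_plink(study: GenotypeStudy, prefix: str | Path) -> None:
    """Write a study to BED/BIM/FAM (SNP-major).  Dosages must be in {0,1,2}."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = study.X
    if not np.all(np.isin(X[~np.isnan(X)], (0.0, 1.0, 2.0))):
        raise ValueError("write_plink requires hard-call dosages in {0,1,2}")
    n, p = X.shape
    dosage_to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    codes = np.full((p, n), 0b01, dtype=np.uint8)  # 01 = missing
    for d, c in dosage_to_code.items():
        codes[(X.T == d)] = c
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    # NA padding must be 00 (ignored by readers); our 0b01 filler only covers samples
    padded[:, n:] = 0
    packed = padded[:, 0::4] | (padded[:, 1::4] << 2) | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    v = study.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "snp_id": v["snp_id"],
            "cm": 0,
            "pos": v["pos"],
            "allele1": v["allele1"],
            "allele2": v["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(prefix.suffix + ".bim"), sep="\t", header=False, index=False)

    yout = study.y
    if np.all(np.isin(yout[~np.isnan(yout)], (0.0, 1.0))):
        pheno = np.where(np.isnan(yout), -9, yout + 1).astype(int)
    else:
        pheno = np.where(np.isnan(yout), -9.0, yout)
    fam = pd.DataFrame(
        {
            "fid": [sid.split("_", 1)[0] if "_" in sid else sid for sid in study.sample_ids],
            "iid": [sid.split("_", 1)[1] if "_" in sid else sid for sid in study.sample_ids],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": pheno,
        }
    )
    fam.to_csv(prefix.with_suffix(prefix.suffix + ".fam"), sep="\t", header=False, index=False)


def _chrom_sort_key(chrom: str) -> tuple:
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def intersect_snps(s1: GenotypeStudy, s2: GenotypeStudy) -> PairedStudy:
    """Restrict two studies to their common SNP ids, harmonizing alleles.

    Common SNPs are ordered deterministically by (chromosome, position, id)
    taken from study 1.  When study 2 records the allele pair swapped
    relative to study 1, its dosages are flipped (``d -> 2 - d``).  SNPs
    whose allele pairs neither match nor swap are dropped with a warning.
    """
    v1 = s1.variants.set_index("snp_id")
    v2 = s2.variants.set_index("snp_id")
    common = [sid for sid in v1.index if sid in set(v2.index)]
    if not common:
        raise ValueError("no common SNP ids between the two studies")

    keep, flip = [], []
    for sid in common:
        a1, a2 = v1.loc[sid, ["allele1", "allele2"]]
        b1, b2 = v2.loc[sid, ["allele1", "allele2"]]
        if (a1, a2) == (b1, b2):
            keep.append(sid)
            flip.append(False)
        elif (a1, a2) == (b2, b1):
            keep.append(sid)
            flip.append(True)
        else:
            warnings.warn(f"SNP {sid}: irreconcilable alleles ({a1}/{a2} vs {b1}/{b2}); dropped")
    if not keep:
        raise ValueError("no common SNPs left after allele harmonization")

    order = sorted(
        range(len(keep)),
        key=lambda i: (_chrom_sort_key(str(v1.loc[keep[i], "chrom"])), v1.loc[keep[i], "pos"], keep[i]),
    )
    keep = [keep[i] for i in order]
    flip = np.array([flip[i] for i in order], dtype=bool)

    idx1 = [s1.snp_ids.index(sid) for sid in keep]
    idx2 = [s2.snp_ids.index(sid) for sid in keep]

    X1 = s1.X[:, idx1].copy()
    X2 = s2.X[:, idx2].copy()
    X2[:, flip] = 2.0 - X2[:, flip]

    var1 = s1.variants.iloc[idx1].reset_index(drop=True)
    # after flipping, study2 adopts study1's allele orientation
    var2 = var1.copy()

    out1 = replace(s1, X=X1, variants=var1)
    out2 = replace(s2, X=X2, variants=var2)
    return PairedStudy(study1=out1, study2=out2, common_snp_ids=keep)


def standardize(study: GenotypeStudy) -> GenotypeStudy:
    """Return a copy with zero-mean, unit-variance SNP columns.

    Zero-variance (monomorphic) columns become all-zero and are flagged in
    ``monomorphic``.  Idempotent.  Requires no missing values.
    """
    X = study.X
    if np.isnan(X).any():
        raise ValueError("standardize requires imputed (non-missing) dosages")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    mono = sd == 0.0
    safe_sd = np.where(mono, 1.0, sd)
    Xs = (X - mean) / safe_sd
    Xs[:, mono] = 0.0
    return replace(study, X=Xs, standardized=True, monomorphic=mono)


def exclude_x_chromosome(study: GenotypeStudy) -> GenotypeStudy:
    """Drop SNPs on the X chromosome (chrom '23' or 'X')."""
    chrom = study.variants["chrom"].astype(str)
    keep = ~chrom.isin(("23", "X", "x"))
    if keep.all():
        return study
    idx = np.nonzero(keep.to_numpy())[0]
    return replace(study, X=study.X[:, idx], variants=study.variants.iloc[idx].reset_index(drop=True))
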