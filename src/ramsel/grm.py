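"""SNP quality control and the VanRaden (method 1) genomic relationship matrix.

Genotypes are coded as counts of the B allele (0/1/2) with an explicit
missing code.  QC applies the three marker filters used for high-density
layer panels: minor allele frequency > 0.025, missing-call proportion
< 0.05, and parent-offspring opposing-homozygote (mismatch) rate < 0.05.
After mean imputation the genomic relationship matrix is

    G = Z Z' / (2 sum_j p_j (1 - p_j)),   Z_ij = g_ij - 2 p_j,

with allele frequencies computed over all genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelationshipMatrix

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "SnpQcReport",
    "QcError",
    "QcThresholds",
    "load_genotypes",
    "qc_filter",
    "allele_frequencies",
    "impute_missing",
    "vanraden_grm",
    "compare_relationships",
    "parent_mismatch_rates",
    "verify_parentage",
]


class QcError(ValueError):
    """Raised when QC removes every SNP or inputs are inconsistent."""


@dataclass(frozen=True)
class QcThresholds:
    maf: float = 0.025
    miss: float = 0.05
    mismatch: float = 0.05


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (individuals x SNPs), B-allele dosage 0/1/2.

    Missing calls are stored as ``missing_code`` (-1 by default); after
    :func:`impute_missing` calls are floats and no missing codes remain.
    """

    individual_labels: list[str]
    snp_labels: list[str]
    calls: np.ndarray
    missing_code: int = MISSING
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.individual_labels), len(self.snp_labels)):
            raise ValueError("genotype calls shape does not match labels")
        legal = (
            (self.calls == 0)
            | (self.calls == 1)
            | (self.calls == 2)
            | (self.calls == self.missing_code)
        )
        if not np.all(legal):
            bad = np.unique(np.asarray(self.calls)[~legal])
            raise ValueError(f"illegal genotype codes: {bad}")
        self._index = {iid: i for i, iid in enumerate(self.individual_labels)}

    @property
    def n_individuals(self) -> int:
        return len(self.individual_labels)

    @property
    def n_snps(self) -> int:
        return len(self.snp_labels)

    def row(self, iid: str) -> np.ndarray:
        return self.calls[self._index[iid]]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[i] for i in ids]
        return GenotypeMatrix(
            list(ids), list(self.snp_labels), self.calls[idx], self.missing_code
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        labels = [s for s, k in zip(self.snp_labels, keep) if k]
        return GenotypeMatrix(
            list(self.individual_labels), labels, self.calls[:, keep], self.missing_code
        )

    def write_csv(self, path) -> None:
        df = pd.DataFrame(
            self.calls, index=self.individual_labels, columns=self.snp_labels
        )
        df = df.replace(self.missing_code, np.nan)
        df.index.name = "id"
        df.to_csv(path, na_rep="NA")


@dataclass
class SnpQcReport:
    """Per-SNP QC statistics and pass/fail status."""

    snp_labels: list[str]
    maf: np.ndarray
    miss_rate: np.ndarray
    mismatch_rate: np.ndarray
    passed: np.ndarray
    fail_reason: list[str]  # "" for passing SNPs
    thresholds: QcThresholds
    n_before: int = 0
    n_after: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_labels,
                "maf": self.maf,
                "miss_rate": self.miss_rate,
                "mismatch_rate": self.mismatch_rate,
                "pass": self.passed,
                "fail_reason": self.fail_reason,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "n_before": int(self.n_before),
            "n_after": int(self.n_after),
            "thresholds": vars(self.thresholds),
            "snps": self.to_frame().to_dict(orient="records"),
        }

    def summary(self) -> str:
        reasons = pd.Series([r for r in self.fail_reason if r]).value_counts()
        lines = [
            f"SNP QC: {self.n_before} before, {self.n_after} after",
            f"thresholds: MAF>{self.thresholds.maf}, "
            f"missing<{self.thresholds.miss}, mismatch<{self.thresholds.mismatch}",
        ]
        for reason, count in reasons.items():
            lines.append(f"  removed for {reason}: {count}")
        return "\n".join(lines)


def load_genotypes(path) -> GenotypeMatrix:
    """Read a genotype table: CSV/TSV with first column ``id`` and one column
    per SNP (cells 0/1/2/NA), or PLINK ``.raw`` additive coding."""
    with open(path) as fh:
        header = fh.readline()
    if header.split()[:2] == ["FID", "IID"]:  # PLINK .raw (whitespace separated)
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).tolist()
        snps = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
        calls = df[snps].to_numpy(dtype=float)
    else:
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        ids = df.index.astype(str).tolist()
        snps = list(df.columns)
        calls = df.to_numpy(dtype=float)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(ids, [str(s) for s in snps], out)


def _trio_pairs(G: GenotypeMatrix, ped: Pedigree) -> list[tuple[int, int]]:
    """(offspring_row, parent_row) index pairs for genotyped parent-offspring."""
    pairs = []
    for r in ped.records:
        if r.id not in G:
            continue
        for p in ped.parents(r.id):
            if p is not None and p in G:
                pairs.append((G._index[r.id], G._index[p]))
    return pairs


def parent_mismatch_rates(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Per-SNP opposing-homozygote rate over genotyped parent-offspring pairs.

    A pair opposes at a SNP when one is 0 and the other 2 — impossible under
    Mendelian transmission without error.  SNPs with no informative pair get
    rate 0.
    """
    pairs = _trio_pairs(G, ped)
    m = G.n_snps
    if not pairs:
        return np.zeros(m)
    off = np.array([p[0] for p in pairs])
    par = np.array([p[1] for p in pairs])
    a = G.calls[off]
    b = G.calls[par]
    valid = (a != G.missing_code) & (b != G.missing_code)
    opposing = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_valid > 0, opposing.sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    return rate


def verify_parentage(
    G: GenotypeMatrix, ped: Pedigree, threshold: float = 0.05
) -> pd.DataFrame:
    """Flag declared parent-offspring pairs whose genome-wide
    opposing-homozygote rate exceeds ``threshold``.

    This is a genotype-only parentage verification: true parent-offspring
    pairs oppose only through genotyping error, so a high rate indicates a
    pedigree or sample error.  Pairs are flagged, never dropped.
    """
    rows = []
    for r in ped.records:
        if r.id not in G:
            continue
        g_off = G.row(r.id)
        for p in ped.parents(r.id):
            if p is None or p not in G:
                continue
            g_par = G.row(p)
            valid = (g_off != G.missing_code) & (g_par != G.missing_code)
            if valid.sum() == 0:
                continue
            opp = (
                ((g_off == 0) & (g_par == 2)) | ((g_off == 2) & (g_par == 0))
            ) & valid
            rate = opp.sum() / valid.sum()
            rows.append(
                {
                    "offspring": r.id,
                    "parent": p,
                    "opposing_rate": rate,
                    "n_snps": int(valid.sum()),
                    "flagged": bool(rate > threshold),
                }
            )
    return pd.DataFrame(rows, columns=["offspring", "parent", "opposing_rate", "n_snps", "flagged"])


def qc_filter(
    G: GenotypeMatrix,
    ped: Pedigree | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Remove SNPs failing MAF, missingness or parent-offspring mismatch
    thresholds.  The report keeps all per-SNP statistics; a SNP's
    ``fail_reason`` names the first failing filter (maf, miss, mismatch)."""
    calls = G.calls
    missing = calls == G.missing_code
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(
            n_obs > 0, np.where(missing, 0, calls).sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.0
        )
    maf = np.minimum(p, 1 - p)
    miss_rate = missing.mean(axis=0)
    mismatch = (
        parent_mismatch_rates(G, ped) if ped is not None else np.zeros(G.n_snps)
    )

    reasons = []
    passed = np.ones(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        if not (maf[j] > thresholds.maf):
            reasons.append("maf")
            passed[j] = False
        elif not (miss_rate[j] < thresholds.miss):
            reasons.append("miss")
            passed[j] = False
        elif not (mismatch[j] < thresholds.mismatch):
            reasons.append("mismatch")
            passed[j] = False
        else:
            reasons.append("")
    if not passed.any():
        raise QcError("no SNPs survive QC")
    report = SnpQcReport(
        snp_labels=list(G.snp_labels),
        maf=maf,
        miss_rate=miss_rate,
        mismatch_rate=mismatch,
        passed=passed,
        fail_reason=reasons,
        thresholds=thresholds,
        n_before=G.n_snps,
        n_after=int(passed.sum()),
    )
    return G.subset_snps(passed), report


def allele_frequencies(
    G: GenotypeMatrix, reference_ids: Iterable[str] | None = None
) -> pd.Series:
    """B-allele frequency per SNP over a reference set (default: all
    genotyped animals): p_j = sum(calls) / (2 * non-missing count)."""
    if reference_ids is None:
        sub = G
    else:
        ids = list(reference_ids)
        if not ids:
            raise QcError("empty reference set for allele frequencies")
        sub = G.subset_individuals(ids)
    calls = sub.calls
    missing = calls == sub.missing_code
    n_obs = (~missing).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [s for s, n in zip(sub.snp_labels, n_obs) if n == 0]
        raise QcError(f"SNPs with all calls missing in reference set: {bad[:5]}")
    p = np.where(missing, 0, calls).sum(axis=0) / (2.0 * n_obs)
    return pd.Series(p, index=sub.snp_labels, name="p")


def impute_missing(G: GenotypeMatrix, freqs: pd.Series) -> GenotypeMatrix:
    """Replace missing calls at SNP j by the population mean dosage 2*p_j."""
    if list(freqs.index) != list(G.snp_labels):
        raise QcError("allele frequencies do not match genotype SNP set")
    calls = G.calls.astype(float)
    missing = G.calls == G.missing_code
    calls[missing] = np.broadcast_to(2.0 * freqs.to_numpy(), calls.shape)[missing]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.individual_labels = list(G.individual_labels)
    out.snp_labels = list(G.snp_labels)
    out.calls = calls
    out.missing_code = G.missing_code
    out._index = dict(G._index)
    return out


def center(G: GenotypeMatrix, freqs: pd.Series) -> np.ndarray:
    """Centered dosage matrix Z = calls - 2p (missing must be imputed)."""
    calls = np.asarray(G.calls, dtype=float)
    if np.any(calls == G.missing_code):
        raise QcError("impute missing calls before centering")
    return calls - 2.0 * freqs.to_numpy()


def vanraden_scale(freqs: pd.Series) -> float:
    """The VanRaden denominator 2 sum_j p_j (1 - p_j)."""
    p = freqs.to_numpy()
    return float(2.0 * np.sum(p * (1.0 - p)))


def vanraden_grm(G: GenotypeMatrix, freqs: pd.Series) -> RelationshipMatrix:
    """Genomic relationship matrix G = ZZ' / (2 sum p(1-p))."""
    Z = center(G, freqs)
    denom = vanraden_scale(freqs)
    if denom <= 0:
        raise QcError("VanRaden denominator is zero (all SNPs monomorphic)")
    return RelationshipMatrix(
        list(G.individual_labels), (Z @ Z.T) / denom, "genomic_G"
    )


def compare_relationships(
    Gm: RelationshipMatrix,
    Am: RelationshipMatrix,
    ids: Sequence[str] | None = None,
    include_diagonal: bool = False,
) -> dict:
    """Regression of genomic on pedigree relationships over element pairs.

    Returns the least-squares slope, intercept, Pearson correlation and the
    number of element pairs used.  Off-diagonal elements only by default.
    """
    if ids is None:
        ids = [i for i in Gm.labels if i in Am._index]
    gs = Gm.submatrix(ids).values
    as_ = Am.submatrix(ids).values
    n = len(ids)
    if include_diagonal:
        iu = np.triu_indices(n, k=0)
    else:
        iu = np.triu_indices(n, k=1)
    x = as_[iu]
    y = gs[iu]
    if x.size < 3:
        raise QcError("fewer than 3 element pairs for relationship comparison")
    if np.var(x) == 0 or np.var(y) == 0:
        raise QcError("relationship elements have zero variance; cannot regress")
    slope, intercept = np.polyfit(x, y, 1)
    corr = float(np.corrcoef(x, y)[0, 1])
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "correlation": corr,
        "n_pairs": int(x.size),
    }
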