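"""Forward-validation metrics for predicted breeding values.

Validation compares EBV against phenotypes corrected for fixed effects in
a generation-forward split: accuracy = cor(EBV, y*) / sqrt(h2), bias =
the regression slope of y* on EBV (1 = unbiased dispersion), the mean
corrected phenotype of the top-k selected individuals, parent-average EBV
and the nested-regression test of whether parent averages add predictive
information beyond genomic EBV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .ram import MmeSolution
from .bayescpi import preadjust_phenotypes

__all__ = [
    "EbvSet",
    "hatch_corrected_phenotypes",
    "accuracy",
    "bias_slope",
    "msd_from_one",
    "top_k_mean",
    "parental_average_ebv",
    "pa_increment_test",
    "ebv_correlation_matrix",
    "ValidationReport",
]


@dataclass
class EbvSet:
    """Labelled EBV from one prediction method."""

    method: str
    values: pd.Series  # id -> EBV

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate ids in EBV set")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite EBV")

    def common_ids(self, other: "pd.Series | EbvSet") -> pd.Index:
        idx = other.values.index if isinstance(other, EbvSet) else other.index
        return self.values.index.intersection(idx)


def hatch_corrected_phenotypes(
    phenos: pd.DataFrame,
    full_am_solution: MmeSolution,
    fixed_factors: Sequence[str] = ("generation", "hatch"),
) -> pd.Series:
    """Phenotypes corrected for fixed effects, y* = y - x'b_hat (same
    computation as the Bayes-C-pi pre-adjustment)."""
    adj = preadjust_phenotypes(phenos, full_am_solution, fixed_factors)
    return pd.Series(adj["ystar"].to_numpy(), index=adj["id"].astype(str), name="ystar")


def _align(ebv: EbvSet, ystar: pd.Series, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    ids = ebv.common_ids(ystar)
    if len(ids) < min_n:
        raise ValueError(f"only {len(ids)} overlapping ids (need >= {min_n})")
    return ebv.values[ids].to_numpy(), ystar[ids].to_numpy()


def accuracy(ebv: EbvSet, ystar: pd.Series, h2: float) -> float:
    """cor(EBV, corrected phenotype) / sqrt(h2).

    Not clamped: sampling noise can push it past 1.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    x, y = _align(ebv, ystar)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in EBV or corrected phenotypes")
    return float(np.corrcoef(x, y)[0, 1] / np.sqrt(h2))


def bias_slope(ystar: pd.Series, ebv: EbvSet) -> float:
    """OLS slope of corrected phenotype on EBV; 1 means unbiased."""
    x, y = _align(ebv, ystar)
    if np.var(x) == 0:
        raise ValueError("zero EBV variance")
    return float(np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1))


def msd_from_one(slopes: Sequence[float]) -> float:
    """Mean squared deviation of regression slopes from 1 across traits."""
    slopes = np.asarray(list(slopes), dtype=float)
    if slopes.size == 0:
        raise ValueError("empty slope list")
    return float(np.mean((slopes - 1.0) ** 2))


def top_k_mean(
    ebv: EbvSet, ystar: pd.Series, k: int = 30, higher_is_better: bool = True
) -> float:
    """Mean corrected phenotype of the k individuals with the most
    favourable EBV; ties broken by stable id order."""
    ids = ebv.common_ids(ystar)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} validation individuals")
    sub = ebv.values[ids]
    key = -sub if higher_is_better else sub
    order = sorted(ids, key=lambda i: (key[i], i))
    chosen = order[:k]
    return float(ystar[chosen].mean())


def parental_average_ebv(ped: Pedigree, ebv: EbvSet, ids: Sequence[str]) -> EbvSet:
    """PA_i = (EBV_sire + EBV_dam) / 2 for each requested individual.

    Individuals with a missing parent EBV are excluded (logged)."""
    import logging

    out = {}
    skipped = []
    for iid in ids:
        sire, dam = ped.parents(iid)
        if (
            sire is None
            or dam is None
            or sire not in ebv.values.index
            or dam not in ebv.values.index
        ):
            skipped.append(iid)
            continue
        out[iid] = 0.5 * (ebv.values[sire] + ebv.values[dam])
    if skipped:
        logging.getLogger(__name__).info(
            "parental_average_ebv: skipped %d ids without both parent EBV", len(skipped)
        )
    return EbvSet(f"{ebv.method}-PA", pd.Series(out, dtype=float))


def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(R^2, residual sum of squares) of y on [1, X]."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - rss / tss, rss


def pa_increment_test(ystar: pd.Series, gebv: EbvSet, pa: EbvSet) -> dict:
    """Does the parent average add predictive ability beyond genomic EBV?

    Fits y* ~ GEBV and y* ~ GEBV + PA on the common validation ids and
    reports both R^2, the increment, and the partial F-test p-value for
    the added regressor.  The null (no increment) holds when the markers
    capture all pedigree information.  Near-collinear GEBV/PA
    (|correlation| > 0.9999) is flagged and the p-value suppressed.
    """
    ids = gebv.common_ids(pa).intersection(ystar.index)
    n = len(ids)
    if n < 5:
        raise ValueError(f"only {n} validation ids (need >= 5)")
    y = ystar[ids].to_numpy()
    g = gebv.values[ids].to_numpy()
    p = pa.values[ids].to_numpy()
    r2_base, rss_base = _ols_r2(y, g[:, None])
    r2_full, rss_full = _ols_r2(y, np.column_stack([g, p]))
    out = {
        "r2_base": r2_base,
        "r2_full": r2_full,
        "delta_r2": r2_full - r2_base,
        "n": n,
        "collinear": False,
        "p_value": np.nan,
    }
    if abs(np.corrcoef(g, p)[0, 1]) > 0.9999:
        out["collinear"] = True
        return out
    df_full = n - 3  # intercept + 2 slopes
    f = (rss_base - rss_full) / (rss_full / df_full)
    out["p_value"] = float(stats.f.sf(max(f, 0.0), 1, df_full))
    return out


def pa_increment_test_bootstrap(
    ystar: pd.Series,
    gebv: EbvSet,
    pa: EbvSet,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Bootstrap alternative to the partial F-test: resamples validation
    individuals and reports the fraction of resamples with delta R^2 <= 0."""
    rng = np.random.default_rng(seed)
    ids = list(gebv.common_ids(pa).intersection(ystar.index))
    base = pa_increment_test(ystar, gebv, pa)
    y = ystar[ids].to_numpy()
    g = gebv.values[ids].to_numpy()
    p = pa.values[ids].to_numpy()
    n = len(ids)
    count = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r2b, _ = _ols_r2(y[idx], g[idx, None])
        r2f, _ = _ols_r2(y[idx], np.column_stack([g[idx], p[idx]]))
        if r2f - r2b <= 0:
            count += 1
    base["p_boot"] = count / n_boot
    return base


def ebv_correlation_matrix(sets: Sequence[EbvSet]) -> pd.DataFrame:
    """Pairwise Pearson correlations of EBV over the common id subset."""
    ids = sets[0].values.index
    for s in sets[1:]:
        ids = ids.intersection(s.values.index)
    if len(ids) < 3:
        raise ValueError("fewer than 3 common ids across EBV sets")
    mat = np.column_stack([s.values[ids].to_numpy() for s in sets])
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        flat = [s.method for s, v in zip(sets, sd) if v == 0]
        raise ValueError(f"degenerate EBV variance for: {flat}")
    corr = np.corrcoef(mat, rowvar=False)
    names = [s.method for s in sets]
    return pd.DataFrame(corr, index=names, columns=names)


@dataclass
class ValidationReport:
    """Per-method validation metrics for one trait, plus cross-method
    comparisons, serializable as JSON and as a formatted text table."""

    trait: str
    h2: float
    n_validation: int
    per_method: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: method, accuracy, slope, top_k_mean
    ebv_correlations: pd.DataFrame | None = None
    pa_increment: dict | None = None

    @classmethod
    def build(
        cls,
        trait: str,
        h2: float,
        ystar: pd.Series,
        ebv_sets: Sequence[EbvSet],
        k: int = 30,
        higher_is_better: bool = True,
        pa_pair: tuple[EbvSet, EbvSet] | None = None,
    ) -> "ValidationReport":
        rows = []
        for s in ebv_sets:
            rows.append(
                {
                    "method": s.method,
                    "accuracy": accuracy(s, ystar, h2),
                    "slope": bias_slope(ystar, s),
                    "top_k_mean": top_k_mean(s, ystar, k=min(k, len(s.common_ids(ystar))),
                                             higher_is_better=higher_is_better),
                }
            )
        corr = ebv_correlation_matrix(ebv_sets) if len(ebv_sets) > 1 else None
        inc = pa_increment_test(ystar, *pa_pair) if pa_pair is not None else None
        n_val = len(ebv_sets[0].common_ids(ystar))
        return cls(
            trait=trait,
            h2=h2,
            n_validation=n_val,
            per_method=pd.DataFrame(rows).set_index("method"),
            ebv_correlations=corr,
            pa_increment=inc,
        )

    def to_json_dict(self) -> dict:
        out = {
            "trait": self.trait,
            "h2": self.h2,
            "n_validation": self.n_validation,
            "per_method": self.per_method.reset_index().to_dict(orient="records"),
        }
        if self.ebv_correlations is not None:
            out["ebv_correlations"] = self.ebv_correlations.to_dict()
        if self.pa_increment is not None:
            out["pa_increment"] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.pa_increment.items()
            }
        return out

    def summary(self) -> str:
        title = f"Validation report: {self.trait} (h2={self.h2}, n={self.n_validation})"
        lines = [title, "=" * len(title), "", self.per_method.round(4).to_string()]
        if self.ebv_correlations is not None:
            lines += ["", "EBV correlations", self.ebv_correlations.round(3).to_string()]
        if self.pa_increment is not None:
            inc = self.pa_increment
            lines += [
                "",
                "PA increment: R2 {:.4f} -> {:.4f} (delta {:.4f}, p={})".format(
                    inc["r2_base"],
                    inc["r2_full"],
                    inc["delta_r2"],
                    "n/a" if np.isnan(inc.get("p_value", np.nan)) else f"{inc['p_value']:.4g}",
                ),
            ]
        return "\n".join(lines)
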