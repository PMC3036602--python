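"""Reduced animal model (RAM) mixed-model equations and variance estimation.

The RAM fits breeding values only for genotyped individuals (all parents
plus any genotyped non-parents) and absorbs records on non-genotyped
non-parents through their parents:

    y = X b + (P + 1/2 Q S + 1/2 Q D) a + e

where ``a`` (length p) holds breeding values of genotyped individuals with
Var(a) = K sigma_a^2 (K is the pedigree A among genotyped animals for
PBLUP or the VanRaden G for GBLUP), P indicates records on genotyped
individuals, and S/D point records on non-genotyped individuals at their
sire and dam columns.  Residual variance is sigma_e^2 for records on
genotyped individuals and sigma_e^2 + 1/2 sigma_a^2 for records on
non-genotyped individuals (the Mendelian sampling deviation joins the
residual; the effect of parental inbreeding on it is ignored).  EBV of
non-genotyped individuals are recovered afterwards by backsolution.

The module also provides the full (non-reduced) animal model, which serves
both as the pre-adjustment model for Bayes-C-pi and as the structural
oracle the RAM must agree with, and an EM-REML estimator of the two
variance components operating on the model's marginal covariance.

Model-object interface: :class:`ReducedAnimalModel` and :class:`AnimalModel`
wrap the functional layer; their ``fit()`` returns results objects with a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.sparse.linalg import spsolve

from .pedigree import (
    IndividualPartition,
    Pedigree,
    RelationshipMatrix,
    a_inverse,
    partition_individuals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RamDesignError",
    "VarianceComponents",
    "RamDesign",
    "MmeSolution",
    "build_fixed_design",
    "build_ram_design",
    "solve_ram",
    "backsolve_nonparents",
    "fit_full_animal_model",
    "ram_marginal_relationship",
    "RemlBasis",
    "em_reml",
    "ReducedAnimalModel",
    "AnimalModel",
]


class RamDesignError(ValueError):
    """Raised when records cannot be expressed in the reduced model."""


@dataclass
class VarianceComponents:
    """Additive and residual variance (trait units squared)."""

    sigma_a2: float
    sigma_e2: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @classmethod
    def from_h2(cls, h2: float, phenotypic_variance: float = 1.0) -> "VarianceComponents":
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        return cls(h2 * phenotypic_variance, (1 - h2) * phenotypic_variance)


@dataclass
class RamDesign:
    """Incidence structures of the reduced animal model.

    ``W = P + 1/2 (QS + QD)`` is stored directly as a sparse matrix; each
    record row sums to 1 (either a single 1 on a genotyped individual or
    1/2 on each parent).  ``nongenotyped`` marks the heterogeneous residual
    class.
    """

    y: np.ndarray
    X: np.ndarray
    fixed_levels: list[str]
    W: sparse.csr_matrix
    genotyped_ids: list[str]
    record_ids: list[str]
    nongenotyped: np.ndarray  # bool per record
    record_parents: dict[str, tuple[str, str]]  # for non-genotyped records

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class MmeSolution:
    """Solutions of the mixed-model equations."""

    b: pd.Series  # fixed-effect solutions by level
    a: pd.Series  # EBV of individuals fitted in the model
    a_nonparents: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    diagnostics: dict = field(default_factory=dict)

    def all_ebv(self) -> pd.Series:
        return pd.concat([self.a, self.a_nonparents])

    def fixed_value(self, level: str) -> float:
        return float(self.b.get(level, 0.0))


def build_fixed_design(
    phenos: pd.DataFrame, fixed_factors: Sequence[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Cell-means design for the combined fixed factor.

    The listed columns are fused into one factor (e.g. hatch within
    generation).  Full dummy coding of the combined factor is full rank, so
    no explicit identifiability constraint is needed; estimable contrasts
    match any other parameterization.  Returns (X, level labels, per-record
    level index).
    """
    n = len(phenos)
    if not fixed_factors:
        return np.ones((n, 1)), ["(mean)"], np.zeros(n, dtype=int)
    combined = phenos[list(fixed_factors)].astype(str).agg(":".join, axis=1)
    levels = sorted(combined.unique())
    lut = {lev: k for k, lev in enumerate(levels)}
    idx = combined.map(lut).to_numpy()
    X = np.zeros((n, len(levels)))
    X[np.arange(n), idx] = 1.0
    return X, levels, idx


def trait_records(phenos: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    if trait is not None and "trait" in phenos.columns:
        phenos = phenos[phenos["trait"] == trait]
    if phenos.empty:
        raise RamDesignError(f"no phenotype records for trait {trait!r}")
    return phenos.reset_index(drop=True)


def build_ram_design(
    ped: Pedigree,
    phenos: pd.DataFrame,
    partition: IndividualPartition,
    fixed_factors: Sequence[str] = ("generation", "hatch"),
    trait: str | None = None,
) -> RamDesign:
    """Assemble the RAM incidence structures for one trait.

    Records on genotyped individuals get a P-row; records on non-genotyped
    individuals get 1/2 at the sire and dam columns and the heterogeneous
    residual class.  A non-genotyped record whose sire or dam is not
    genotyped cannot be absorbed and raises, naming the individual.
    """
    phenos = trait_records(phenos, trait)
    genotyped = sorted(partition.genotyped)
    gidx = {iid: j for j, iid in enumerate(genotyped)}
    X, levels, _ = build_fixed_design(phenos, fixed_factors)
    y = phenos["value"].to_numpy(dtype=float)
    ids = phenos["id"].astype(str).tolist()

    rows, cols, vals = [], [], []
    nongeno = np.zeros(len(ids), dtype=bool)
    record_parents: dict[str, tuple[str, str]] = {}
    for i, iid in enumerate(ids):
        if iid in gidx:
            rows.append(i)
            cols.append(gidx[iid])
            vals.append(1.0)
        else:
            if iid not in ped:
                raise RamDesignError(f"phenotyped individual {iid} not in pedigree")
            sire, dam = ped.parents(iid)
            if sire is None or dam is None:
                raise RamDesignError(
                    f"non-genotyped individual {iid} has unknown parents"
                )
            if sire not in gidx or dam not in gidx:
                raise RamDesignError(
                    f"non-genotyped individual {iid} has non-genotyped parent "
                    f"({sire if sire not in gidx else dam}); the reduced model "
                    "requires all parents genotyped"
                )
            nongeno[i] = True
            record_parents[iid] = (sire, dam)
            rows.extend([i, i])
            cols.extend([gidx[sire], gidx[dam]])
            vals.extend([0.5, 0.5])
    W = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(len(ids), len(genotyped)))
    )
    return RamDesign(
        y=y,
        X=X,
        fixed_levels=levels,
        W=W,
        genotyped_ids=genotyped,
        record_ids=ids,
        nongenotyped=nongeno,
        record_parents=record_parents,
    )


def _min_eig(V: np.ndarray) -> float:
    return float(linalg.eigvalsh(V, subset_by_index=[0, 0])[0])


def solve_ram(
    design: RamDesign,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    method: str = "auto",
    cg_tol: float = 1e-10,
) -> MmeSolution:
    """Solve the RAM mixed-model equations.

    Coefficient matrix::

        [ X'R^-1 X   X'R^-1 W                      ] [b]   [X'R^-1 y]
        [ W'R^-1 X   W'R^-1 W + K^-1 / sigma_a^2   ] [a] = [W'R^-1 y]

    with R diagonal: sigma_e^2 for genotyped-record rows and
    sigma_e^2 + 1/2 sigma_a^2 for non-genotyped rows.  Direct dense solve
    up to 5,000 equations, preconditioned CG above.  A singular K (the
    centered genomic G always has the all-ones vector in its null space)
    is handled exactly by premultiplying the animal equations by K
    (Henderson's form for singular covariance), avoiding any ridge.
    """
    if list(K.labels) != list(design.genotyped_ids):
        K = K.submatrix(design.genotyped_ids)
    X, W, y = design.X, design.W, design.y
    r = np.where(
        design.nongenotyped, vc.sigma_e2 + 0.5 * vc.sigma_a2, vc.sigma_e2
    )
    Ri = 1.0 / r
    Kv = np.array(K.values, dtype=float)
    min_eig = _min_eig(Kv)
    singular = min_eig < 1e-8

    XtRi = X.T * Ri
    WtRi = W.T.multiply(Ri)
    Cxx = XtRi @ X
    Cxw = np.asarray(XtRi @ W)
    Cww_data = (WtRi @ W).toarray()
    nf = X.shape[1]
    p = W.shape[1]
    n_eq = nf + p
    diagnostics: dict = {"n_equations": n_eq, "k_min_eig": min_eig}
    if method == "auto":
        method = "dense" if n_eq <= 5000 else "cg"

    if singular:
        logger.info(
            "relationship matrix singular (min eig %.3e); using K-premultiplied "
            "non-symmetric MME",
            min_eig,
        )
        C = np.block(
            [
                [Cxx, Cxw],
                [Kv @ Cxw.T, Kv @ Cww_data + np.eye(p) / vc.sigma_a2],
            ]
        )
        rhs = np.concatenate([XtRi @ y, Kv @ (WtRi @ y)])
        try:
            sol = linalg.solve(C, rhs)
        except linalg.LinAlgError as exc:
            raise RamDesignError(
                f"singular MME coefficient matrix ({n_eq} equations): {exc}"
            ) from exc
        diagnostics["solver"] = "lu_singular_k"
    else:
        Kinv = linalg.inv(Kv) / vc.sigma_a2
        C = np.block([[Cxx, Cxw], [Cxw.T, Cww_data + Kinv]])
        rhs = np.concatenate([XtRi @ y, WtRi @ y])
        if method == "dense":
            try:
                cf = linalg.cho_factor(C)
                sol = linalg.cho_solve(cf, rhs)
            except linalg.LinAlgError as exc:
                raise RamDesignError(
                    f"singular MME coefficient matrix ({n_eq} equations): {exc}"
                ) from exc
            diagnostics["solver"] = "cholesky"
        else:
            from scipy.sparse.linalg import cg

            M = sparse.diags(1.0 / np.maximum(np.diag(C), 1e-12))
            sol, info = cg(sparse.csr_matrix(C), rhs, rtol=cg_tol, M=M, maxiter=50_000)
            if info != 0:
                raise RamDesignError(f"CG failed to converge (info={info})")
            diagnostics["solver"] = "cg"

    b = pd.Series(sol[:nf], index=design.fixed_levels, name="b_hat")
    a = pd.Series(sol[nf:], index=design.genotyped_ids, name="ebv")
    return MmeSolution(b=b, a=a, diagnostics=diagnostics)


def backsolve_nonparents(
    sol: MmeSolution,
    design: RamDesign,
    ped: Pedigree,
    vc: VarianceComponents,
    extra_ids: Sequence[str] = (),
) -> MmeSolution:
    """Recover EBV of non-genotyped individuals from the RAM solution.

    With a record: a_i = PA_i + k (y_i - x_i'b - PA_i) where PA is the
    parent average and k = (1/2 sigma_a^2) / (1/2 sigma_a^2 + sigma_e^2)
    is the regression of the Mendelian sampling deviation on the record
    deviation.  Without a record: a_i = PA_i.
    """
    k = (0.5 * vc.sigma_a2) / (0.5 * vc.sigma_a2 + vc.sigma_e2)
    X = design.X
    out = {}
    for i, iid in enumerate(design.record_ids):
        if not design.nongenotyped[i]:
            continue
        sire, dam = design.record_parents[iid]
        pa = 0.5 * (sol.a[sire] + sol.a[dam])
        xb = float(X[i] @ sol.b.to_numpy())
        out[iid] = pa + k * (design.y[i] - xb - pa)
    for iid in extra_ids:
        if iid in out or iid in sol.a.index:
            continue
        sire, dam = ped.parents(iid)
        if sire is None or dam is None or sire not in sol.a.index or dam not in sol.a.index:
            raise RamDesignError(
                f"cannot backsolve {iid}: parents unknown or without EBV"
            )
        out[iid] = 0.5 * (sol.a[sire] + sol.a[dam])
    return MmeSolution(
        b=sol.b,
        a=sol.a,
        a_nonparents=pd.Series(out, dtype=float, name="ebv"),
        diagnostics=dict(sol.diagnostics),
    )


def fit_full_animal_model(
    ped: Pedigree,
    phenos: pd.DataFrame,
    vc: VarianceComponents,
    fixed_factors: Sequence[str] = ("generation", "hatch"),
    trait: str | None = None,
) -> MmeSolution:
    """Single-trait animal model with all observations and full pedigree
    relationships (sparse A-inverse); homogeneous residual variance.

    Used for Bayes-C-pi pre-adjustment and as the structural oracle for
    the reduced model.
    """
    phenos = trait_records(phenos, trait)
    missing = set(phenos["id"].astype(str)) - set(ped.ids)
    if missing:
        raise RamDesignError(f"phenotyped ids not in pedigree: {sorted(missing)[:5]}")
    X, levels, _ = build_fixed_design(phenos, fixed_factors)
    y = phenos["value"].to_numpy(dtype=float)
    n_ind = len(ped)
    ids = phenos["id"].astype(str).tolist()
    rows = np.arange(len(ids))
    cols = np.array([ped.index(i) for i in ids])
    Z = sparse.csr_matrix(
        (np.ones(len(ids)), (rows, cols)), shape=(len(ids), n_ind)
    )
    Ainv = a_inverse(ped)
    lam = vc.sigma_e2 / vc.sigma_a2
    Xs = sparse.csr_matrix(X)
    C = sparse.bmat(
        [
            [Xs.T @ Xs, Xs.T @ Z],
            [Z.T @ Xs, Z.T @ Z + Ainv * lam],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = spsolve(C, rhs)
    nf = X.shape[1]
    return MmeSolution(
        b=pd.Series(sol[:nf], index=levels, name="b_hat"),
        a=pd.Series(sol[nf:], index=ped.ids, name="ebv"),
        diagnostics={"n_equations": C.shape[0], "solver": "sparse_direct"},
    )


# ---------------------------------------------------------------------------
# EM-REML on the marginal covariance  Var(y) = K_y sigma_a^2 + I sigma_e^2
# ---------------------------------------------------------------------------


def ram_marginal_relationship(design: RamDesign, K: RelationshipMatrix) -> np.ndarray:
    """Relationship structure of the records implied by the RAM:
    K_y = W K_par W' + 1/2 diag(non-genotyped), so that
    Var(y) = K_y sigma_a^2 + I sigma_e^2."""
    if list(K.labels) != list(design.genotyped_ids):
        K = K.submatrix(design.genotyped_ids)
    W = design.W
    Ky = np.asarray((W @ K.values) @ W.T.toarray())
    Ky[np.diag_indices_from(Ky)] += 0.5 * design.nongenotyped
    return Ky


class RemlBasis:
    """Error-contrast eigenbasis for two-variance REML.

    Projects y onto an orthonormal basis of the complement of col(X) and
    diagonalizes the projected relationship matrix once; every EM-REML
    iteration is then O(n).  Reusable across replicate response vectors
    sharing the same X and K_y.
    """

    def __init__(self, X: np.ndarray, Ky: np.ndarray):
        B = linalg.null_space(X.T)  # n x (n - rank X), orthonormal
        H = B.T @ Ky @ B
        lam, V = linalg.eigh(H)
        self.lam = np.clip(lam, 0.0, None)
        self.T = B @ V  # y -> contrasts: w = T' y

    def transform(self, y: np.ndarray) -> np.ndarray:
        return self.T.T @ y


def em_reml(
    y: np.ndarray,
    X: np.ndarray | None = None,
    Ky: np.ndarray | None = None,
    basis: RemlBasis | None = None,
    start: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VarianceComponents:
    """EM-REML for (sigma_a^2, sigma_e^2) in Var(y) = Ky sa2 + I se2.

    Iterates the expectation-maximization updates in the error-contrast
    eigenbasis until the relative change in both components is below
    ``tol`` or ``max_iter`` iterations; non-convergence is flagged on the
    result, not raised.
    """
    if basis is None:
        if X is None or Ky is None:
            raise ValueError("provide either a RemlBasis or X and Ky")
        basis = RemlBasis(np.asarray(X, dtype=float), np.asarray(Ky, dtype=float))
    w = basis.transform(np.asarray(y, dtype=float))
    lam = basis.lam
    n = w.size
    pos = lam > 1e-10
    m = int(pos.sum())
    if m < 1:
        raise ValueError("genetic variance not identifiable: K_y projects to zero")

    var_w = float(np.var(w))
    sa2, se2 = start if start is not None else (0.5 * var_w, 0.5 * var_w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = lam * sa2 + se2
        h = lam * sa2 / v
        u_hat = h * w
        c = h * se2  # posterior variance of u_i (= lam sa2 se2 / v)
        sa2_new = float(np.sum((u_hat[pos] ** 2 + c[pos]) / lam[pos]) / m)
        se2_new = float(np.sum((w - u_hat) ** 2 + c) / n)
        sa2_new = max(sa2_new, 1e-12)
        se2_new = max(se2_new, 1e-12)
        if (
            abs(sa2_new - sa2) < tol * max(sa2, 1e-12)
            and abs(se2_new - se2) < tol * max(se2, 1e-12)
        ):
            sa2, se2 = sa2_new, se2_new
            converged = True
            break
        sa2, se2 = sa2_new, se2_new
    return VarianceComponents(
        sigma_a2=sa2, sigma_e2=se2, converged=converged, n_iter=it
    )


# ---------------------------------------------------------------------------
# Model objects
# ---------------------------------------------------------------------------


def _format_summary(title: str, blocks: list[tuple[str, pd.Series | pd.DataFrame]]) -> str:
    lines = [title, "=" * len(title)]
    for name, obj in blocks:
        lines.append("")
        lines.append(name)
        lines.append("-" * len(name))
        lines.append(obj.to_string())
    return "\n".join(lines)


@dataclass
class RamResults:
    """Fitted reduced-animal-model results.

    ``ebv`` concatenates EBV of genotyped individuals (solved directly)
    and backsolved EBV of non-genotyped individuals.
    """

    model: "ReducedAnimalModel"
    solution: MmeSolution
    vc: VarianceComponents

    @property
    def fixed_effects(self) -> pd.Series:
        return self.solution.b

    @property
    def ebv(self) -> pd.Series:
        return self.solution.all_ebv()

    @property
    def ebv_genotyped(self) -> pd.Series:
        return self.solution.a

    @property
    def ebv_backsolved(self) -> pd.Series:
        return self.solution.a_nonparents

    def write_solutions(self, path) -> None:
        rows = [
            {"id": lev, "effect_type": "fixed", "level_or_id": lev, "estimate": v}
            for lev, v in self.solution.b.items()
        ]
        for iid, v in self.ebv.items():
            rows.append(
                {"id": iid, "effect_type": "ebv", "level_or_id": iid, "estimate": v}
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        sol = self.solution
        info = pd.Series(
            {
                "kind": self.model.relationship.kind,
                "records": self.model.design.n_records,
                "genotyped": len(sol.a),
                "backsolved": len(sol.a_nonparents),
                "sigma_a2": round(self.vc.sigma_a2, 6),
                "sigma_e2": round(self.vc.sigma_e2, 6),
                "h2": round(self.vc.h2, 4),
            }
        )
        ebv = self.ebv
        stats = pd.Series(
            {
                "mean": ebv.mean(),
                "sd": ebv.std(),
                "min": ebv.min(),
                "max": ebv.max(),
            }
        ).round(6)
        return _format_summary(
            "Reduced animal model results",
            [
                ("Model", info),
                ("Fixed effects", sol.b.round(6)),
                ("EBV distribution", stats),
            ],
        )


class ReducedAnimalModel:
    """Reduced animal model for a single trait.

    Parameters
    ----------
    phenotypes : DataFrame with columns id, value, plus the fixed factors
        (and optionally a ``trait`` column filtered by ``trait``).
    pedigree : validated Pedigree.
    relationship : pedigree-A or genomic-G RelationshipMatrix whose labels
        cover the genotyped individuals.
    genotyped : ids treated as genotyped; defaults to the relationship
        matrix labels.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        relationship: RelationshipMatrix,
        genotyped: set[str] | None = None,
        fixed_factors: Sequence[str] = ("generation", "hatch"),
        trait: str | None = None,
    ):
        self.pedigree = pedigree
        self.relationship = relationship
        self.fixed_factors = tuple(fixed_factors)
        self.trait = trait
        phenotypes = trait_records(phenotypes, trait)
        self.phenotypes = phenotypes
        if genotyped is None:
            genotyped = set(relationship.labels)
        self.partition = partition_individuals(
            pedigree, genotyped, set(phenotypes["id"].astype(str))
        )
        if relationship.kind == "genomic_G" and self.partition.nongenotyped_parents:
            raise RamDesignError(
                "RAM-GBLUP requires all parents genotyped; missing genotypes for "
                f"{sorted(self.partition.nongenotyped_parents)[:5]}"
            )
        self.design = build_ram_design(
            pedigree, phenotypes, self.partition, fixed_factors
        )

    @classmethod
    def from_dataframes(cls, phenotypes, pedigree_df, relationship, **kw):
        return cls(phenotypes, Pedigree.from_frame(pedigree_df), relationship, **kw)

    def estimate_variances(self, **kw) -> VarianceComponents:
        """EM-REML on the RAM marginal covariance."""
        Ky = ram_marginal_relationship(self.design, self.relationship)
        return em_reml(self.design.y, X=self.design.X, Ky=Ky, **kw)

    def fit(
        self,
        vc: VarianceComponents | None = None,
        backsolve: bool = True,
        method: str = "auto",
    ) -> RamResults:
        if vc is None:
            vc = self.estimate_variances()
        sol = solve_ram(self.design, self.relationship, vc, method=method)
        if backsolve:
            sol = backsolve_nonparents(sol, self.design, self.pedigree, vc)
        return RamResults(model=self, solution=sol, vc=vc)


@dataclass
class AnimalModelResults:
    model: "AnimalModel"
    solution: MmeSolution
    vc: VarianceComponents

    @property
    def fixed_effects(self) -> pd.Series:
        return self.solution.b

    @property
    def ebv(self) -> pd.Series:
        return self.solution.a

    def summary(self) -> str:
        info = pd.Series(
            {
                "records": len(self.model.phenotypes),
                "individuals": len(self.solution.a),
                "sigma_a2": round(self.vc.sigma_a2, 6),
                "sigma_e2": round(self.vc.sigma_e2, 6),
                "h2": round(self.vc.h2, 4),
            }
        )
        return _format_summary(
            "Animal model results",
            [("Model", info), ("Fixed effects", self.solution.b.round(6))],
        )


class AnimalModel:
    """Full single-trait animal model over the complete pedigree."""

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        fixed_factors: Sequence[str] = ("generation", "hatch"),
        trait: str | None = None,
    ):
        self.pedigree = pedigree
        self.fixed_factors = tuple(fixed_factors)
        self.trait = trait
        self.phenotypes = trait_records(phenotypes, trait)

    def estimate_variances(self, **kw) -> VarianceComponents:
        """EM-REML using pedigree relationships among phenotyped animals."""
        from .pedigree import numerator_relationship

        ids = self.phenotypes["id"].astype(str).tolist()
        A = numerator_relationship(self.pedigree).submatrix(ids)
        X, _, _ = build_fixed_design(self.phenotypes, self.fixed_factors)
        return em_reml(
            self.phenotypes["value"].to_numpy(dtype=float), X=X, Ky=A.values, **kw
        )

    def fit(self, vc: VarianceComponents | None = None) -> AnimalModelResults:
        if vc is None:
            vc = self.estimate_variances()
        sol = fit_full_animal_model(
            self.pedigree, self.phenotypes, vc, self.fixed_factors
        )
        return AnimalModelResults(model=self, solution=sol, vc=vc)
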