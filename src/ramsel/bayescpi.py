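"""Bayes-C-pi: Bayesian variable selection for SNP effects.

Each SNP effect is zero with probability pi and otherwise drawn from a
normal with a common variance sigma_alpha^2; pi has a uniform (0,1) prior
and the two variances have scaled inverse chi-square priors.  A single-site
Gibbs sampler cycles over SNP inclusion indicators and effects (effect
integrated out of the inclusion full conditional, computed in log space),
then the common effect variance, the residual variance, and
pi ~ Beta(n_snp - m + 1, m + 1) given the model size m.

Training units are either genotyped individuals with their own centered
genotype and pre-adjusted phenotype, or parent pairs whose average
genotype carries the pre-adjusted mean phenotype of their non-genotyped
progeny; progeny-mean records get residual weight
w_p = p (1 - h^2) / (1 - 0.5 h^2), so that a record's residual variance is
sigma_e^2 / w_p (at p = 1 this equals the reduced-model non-genotyped
residual class sigma_e^2 + 1/2 sigma_a^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .grm import GenotypeMatrix
from .pedigree import IndividualPartition, Pedigree
from .ram import MmeSolution, build_fixed_design

__all__ = [
    "TrainingRecord",
    "McmcConfig",
    "ChainResult",
    "preadjust_phenotypes",
    "weight_progeny_mean",
    "build_training_records",
    "gebv_from_effects",
    "BayesCPi",
    "BayesCPiResults",
    "two_chain_pi_diagnostics",
]


@dataclass
class TrainingRecord:
    """One training unit for the sampler.

    ``covariates`` is the centered SNP coding: the unit's own genotype for
    genotyped individuals (p_count = 1, weight 1) or the average parental
    genotype for a family of non-genotyped progeny.
    """

    unit_id: str
    covariates: np.ndarray
    response: float
    p_count: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("record weight must be positive")
        if self.p_count < 1:
            raise ValueError("p_count must be >= 1")


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs chain settings and priors.

    ``scale_a``/``scale_e`` default to values making the prior mean of the
    total marker variance (resp. residual variance) match the supplied
    ``genetic_variance``/``residual_variance`` given the starting pi.
    ``fix_pi``, ``fix_effect_variance`` and ``fix_indicators`` freeze parts
    of the sampler for diagnostics and equivalence checks.
    """

    chain_length: int = 160_000
    burn_in: int = 50_000
    thinning: int = 10
    seed: int = 0
    pi_start: float = 0.5
    nu_a: float = 4.2
    scale_a: float | None = None
    nu_e: float = 4.2
    scale_e: float | None = None
    genetic_variance: float | None = None
    residual_variance: float | None = None
    fix_pi: float | None = None
    fix_effect_variance: float | None = None
    fix_residual_variance: float | None = None
    fix_indicators: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.pi_start < 1:
            raise ValueError("pi_start must be in (0, 1)")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")


def preadjust_phenotypes(
    phenos: pd.DataFrame,
    full_am_solution: MmeSolution,
    fixed_factors: Sequence[str] = ("generation", "hatch"),
) -> pd.DataFrame:
    """Subtract fixed-effect solutions of the full animal model:
    y* = y - x'b_hat.  Adds columns ``ystar`` and ``adjusted_level``."""
    phenos = phenos.reset_index(drop=True)
    X, levels, idx = build_fixed_design(phenos, fixed_factors)
    unknown = set(np.array(levels)[np.unique(idx)]) - set(full_am_solution.b.index)
    if unknown:
        raise KeyError(
            f"records with fixed-effect levels missing from the model solution: "
            f"{sorted(unknown)[:5]}"
        )
    b = full_am_solution.b.reindex(levels).to_numpy()
    out = phenos.copy()
    out["ystar"] = phenos["value"].to_numpy(dtype=float) - b[idx]
    out["adjusted_level"] = np.array(levels)[idx]
    return out


def weight_progeny_mean(p: int, h2: float, literal: bool = False) -> float:
    """Residual weight for a mean of p progeny records.

    w_p = p (1 - h^2) / (1 - 0.5 h^2); the record's residual variance in
    the sampler is sigma_e^2 / w_p, which for p = 1 equals
    sigma_e^2 + 1/2 sigma_a^2 (the non-genotyped residual class).  The
    alternative literal reading 1 - h^2 (1 - 0.5 h^2) / p is available for
    comparison via ``literal=True``.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if literal:
        return 1.0 - h2 * (1.0 - 0.5 * h2) / p
    return p * (1.0 - h2) / (1.0 - 0.5 * h2)


def build_training_records(
    ped: Pedigree,
    partition: IndividualPartition,
    adjusted: pd.DataFrame,
    genotypes: GenotypeMatrix,
    freqs: pd.Series,
    h2: float,
    per_progeny: bool = False,
) -> list[TrainingRecord]:
    """Assemble sampler training units from pre-adjusted phenotypes.

    Genotyped phenotyped individuals contribute their own centered genotype
    with weight 1.  Non-genotyped phenotyped individuals are grouped by
    parent pair; each family contributes the average parental genotype with
    the family mean of y* and weight w_p (or, with ``per_progeny=True``,
    one record per progeny with p = 1 weights).
    """
    p2 = 2.0 * freqs.to_numpy()
    records: list[TrainingRecord] = []
    own = adjusted[adjusted["id"].isin(partition.genotyped)]
    for r in own.itertuples(index=False):
        z = np.asarray(genotypes.row(r.id), dtype=float) - p2
        records.append(TrainingRecord(str(r.id), z, float(r.ystar), 1, 1.0))

    rest = adjusted[~adjusted["id"].isin(partition.genotyped)]
    fams: dict[tuple[str, str], list[float]] = {}
    for r in rest.itertuples(index=False):
        sire, dam = ped.parents(str(r.id))
        if sire is None or dam is None:
            raise ValueError(f"non-genotyped individual {r.id} has unknown parents")
        if sire not in genotypes or dam not in genotypes:
            raise ValueError(
                f"non-genotyped individual {r.id} has a non-genotyped parent"
            )
        if per_progeny:
            z = 0.5 * (
                np.asarray(genotypes.row(sire), dtype=float)
                + np.asarray(genotypes.row(dam), dtype=float)
            ) - p2
            records.append(
                TrainingRecord(
                    str(r.id), z, float(r.ystar), 1, weight_progeny_mean(1, h2)
                )
            )
        else:
            fams.setdefault((sire, dam), []).append(float(r.ystar))
    for (sire, dam), ys in fams.items():
        z = 0.5 * (
            np.asarray(genotypes.row(sire), dtype=float)
            + np.asarray(genotypes.row(dam), dtype=float)
        ) - p2
        p = len(ys)
        records.append(
            TrainingRecord(
                f"{sire}x{dam}", z, float(np.mean(ys)), p, weight_progeny_mean(p, h2)
            )
        )
    return records


def gebv_from_effects(
    genotypes: GenotypeMatrix, effects: pd.Series, freqs: pd.Series
) -> pd.Series:
    """Linear score: EBV_i = sum_j (g_ij - 2 p_j) effect_j with the
    training centering."""
    if list(effects.index) != list(genotypes.snp_labels):
        missing = set(effects.index) ^ set(genotypes.snp_labels)
        raise KeyError(f"SNP sets differ between genotypes and effects: {sorted(missing)[:5]}")
    Z = np.asarray(genotypes.calls, dtype=float) - 2.0 * freqs.to_numpy()
    return pd.Series(
        Z @ effects.to_numpy(), index=genotypes.individual_labels, name="gebv"
    )


@njit(cache=True)
def _gibbs_kernel(
    ZT,  # (m, n) C-order: SNP-major covariates
    y,
    w,
    n_iter,
    burn_in,
    thin,
    seed,
    pi_start,
    nu_a,
    scale_a,
    nu_e,
    scale_e,
    fix_pi,  # < 0 => free
    fix_sa,  # <= 0 => free
    fix_se,  # <= 0 => free
    freeze,  # 1 => indicators frozen at delta0
    delta0,
):
    np.random.seed(seed)
    m, n = ZT.shape
    alpha = np.zeros(m)
    delta = delta0.copy()
    pi = pi_start if fix_pi < 0 else fix_pi
    sa2 = scale_a if fix_sa <= 0 else fix_sa
    se2 = scale_e if fix_se <= 0 else fix_se
    mu = 0.0
    e = y.copy()
    sw = w.sum()
    c = np.zeros(m)  # sum_i w_i z_ij^2
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += w[i] * ZT[j, i] * ZT[j, i]
        c[j] = s

    n_keep = n_iter - burn_in
    n_store = n_keep // thin
    pi_store = np.zeros(n_store)
    sa_store = np.zeros(n_store)
    se_store = np.zeros(n_store)
    ms_store = np.zeros(n_store)
    effect_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    pi_sum = 0.0
    pi_sumsq = 0.0
    mu_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # intercept
        e += mu
        num = 0.0
        for i in range(n):
            num += w[i] * e[i]
        mu = num / sw + np.random.normal(0.0, 1.0) * np.sqrt(se2 / sw)
        e -= mu

        msize = 0
        for j in range(m):
            if delta[j] == 1:
                for i in range(n):
                    e[i] += ZT[j, i] * alpha[j]
            # r = sum w z e / se2 ; cprec = c_j / se2
            r = 0.0
            for i in range(n):
                r += w[i] * ZT[j, i] * e[i]
            r /= se2
            cprec = c[j] / se2
            v = 1.0 / (cprec + 1.0 / sa2)
            if freeze == 1:
                include = delta[j] == 1
            elif pi <= 0.0:
                include = True
            elif pi >= 1.0:
                include = False
            else:
                log_lr = 0.5 * (np.log(v) - np.log(sa2)) + 0.5 * r * r * v
                logit = log_lr + np.log(1.0 - pi) - np.log(pi)
                if logit > 35.0:
                    include = True
                elif logit < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-logit))
            if include:
                alpha[j] = v * r + np.random.normal(0.0, 1.0) * np.sqrt(v)
                delta[j] = 1
                msize += 1
                for i in range(n):
                    e[i] -= ZT[j, i] * alpha[j]
            else:
                alpha[j] = 0.0
                delta[j] = 0

        if fix_sa <= 0:
            ssa = nu_a * scale_a
            for j in range(m):
                if delta[j] == 1:
                    ssa += alpha[j] * alpha[j]
            sa2 = ssa / np.random.chisquare(nu_a + msize)
        if fix_se <= 0:
            sse = nu_e * scale_e
            for i in range(n):
                sse += w[i] * e[i] * e[i]
            se2 = sse / np.random.chisquare(nu_e + n)
        if fix_pi < 0:
            g1 = np.random.gamma(m - msize + 1.0, 1.0)
            g2 = np.random.gamma(msize + 1.0, 1.0)
            pi = g1 / (g1 + g2)

        if it >= burn_in:
            effect_sum += alpha
            for j in range(m):
                incl_sum[j] += delta[j]
            pi_sum += pi
            pi_sumsq += pi * pi
            mu_sum += mu
            if (it - burn_in) % thin == 0 and kept < n_store:
                pi_store[kept] = pi
                sa_store[kept] = sa2
                se_store[kept] = se2
                ms_store[kept] = msize
                kept += 1

    return (
        effect_sum / n_keep,
        incl_sum / n_keep,
        pi_sum / n_keep,
        pi_sumsq / n_keep,
        mu_sum / n_keep,
        pi_store,
        sa_store,
        se_store,
        ms_store,
    )


@dataclass
class ChainResult:
    """Posterior summaries and thinned samples from one Gibbs chain."""

    pi_mean: float
    pi_sd: float
    effects: pd.Series  # posterior mean effect per SNP (trait units/allele)
    inclusion: pd.Series  # posterior inclusion frequency per SNP
    intercept: float
    samples: pd.DataFrame  # thinned: pi, sigma_alpha2, sigma_e2, model_size
    config: McmcConfig

    @property
    def mean_model_size(self) -> float:
        return float(self.samples["model_size"].mean())

    def to_json_dict(self) -> dict:
        return {
            "pi_mean": self.pi_mean,
            "pi_sd": self.pi_sd,
            "mean_model_size": self.mean_model_size,
            "intercept": self.intercept,
            "n_snps": int(len(self.effects)),
            "chain_length": self.config.chain_length,
            "burn_in": self.config.burn_in,
            "seed": self.config.seed,
        }


@dataclass
class BayesCPiResults:
    """Fitted-model results wrapping the chain output."""

    model: "BayesCPi"
    chain: ChainResult

    @property
    def effects(self) -> pd.Series:
        return self.chain.effects

    @property
    def pi(self) -> float:
        return self.chain.pi_mean

    def gebv(self, genotypes: GenotypeMatrix, freqs: pd.Series) -> pd.Series:
        """GEBV for (validation) individuals from their own centered
        genotypes and the posterior-mean effects."""
        return gebv_from_effects(genotypes, self.chain.effects, freqs)

    def summary(self) -> str:
        ch = self.chain
        info = pd.Series(
            {
                "records": len(self.model.y),
                "snps": len(ch.effects),
                "chain_length": ch.config.chain_length,
                "burn_in": ch.config.burn_in,
                "pi_mean": round(ch.pi_mean, 4),
                "pi_sd": round(ch.pi_sd, 4),
                "mean_model_size": round(ch.mean_model_size, 1),
                "sigma_alpha2": round(float(ch.samples["sigma_alpha2"].mean()), 6),
                "sigma_e2": round(float(ch.samples["sigma_e2"].mean()), 6),
            }
        )
        title = "Bayes-C-pi results"
        return "\n".join(
            [title, "=" * len(title), info.to_string()]
        )


class BayesCPi:
    """Bayes-C-pi model over a training design (records x SNPs).

    Construct from explicit arrays or with :meth:`from_records` /
    :meth:`from_data`; ``fit`` runs the Gibbs sampler and returns
    :class:`BayesCPiResults`.
    """

    def __init__(
        self,
        Z: np.ndarray,
        y: np.ndarray,
        weights: np.ndarray | None = None,
        snp_labels: Sequence[str] | None = None,
        unit_ids: Sequence[str] | None = None,
    ):
        self.Z = np.ascontiguousarray(np.asarray(Z, dtype=float))
        self.y = np.asarray(y, dtype=float)
        n, m = self.Z.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 records and 1 SNP")
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        self.snp_labels = (
            [f"snp{j}" for j in range(m)] if snp_labels is None else list(snp_labels)
        )
        self.unit_ids = (
            [str(i) for i in range(n)] if unit_ids is None else list(unit_ids)
        )

    @classmethod
    def from_records(cls, records: list[TrainingRecord], snp_labels=None) -> "BayesCPi":
        Z = np.stack([r.covariates for r in records])
        y = np.array([r.response for r in records])
        w = np.array([r.weight for r in records])
        return cls(Z, y, w, snp_labels=snp_labels, unit_ids=[r.unit_id for r in records])

    @classmethod
    def from_data(
        cls,
        ped: Pedigree,
        partition: IndividualPartition,
        adjusted: pd.DataFrame,
        genotypes: GenotypeMatrix,
        freqs: pd.Series,
        h2: float,
        per_progeny: bool = False,
    ) -> "BayesCPi":
        records = build_training_records(
            ped, partition, adjusted, genotypes, freqs, h2, per_progeny
        )
        return cls.from_records(records, snp_labels=list(genotypes.snp_labels))

    def _resolve_scales(self, config: McmcConfig) -> McmcConfig:
        vy = float(np.var(self.y))
        if vy == 0.0:  # degenerate response; keep priors proper
            vy = 1.0
        va = config.genetic_variance if config.genetic_variance is not None else 0.5 * vy
        ve = (
            config.residual_variance
            if config.residual_variance is not None
            else 0.5 * vy
        )
        updates = {}
        if config.scale_a is None:
            # prior mean of sigma_alpha^2, nu S/(nu-2), set so the expected
            # total marker variance (1-pi0) * sum_j var(z_j) * sigma_alpha^2
            # matches the genetic variance
            sum_var = float(np.sum(np.var(self.Z, axis=0)))
            sum_var = max(sum_var, 1e-12)
            target = va / max((1.0 - config.pi_start) * sum_var, 1e-12)
            updates["scale_a"] = target * (config.nu_a - 2.0) / config.nu_a
        if config.scale_e is None:
            updates["scale_e"] = ve * (config.nu_e - 2.0) / config.nu_e
        return replace(config, **updates) if updates else config

    def fit(self, config: McmcConfig = McmcConfig(), seed: int | None = None) -> BayesCPiResults:
        config = self._resolve_scales(config)
        if seed is not None:
            config = replace(config, seed=seed)
        m = self.Z.shape[1]
        if config.fix_indicators is not None:
            delta0 = np.asarray(config.fix_indicators, dtype=np.int64)
            if delta0.size != m:
                raise ValueError("fix_indicators length must equal SNP count")
            freeze = 1
        else:
            delta0 = np.zeros(m, dtype=np.int64)
            freeze = 0
        ZT = np.ascontiguousarray(self.Z.T)
        out = _gibbs_kernel(
            ZT,
            self.y,
            self.weights,
            config.chain_length,
            config.burn_in,
            max(config.thinning, 1),
            config.seed % (2**31),
            config.pi_start,
            config.nu_a,
            config.scale_a,
            config.nu_e,
            config.scale_e,
            -1.0 if config.fix_pi is None else float(config.fix_pi),
            -1.0 if config.fix_effect_variance is None else float(config.fix_effect_variance),
            -1.0 if config.fix_residual_variance is None else float(config.fix_residual_variance),
            freeze,
            delta0,
        )
        (
            eff_mean,
            incl,
            pi_mean,
            pi_msq,
            mu_mean,
            pi_s,
            sa_s,
            se_s,
            ms_s,
        ) = out
        pi_var = max(pi_msq - pi_mean**2, 0.0)
        samples = pd.DataFrame(
            {
                "pi": pi_s,
                "sigma_alpha2": sa_s,
                "sigma_e2": se_s,
                "model_size": ms_s,
            }
        )
        chain = ChainResult(
            pi_mean=float(pi_mean),
            pi_sd=float(np.sqrt(pi_var)),
            effects=pd.Series(eff_mean, index=self.snp_labels, name="effect"),
            inclusion=pd.Series(incl, index=self.snp_labels, name="inclusion"),
            intercept=float(mu_mean),
            samples=samples,
            config=config,
        )
        return BayesCPiResults(model=self, chain=chain)


def two_chain_pi_diagnostics(
    model: BayesCPi,
    config: McmcConfig = McmcConfig(),
    pi_low: float = 0.1,
    pi_high: float = 0.99,
    seeds: tuple[int, int] = (101, 202),
) -> dict:
    """Run two chains with low/high starting pi and compare posteriors.

    Chains that differ by more than their pooled posterior SDs are flagged
    as unconverged (flat-posterior architectures).
    """
    res_low = model.fit(replace(config, pi_start=pi_low, seed=seeds[0]))
    res_high = model.fit(replace(config, pi_start=pi_high, seed=seeds[1]))
    lo, hi = res_low.chain, res_high.chain
    pooled_sd = float(np.sqrt(lo.pi_sd**2 + hi.pi_sd**2))
    diff = abs(lo.pi_mean - hi.pi_mean)
    return {
        "pi_low_start": {"mean": lo.pi_mean, "sd": lo.pi_sd},
        "pi_high_start": {"mean": hi.pi_mean, "sd": hi.pi_sd},
        "abs_difference": diff,
        "pooled_sd": pooled_sd,
        "converged": bool(diff <= max(pooled_sd, 1e-12)),
        "results": (res_low, res_high),
    }
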