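"""End-to-end generation-forward comparison of PBLUP, GBLUP and Bayes-C-pi.

Simulates (or receives) a multi-generation population, trains each
predictor on the early- or late-selection training set, predicts the
genotyped final-generation females, and scores accuracy, bias and top-k
means against hatch-corrected phenotypes.  This is the pipeline behind
the ``ramsel compare`` subcommand and the package's own headline checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayescpi import BayesCPi, McmcConfig, preadjust_phenotypes
from .grm import allele_frequencies, vanraden_grm
from .pedigree import numerator_relationship, partition_individuals
from .ram import AnimalModel, ReducedAnimalModel, VarianceComponents, fit_full_animal_model
from .simulate import Scenario, SimConfig, build_paper_like_scenario
from .validation import (
    EbvSet,
    ValidationReport,
    hatch_corrected_phenotypes,
    parental_average_ebv,
)

__all__ = ["ForwardValidation", "run_forward_validation", "run_method_comparison"]

FIXED = ("generation", "hatch")


@dataclass
class ForwardValidation:
    """EBV sets for the validation individuals plus the corrected
    phenotypes they are scored against."""

    scenario: Scenario
    trait: str
    h2: float
    ystar: pd.Series  # validation individuals only
    ebv_sets: dict[str, EbvSet]

    def report(self, k: int = 30, higher_is_better: bool = True) -> ValidationReport:
        sets = list(self.ebv_sets.values())
        pa_pair = None
        if "GBLUP" in self.ebv_sets and "GBLUP-PA" in self.ebv_sets:
            pa_pair = (self.ebv_sets["GBLUP"], self.ebv_sets["GBLUP-PA"])
        return ValidationReport.build(
            self.trait,
            self.h2,
            self.ystar,
            sets,
            k=min(k, max(3, len(self.ystar) // 2)),
            higher_is_better=higher_is_better,
            pa_pair=pa_pair,
        )


def run_forward_validation(
    scenario: Scenario,
    trait: str = "early",
    which: str = "early",
    methods: tuple[str, ...] = ("PBLUP", "GBLUP"),
    use_true_variances: bool = True,
    mcmc: dict | None = None,
    include_pa: bool = True,
) -> ForwardValidation:
    """Train each method on the scenario's training records and predict the
    validation individuals.

    Variance components default to the simulation's generative values
    (``use_true_variances=False`` estimates them by EM-REML on the
    training data).  Bayes-C-pi chains default to a desk-scale protocol
    (20,000 iterations, 5,000 burn-in) unless overridden via ``mcmc``.
    """
    sim = scenario.sim
    cfg = sim.config
    tcfg = next(t for t in cfg.traits if t.name == trait)
    train = scenario.training(which)
    train = train[train["trait"] == trait].reset_index(drop=True)
    val_ids = scenario.validation_ids

    geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
    geno = sim.genotypes.subset_individuals(geno_ids)
    freqs = allele_frequencies(geno)

    if use_true_variances:
        vc = VarianceComponents(tcfg.sigma_a2, tcfg.sigma_e2)
    else:
        vc = None  # each model estimates its own

    # hatch correction for validation: full animal model on all records
    all_recs = sim.phenotypes[sim.phenotypes["trait"] == trait].reset_index(drop=True)
    am_vc = vc if vc is not None else AnimalModel(
        all_recs, sim.pedigree, FIXED
    ).estimate_variances()
    full_sol = fit_full_animal_model(sim.pedigree, all_recs, am_vc, FIXED)
    ystar_all = hatch_corrected_phenotypes(all_recs, full_sol, FIXED)
    ystar = ystar_all[ystar_all.index.isin(val_ids)]

    ebv_sets: dict[str, EbvSet] = {}
    full_ebv: dict[str, EbvSet] = {}  # all genotyped animals, for PA
    for method in methods:
        if method == "PBLUP":
            K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        elif method == "GBLUP":
            K = vanraden_grm(geno, freqs)
        elif method == "BayesCPi":
            full = _fit_bayescpi(scenario, train, geno, freqs, tcfg, vc, mcmc or {})
            full_ebv[method] = full
            ebv_sets[method] = EbvSet(method, full.values[val_ids])
            continue
        else:
            raise ValueError(f"unknown method {method}")
        model = ReducedAnimalModel(
            train, sim.pedigree, K, genotyped=set(geno_ids), fixed_factors=FIXED
        )
        res = model.fit(vc if vc is not None else model.estimate_variances())
        full_ebv[method] = EbvSet(method, res.ebv_genotyped)
        ebv_sets[method] = EbvSet(method, res.ebv_genotyped[val_ids])

    if include_pa:
        for method in list(ebv_sets):
            ebv_sets[f"{method}-PA"] = parental_average_ebv(
                sim.pedigree, full_ebv[method], val_ids
            )
    return ForwardValidation(
        scenario=scenario,
        trait=trait,
        h2=tcfg.h2,
        ystar=ystar,
        ebv_sets=ebv_sets,
    )


def _fit_bayescpi(
    scenario: Scenario,
    train: pd.DataFrame,
    geno,
    freqs: pd.Series,
    tcfg,
    vc: VarianceComponents | None,
    mcmc: dict,
) -> EbvSet:
    sim = scenario.sim
    am = AnimalModel(train, sim.pedigree, FIXED)
    vc_t = vc if vc is not None else am.estimate_variances()
    am_res = am.fit(vc_t)
    adjusted = preadjust_phenotypes(train, am_res.solution, FIXED)
    partition = partition_individuals(
        sim.pedigree, set(geno.individual_labels), set(train["id"].astype(str))
    )
    model = BayesCPi.from_data(
        sim.pedigree, partition, adjusted, geno, freqs, vc_t.h2
    )
    defaults = dict(
        chain_length=20_000,
        burn_in=5_000,
        genetic_variance=vc_t.sigma_a2,
        residual_variance=vc_t.sigma_e2,
        seed=sim.config.seed + 7,
    )
    defaults.update(mcmc)
    res = model.fit(McmcConfig(**defaults))
    gebv = res.gebv(geno, freqs)  # all genotyped animals (parents included)
    return EbvSet("BayesCPi", gebv)


def run_method_comparison(
    sim_cfg: SimConfig,
    scenario: str = "early",
    trait: str = "early",
    methods: tuple[str, ...] = ("PBLUP", "GBLUP", "BayesCPi"),
    mcmc: dict | None = None,
    k: int = 30,
) -> ValidationReport:
    """Simulate one population and produce the joint validation report."""
    sc = build_paper_like_scenario(sim_cfg)
    fv = run_forward_validation(
        sc, trait=trait, which=scenario, methods=methods, mcmc=mcmc
    )
    tcfg = next(t for t in sim_cfg.traits if t.name == trait)
    return fv.report(k=k, higher_is_better=tcfg.direction > 0)
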