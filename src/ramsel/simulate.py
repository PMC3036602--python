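"""Breeding-population simulator: gene dropping with known truth.

Generates multi-generation layer-like populations with the structure the
reduced-animal-model analysis assumes: discrete generations, hierarchical
matings (each sire with several dams) avoiding full-sib pairs, hatch
fixed effects within generation, an early trait recorded on all females
and a late trait recorded only on selected females, all parents genotyped
plus a subset of final-generation females.  Genotypes descend from founder
haplotypes by Mendelian segregation with Haldane recombination (crossover
count Poisson in the chromosome length in Morgans; length 0 = unlinked).
True breeding values come from a configurable QTL architecture, so every
estimator in the package can be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix, MISSING
from .pedigree import Pedigree, PedigreeRecord

__all__ = [
    "TraitConfig",
    "SimConfig",
    "SimOutput",
    "simulate_founder_haplotypes",
    "meiosis",
    "gene_drop",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "select_parents",
    "make_matings",
    "simulate_population",
    "build_paper_like_scenario",
]


@dataclass(frozen=True)
class TraitConfig:
    """One simulated trait.

    ``recorded`` is "all_females" (early traits: measured on every hen) or
    "selected_females" (late traits: only hens kept after early selection
    ever express them).  ``direction`` is +1 when larger is better, -1 when
    smaller is better (e.g. age at sexual maturity).
    """

    name: str = "early"
    h2: float = 0.4
    n_qtl: int = 100
    phenotypic_variance: float = 1.0
    recorded: str = "all_females"
    direction: int = 1

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.phenotypic_variance

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.phenotypic_variance


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults emulate a five-generation brown-egg layer line: ~n_dams *
    progeny_per_dam female-and-male progeny per generation, hierarchical
    matings, five hatches per generation treated as fixed effects, and
    heritabilities in the moderate range typical of egg-quality traits.
    """

    n_generations: int = 5
    n_sires: int = 30
    n_dams: int = 300
    progeny_per_dam: int = 9
    n_snp: int = 5000
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0  # 0 => unlinked loci
    ancestral_pool: int | None = 50  # haplotype pool inducing founder LD; None = independent
    freq_range: tuple[float, float] = (0.05, 0.95)
    n_hatches: int = 5
    hatch_sd: float = 0.5
    traits: tuple[TraitConfig, ...] = (
        TraitConfig("early", h2=0.4, n_qtl=100, recorded="all_females"),
        TraitConfig("late", h2=0.3, n_qtl=100, recorded="selected_females"),
    )
    selection: str = "phenotype"  # or "random"
    selection_trait: str = "early"
    genotype_final_fraction: float = 0.15
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class SimOutput:
    """Simulated population with generative truth."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped individuals only
    phenotypes: pd.DataFrame  # id, trait, value, generation, hatch, sex
    tbv: pd.DataFrame  # index id, one column per trait
    qtl: dict[str, pd.DataFrame]  # per trait: snp index, label, effect
    founder_freqs: pd.Series
    selected: set[str]
    genotyped: set[str]
    all_haplotypes: np.ndarray | None = None  # (n_ind, 2, n_snp) int8

    def write(self, outdir) -> None:
        """Write the standard pedigree/genotype/phenotype files plus a
        truth file (id, TBV per trait, selected flag)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(out / "pedigree.csv")
        self.genotypes.write_csv(out / "genotypes.csv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        truth = self.tbv.copy()
        truth["selected"] = [i in self.selected for i in truth.index]
        truth.index.name = "id"
        truth.to_csv(out / "truth.tsv", sep="\t")
        with open(out / "simconfig.txt", "w") as fh:
            fh.write(repr(self.config) + "\n")


def _snp_map(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome assignment and position (Morgans) for each SNP."""
    chrom = np.repeat(np.arange(cfg.n_chromosomes), -(-cfg.n_snp // cfg.n_chromosomes))[
        : cfg.n_snp
    ]
    pos = np.zeros(cfg.n_snp)
    for c in range(cfg.n_chromosomes):
        idx = np.where(chrom == c)[0]
        if idx.size:
            pos[idx] = np.linspace(0, cfg.chrom_length_morgans, idx.size)
    return chrom, pos


def simulate_founder_haplotypes(
    cfg: SimConfig, n_founders: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes and the per-SNP frequencies they were drawn from.

    Per-SNP frequency ~ Uniform(freq_range); founder genotypes are
    Hardy-Weinberg unless an ancestral haplotype pool is configured, in
    which case founders draw whole haplotypes from the pool, creating
    linkage disequilibrium.
    """
    p = rng.uniform(*cfg.freq_range, size=cfg.n_snp)
    if cfg.ancestral_pool is None:
        hap = (rng.random((n_founders, 2, cfg.n_snp)) < p).astype(np.int8)
    else:
        pool = (rng.random((cfg.ancestral_pool, cfg.n_snp)) < p).astype(np.int8)
        picks = rng.integers(0, cfg.ancestral_pool, size=(n_founders, 2))
        hap = pool[picks]
    return hap, p


def meiosis(
    parent_hap: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's two haplotypes.

    Haldane model: the crossover count per chromosome is Poisson(length in
    Morgans) with uniform positions; length 0 means independent segregation
    of every locus.
    """
    n_snp = parent_hap.shape[1]
    if length <= 0:
        choose = rng.integers(0, 2, size=n_snp)
        return parent_hap[choose, np.arange(n_snp)]
    gamete = np.empty(n_snp, dtype=np.int8)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        start = rng.integers(0, 2)
        n_x = rng.poisson(length)
        if n_x == 0:
            phase = np.full(idx.size, start)
        else:
            xpos = np.sort(rng.uniform(0, length, size=n_x))
            phase = (start + np.searchsorted(xpos, pos[idx])) % 2
        gamete[idx] = parent_hap[phase, idx]
    return gamete


def gene_drop(
    ped: Pedigree,
    founder_haplotypes: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop founder haplotypes through the pedigree.

    Returns an (n_individuals, 2, n_snp) haplotype array in pedigree order;
    haplotype 0 is paternal, 1 maternal.  Founders (unknown parents) take
    rows of ``founder_haplotypes`` in order of appearance.
    """
    chrom, pos = _snp_map(cfg)
    n = len(ped)
    hap = np.zeros((n, 2, cfg.n_snp), dtype=np.int8)
    si, di = ped.parent_indices()
    f = 0
    for i in range(n):
        if si[i] < 0 and di[i] < 0:
            hap[i] = founder_haplotypes[f]
            f += 1
        else:
            # both-parent case is guaranteed by the simulator's pedigrees
            hap[i, 0] = meiosis(hap[si[i]], chrom, pos, cfg.chrom_length_morgans, rng)
            hap[i, 1] = meiosis(hap[di[i]], chrom, pos, cfg.chrom_length_morgans, rng)
    return hap


def assign_qtl_effects(
    cfg: TraitConfig, freqs: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample QTL positions and effects, rescaled so the expected founder
    additive variance sum_q 2 p_q (1-p_q) a_q^2 equals sigma_a^2 exactly."""
    n_snp = freqs.size
    if cfg.n_qtl > n_snp:
        raise ValueError("more QTL than SNPs")
    qtl = np.sort(rng.choice(n_snp, size=cfg.n_qtl, replace=False))
    a = rng.standard_normal(cfg.n_qtl)
    p = freqs[qtl]
    scale = np.sqrt(cfg.sigma_a2 / np.sum(2 * p * (1 - p) * a**2))
    return pd.DataFrame({"snp_index": qtl, "effect": a * scale})


def true_breeding_values(
    hap: np.ndarray, qtl: pd.DataFrame, freqs: np.ndarray
) -> np.ndarray:
    """TBV_i = sum_q (g_iq - 2 p_q) a_q (centered at founder frequencies)."""
    idx = qtl["snp_index"].to_numpy()
    g = hap[:, 0, idx].astype(float) + hap[:, 1, idx].astype(float)
    return (g - 2 * freqs[idx]) @ qtl["effect"].to_numpy()


def simulate_phenotypes(
    cohort: pd.DataFrame,
    tbv: np.ndarray,
    trait: TraitConfig,
    hatch_effects: dict[str, float],
    rng: np.random.Generator,
    record_mask: np.ndarray,
) -> pd.DataFrame:
    """Phenotype = hatch effect + TBV + N(0, sigma_e^2) for recorded rows."""
    noise = rng.normal(0, np.sqrt(trait.sigma_e2), size=len(cohort))
    y = np.array([hatch_effects[h] for h in cohort["hatch"]]) + tbv + noise
    out = cohort.loc[record_mask, ["id", "generation", "hatch", "sex"]].copy()
    out["trait"] = trait.name
    out["value"] = y[record_mask]
    return out[["id", "trait", "value", "generation", "hatch", "sex"]]


def select_parents(
    cohort: pd.DataFrame,
    scores: pd.Series | None,
    cfg: SimConfig,
    rng: np.random.Generator,
    allow_partial: bool = False,
) -> tuple[list[str], list[str]]:
    """Choose the next generation's sires and dams.

    Under phenotype selection, females rank on their own early-trait
    phenotype (direction-adjusted) and males on the mean phenotype of their
    full-sib females (sib-based male selection); under random selection
    both sexes are drawn uniformly.  ``allow_partial`` caps the counts at
    the number of candidates (used for the final generation, where the
    flags only mark who would have been kept).
    """
    males = cohort[cohort["sex"] == "M"]
    females = cohort[cohort["sex"] == "F"]
    n_sires, n_dams = cfg.n_sires, cfg.n_dams
    if len(males) < n_sires or len(females) < n_dams:
        if not allow_partial:
            raise ValueError(
                f"insufficient candidates: {len(males)} males / {len(females)} "
                f"females for {n_sires} sires / {n_dams} dams"
            )
        n_sires = min(n_sires, len(males))
        n_dams = min(n_dams, len(females))
    if cfg.selection == "random" or scores is None:
        sires = list(rng.choice(males["id"], size=n_sires, replace=False))
        dams = list(rng.choice(females["id"], size=n_dams, replace=False))
        return sires, dams
    fem_scores = females.set_index("id").join(scores.rename("score"))["score"]
    dams = list(fem_scores.sort_values(ascending=False).index[:n_dams])
    fam = females.set_index("id").join(scores.rename("score"))
    fam["family"] = fam["sire"] + "|" + fam["dam"]
    fam_mean = fam.groupby("family")["score"].mean()
    m = males.copy()
    m["family"] = m["sire"] + "|" + m["dam"]
    # unseen families (no phenotyped sisters) rank at the family-mean median
    m["score"] = m["family"].map(fam_mean).fillna(fam_mean.median() if len(fam_mean) else 0.0)
    m["tiebreak"] = rng.random(len(m))
    sires = list(
        m.sort_values(["score", "tiebreak"], ascending=False)["id"][:n_sires]
    )
    return sires, dams


def make_matings(
    sires: Sequence[str],
    dams: Sequence[str],
    parent_info: pd.DataFrame,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Hierarchical sire-by-dams matings avoiding full-sib pairs."""
    fam = {
        r.id: (r.sire, r.dam) for r in parent_info.itertuples(index=False)
    }
    dams = list(dams)
    rng.shuffle(dams)
    per_sire = -(-len(dams) // len(sires))
    load = {s: 0 for s in sires}
    pairs: list[tuple[str, str]] = []
    for dam in dams:
        placed = False
        for s in sorted(sires, key=lambda x: load[x]):
            if load[s] >= per_sire:
                continue
            if fam.get(s) is not None and fam.get(s) == fam.get(dam) and fam[s] != ("0", "0"):
                continue  # full sibs
            pairs.append((s, dam))
            load[s] += 1
            placed = True
            break
        if not placed:  # every eligible sire full; relax load cap
            s = min(sires, key=lambda x: load[x])
            if fam.get(s) == fam.get(dam) and fam[s] != ("0", "0"):
                s = next(
                    (t for t in sires if fam.get(t) != fam.get(dam)), s
                )
            pairs.append((s, dam))
            load[s] += 1
    return pairs


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Run the full breeding simulation.

    Generation 1 is a founder cohort; each later generation is produced by
    truncation-selected parents of the previous one.  Returns pedigree,
    genotypes of the genotyped set (all parents plus a fraction of
    final-generation females), phenotypes, true breeding values and the
    generative parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _snp_map(cfg)
    founders_n = cfg.n_sires + cfg.n_dams  # generation-0 breeding animals

    founder_hap, p = simulate_founder_haplotypes(cfg, founders_n, rng)
    qtl = {t.name: assign_qtl_effects(t, p, rng) for t in cfg.traits}

    records: list[PedigreeRecord] = []
    hap_list: list[np.ndarray] = []
    pheno_frames: list[pd.DataFrame] = []
    tbv_rows: dict[str, dict[str, float]] = {t.name: {} for t in cfg.traits}
    selected: set[str] = set()
    genotyped: set[str] = set()
    # per-trait hatch effects, drawn once per generation-hatch level
    hatch_fx = {
        t.name: {} for t in cfg.traits
    }  # type: dict[str, dict[str, float]]

    def new_cohort_frame(gen: int, parents: list[tuple[str, str]]) -> pd.DataFrame:
        rows = []
        i = 0
        for sire, dam in parents:
            for _ in range(cfg.progeny_per_dam):
                rows.append(
                    {
                        "id": f"G{gen}I{i:05d}",
                        "sire": sire,
                        "dam": dam,
                        "sex": "M" if i % 2 == 0 else "F",
                        "generation": gen,
                    }
                )
                i += 1
        df = pd.DataFrame(rows)
        df["hatch"] = [f"g{gen}h{i % cfg.n_hatches}" for i in range(len(df))]
        return df

    sel_trait = next(t for t in cfg.traits if t.name == cfg.selection_trait)
    hap_index: dict[str, int] = {}

    # generation 0: founder breeding animals (all genotyped, no records)
    founder_rows = []
    for i in range(founders_n):
        sex = "M" if i < cfg.n_sires else "F"
        iid = f"G0I{i:05d}"
        founder_rows.append(
            {"id": iid, "sire": "0", "dam": "0", "sex": sex,
             "generation": 0, "hatch": "g0h0"}
        )
        hap_list.append(founder_hap[i])
        hap_index[iid] = i
    founder_cohort = pd.DataFrame(founder_rows)
    records.extend(
        PedigreeRecord(r.id, r.sire, r.dam, r.sex, int(r.generation), r.hatch)
        for r in founder_cohort.itertuples(index=False)
    )
    founder_sires = founder_cohort[founder_cohort["sex"] == "M"]["id"].tolist()
    founder_dams = founder_cohort[founder_cohort["sex"] == "F"]["id"].tolist()
    selected.update(founder_sires)
    selected.update(founder_dams)
    genotyped.update(founder_sires)
    genotyped.update(founder_dams)
    founder_tbv = {
        t.name: true_breeding_values(founder_hap, qtl[t.name], p) for t in cfg.traits
    }
    for t in cfg.traits:
        for iid, v in zip(founder_cohort["id"], founder_tbv[t.name]):
            tbv_rows[t.name][iid] = v
    matings = make_matings(founder_sires, founder_dams, founder_cohort, rng)

    for gen in range(1, cfg.n_generations + 1):
        cohort = new_cohort_frame(gen, matings)
        n0 = len(hap_list)
        for r in cohort.itertuples(index=False):
            pat = meiosis(
                hap_list[hap_index[r.sire]], chrom, pos, cfg.chrom_length_morgans, rng
            )
            mat = meiosis(
                hap_list[hap_index[r.dam]], chrom, pos, cfg.chrom_length_morgans, rng
            )
            hap_list.append(np.stack([pat, mat]))
        for k, iid in enumerate(cohort["id"]):
            hap_index[iid] = n0 + k
        records.extend(
            PedigreeRecord(r.id, r.sire, r.dam, r.sex, int(r.generation), r.hatch)
            for r in cohort.itertuples(index=False)
        )

        cohort_hap = np.stack(hap_list[n0:])
        gen_tbv = {
            t.name: true_breeding_values(cohort_hap, qtl[t.name], p) for t in cfg.traits
        }
        for t in cfg.traits:
            for iid, v in zip(cohort["id"], gen_tbv[t.name]):
                tbv_rows[t.name][iid] = v

        # phenotypes: early traits now; late traits after selection flags known
        early_traits = [t for t in cfg.traits if t.recorded == "all_females"]
        late_traits = [t for t in cfg.traits if t.recorded == "selected_females"]
        gen_early: dict[str, pd.DataFrame] = {}
        for t in early_traits:
            for h in cohort["hatch"].unique():
                hatch_fx[t.name].setdefault(h, rng.normal(0, cfg.hatch_sd))
            mask = (cohort["sex"] == "F").to_numpy()
            frame = simulate_phenotypes(
                cohort, gen_tbv[t.name], t, hatch_fx[t.name], rng, mask
            )
            gen_early[t.name] = frame
            pheno_frames.append(frame)

        scores = None
        if cfg.selection == "phenotype" and sel_trait.name in gen_early:
            sc = gen_early[sel_trait.name]
            scores = pd.Series(
                sc["value"].to_numpy() * sel_trait.direction,
                index=sc["id"].to_numpy(),
            )
        sires, dams = select_parents(
            cohort, scores, cfg, rng, allow_partial=(gen == cfg.n_generations)
        )
        selected.update(sires)
        selected.update(dams)
        genotyped.update(sires)
        genotyped.update(dams)

        for t in late_traits:
            for h in cohort["hatch"].unique():
                hatch_fx[t.name].setdefault(h, rng.normal(0, cfg.hatch_sd))
            sel_f = cohort["id"].isin(set(dams)).to_numpy() & (
                cohort["sex"] == "F"
            ).to_numpy()
            pheno_frames.append(
                simulate_phenotypes(cohort, gen_tbv[t.name], t, hatch_fx[t.name], rng, sel_f)
            )

        if gen < cfg.n_generations:
            matings = make_matings(sires, dams, cohort, rng)
        else:
            # genotype a fraction of final-generation females (validation set)
            fem = cohort[cohort["sex"] == "F"]["id"].to_numpy()
            n_g = int(round(cfg.genotype_final_fraction * fem.size))
            genotyped.update(rng.choice(fem, size=n_g, replace=False))

    ped = Pedigree(records)
    hap = np.stack(hap_list)

    geno_ids = sorted(genotyped, key=ped.index)
    calls = np.array(
        [hap[hap_index[i], 0] + hap[hap_index[i], 1] for i in geno_ids], dtype=np.int8
    )
    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        calls = np.where(err, rng.integers(0, 3, size=calls.shape), calls).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)
    genotypes = GenotypeMatrix(geno_ids, [f"snp{j}" for j in range(cfg.n_snp)], calls)

    phenos = pd.concat(pheno_frames, ignore_index=True)
    tbv = pd.DataFrame(tbv_rows)
    tbv = tbv.loc[ped.ids]
    for t in cfg.traits:
        qtl[t.name]["snp"] = [f"snp{j}" for j in qtl[t.name]["snp_index"]]
    return SimOutput(
        config=cfg,
        pedigree=ped,
        genotypes=genotypes,
        phenotypes=phenos,
        tbv=tbv,
        qtl=qtl,
        founder_freqs=pd.Series(p, index=genotypes.snp_labels, name="p"),
        selected=selected,
        genotyped=genotyped,
        all_haplotypes=hap,
    )


def simulate_polygenic_tbv(
    ped: Pedigree, sigma_a2: float, rng: np.random.Generator
) -> pd.Series:
    """Infinitesimal-model breeding values down a pedigree (no markers).

    Founders ~ N(0, sigma_a2); progeny = parent average + Mendelian
    deviation N(0, 1/2 sigma_a2 (1 - (F_s + F_d)/2)).  Cheap generator for
    variance-component recovery studies on large pedigrees.
    """
    from .pedigree import inbreeding

    F = inbreeding(ped).to_numpy()
    si, di = ped.parent_indices()
    n = len(ped)
    tbv = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = si[i], di[i]
        if s < 0 and d < 0:
            tbv[i] = z[i] * np.sqrt(sigma_a2)
        else:
            pa = 0.0
            msv = sigma_a2  # variance of the sampled deviation
            if s >= 0 and d >= 0:
                pa = 0.5 * (tbv[s] + tbv[d])
                msv = 0.5 * sigma_a2 * (1 - 0.5 * (F[s] + F[d]))
            elif s >= 0:
                pa = 0.5 * tbv[s]
                msv = 0.75 * sigma_a2 * (1 - F[s] / 3)
            else:
                pa = 0.5 * tbv[d]
                msv = 0.75 * sigma_a2 * (1 - F[d] / 3)
            tbv[i] = pa + z[i] * np.sqrt(msv)
    return pd.Series(tbv, index=ped.ids, name="tbv")


@dataclass
class Scenario:
    """Generation-forward train/validation splits in the two study designs.

    Early selection: training uses all records up to the penultimate
    generation; validation individuals are the genotyped final-generation
    females.  Late selection: the final generation's non-genotyped female
    records (sibs of the validation individuals) are added to training;
    the validation set is unchanged.
    """

    sim: SimOutput
    validation_ids: list[str]
    train_early: pd.DataFrame
    train_late: pd.DataFrame

    def training(self, scenario: str) -> pd.DataFrame:
        if scenario == "early":
            return self.train_early
        if scenario == "late":
            return self.train_late
        raise ValueError("scenario must be 'early' or 'late'")


def build_paper_like_scenario(cfg: SimConfig) -> Scenario:
    if cfg.n_generations < 5:
        raise ValueError("study-like scenario needs at least 5 generations")
    sim = simulate_population(cfg)
    last = cfg.n_generations
    ph = sim.phenotypes
    final_f = {
        r.id
        for r in sim.pedigree.records
        if r.generation == last and r.sex == "F"
    }
    validation = sorted(final_f & sim.genotyped, key=sim.pedigree.index)
    train_early = ph[ph["generation"] < last].reset_index(drop=True)
    sib_mask = (
        (ph["generation"] == last)
        & ~ph["id"].isin(sim.genotyped)
        & (ph["sex"] == "F")
    )
    train_late = pd.concat(
        [train_early, ph[sib_mask]], ignore_index=True
    )
    return Scenario(
        sim=sim,
        validation_ids=validation,
        train_early=train_early,
        train_late=train_late,
    )
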