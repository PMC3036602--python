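"""Reduced-animal-model construction, solving, backsolution, EM-REML."""

import numpy as np
import pandas as pd
import pytest

from ramsel import (
    AnimalModel,
    Pedigree,
    ReducedAnimalModel,
    VarianceComponents,
    allele_frequencies,
    backsolve_nonparents,
    build_ram_design,
    em_reml,
    fit_full_animal_model,
    numerator_relationship,
    partition_individuals,
    solve_ram,
    vanraden_grm,
)
from ramsel.grm import center, vanraden_scale
from ramsel.ram import RamDesignError, RemlBasis, ram_marginal_relationship
from ramsel.simulate import (
    SimConfig,
    TraitConfig,
    simulate_polygenic_tbv,
    simulate_population,
)

from conftest import trio_frame

VC4 = VarianceComponents.from_h2(0.4)


def phenos_for(ids, values, gen=1, hatch="h0"):
    return pd.DataFrame(
        {"id": ids, "trait": "t", "value": values, "generation": gen, "hatch": hatch}
    )


class TestBuildDesign:
    def test_all_genotyped_collapses_to_animal_model(self, trio_pedigree):
        ph = phenos_for(["O"], [1.0])
        part = partition_individuals(trio_pedigree, {"S", "D", "O"}, {"O"})
        d = build_ram_design(trio_pedigree, ph, part)
        assert d.nongenotyped.sum() == 0
        assert d.W.toarray()[0, d.genotyped_ids.index("O")] == 1.0

    def test_nongenotyped_record_gets_half_at_parents(self, trio_pedigree):
        ph = phenos_for(["O"], [1.0])
        part = partition_individuals(trio_pedigree, {"S", "D"}, {"O"})
        d = build_ram_design(trio_pedigree, ph, part)
        row = d.W.toarray()[0]
        assert row[d.genotyped_ids.index("S")] == 0.5
        assert row[d.genotyped_ids.index("D")] == 0.5
        assert d.nongenotyped[0]

    def test_row_sums_are_one(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        part = partition_individuals(sim.pedigree, sim.genotyped, set(ph["id"]))
        d = build_ram_design(sim.pedigree, ph, part)
        assert np.allclose(np.asarray(d.W.sum(axis=1)).ravel(), 1.0)

    def test_nongenotyped_parent_raises_with_name(self, trio_pedigree):
        ph = phenos_for(["O"], [1.0])
        part = partition_individuals(trio_pedigree, {"D"}, {"O"})
        with pytest.raises(RamDesignError, match="S"):
            build_ram_design(trio_pedigree, ph, part)


class TestSolveRam:
    def test_single_record_mean_absorbs_everything(self, trio_pedigree):
        """One genotyped animal, one record, one fixed level: the level
        solution absorbs y and the EBV shrinks to zero."""
        from ramsel.pedigree import RelationshipMatrix

        ph = phenos_for(["O"], [3.7])
        part = partition_individuals(trio_pedigree, {"S", "D", "O"}, {"O"})
        d = build_ram_design(trio_pedigree, ph, part)
        K = numerator_relationship(trio_pedigree)
        sol = solve_ram(d, K, VC4)
        assert sol.b.iloc[0] == pytest.approx(3.7)
        assert np.allclose(sol.a.to_numpy(), 0.0, atol=1e-10)

    def test_matches_direct_mme_oracle(self, allgeno_fixture):
        """Small dense MME assembled independently gives the same solution."""
        fx = allgeno_fixture
        ids = fx["ped"].ids[:60]
        ph = fx["phenos"][fx["phenos"].id.isin(ids)]
        K = numerator_relationship(fx["ped"]).submatrix(ids)
        model = ReducedAnimalModel(ph, fx["ped"], K, genotyped=set(ids))
        sol = model.fit(VC4, backsolve=False)
        n = len(ids)
        y = ph.set_index("id").loc[ids, "value"].to_numpy()
        X = np.ones((n, 1))
        se, sa = VC4.sigma_e2, VC4.sigma_a2
        C = np.block(
            [
                [X.T @ X / se, X.T / se],
                [X / se, np.eye(n) / se + np.linalg.inv(K.values) / sa],
            ]
        )
        r = np.concatenate([X.T @ y / se, y / se])
        direct = np.linalg.solve(C, r)
        assert sol.fixed_effects.iloc[0] == pytest.approx(direct[0], rel=1e-9)
        assert np.allclose(sol.ebv_genotyped[ids].to_numpy(), direct[1:], atol=1e-9)

    def test_sire_with_progeny_only_matches_full_model(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        res = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        full = fit_full_animal_model(sim.pedigree, ph, VC4)
        # founder sires have no records: EBV comes entirely from progeny
        sires = [r.id for r in sim.pedigree.records if r.generation == 0 and r.sex == "M"]
        assert np.allclose(
            res.ebv_genotyped[sires].to_numpy(), full.a[sires].to_numpy(), atol=1e-10
        )

    def test_scale_equivariance(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"].copy()
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        base = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        c = 3.0
        ph2 = ph.copy()
        ph2["value"] = c * ph2["value"]
        vc2 = VarianceComponents(VC4.sigma_a2 * c**2, VC4.sigma_e2 * c**2)
        scaled = ReducedAnimalModel(ph2, sim.pedigree, K, genotyped=set(geno_ids)).fit(vc2)
        assert np.allclose(scaled.ebv.to_numpy(), c * base.ebv[scaled.ebv.index].to_numpy())

    def test_record_order_invariance(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        a = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        shuffled = ph.sample(frac=1.0, random_state=1)
        b = ReducedAnimalModel(shuffled, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        assert np.allclose(
            a.ebv.sort_index().to_numpy(), b.ebv.sort_index().to_numpy(), atol=1e-10
        )


class TestRamFullAmEquivalence:
    def test_pblup_solutions_identical(self, equiv_sim):
        """The reduced model with absorption must reproduce the full animal
        model exactly when all parents are genotyped and non-inbred."""
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        res = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        full = fit_full_animal_model(sim.pedigree, ph, VC4)
        scale = full.a.abs().max()
        diff = (res.ebv - full.a[res.ebv.index]).abs().max()
        assert diff / scale < 1e-8
        bdiff = (res.fixed_effects - full.b[res.fixed_effects.index]).abs().max()
        assert bdiff < 1e-8


class TestBacksolve:
    def test_zero_deviation_gives_parent_average(self, trio_pedigree):
        ph = phenos_for(["O"], [0.0])
        part = partition_individuals(trio_pedigree, {"S", "D"}, {"O"})
        d = build_ram_design(trio_pedigree, ph, part)
        K = numerator_relationship(trio_pedigree).submatrix(["D", "S"])
        sol = solve_ram(d, K, VC4)
        # construct record equal to x'b + parent average
        pa = 0.5 * (sol.a["S"] + sol.a["D"])
        ph2 = phenos_for(["O"], [sol.b.iloc[0] + pa])
        d2 = build_ram_design(trio_pedigree, ph2, part)
        sol2 = solve_ram(d2, K, VC4)
        aug = backsolve_nonparents(sol2, d2, trio_pedigree, VC4)
        pa2 = 0.5 * (sol2.a["S"] + sol2.a["D"])
        assert aug.a_nonparents["O"] == pytest.approx(pa2)

    def test_low_h2_limit_shrinks_to_parent_average(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        vc = VarianceComponents.from_h2(1e-6)
        res = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(vc)
        for iid in list(res.ebv_backsolved.index)[:10]:
            sire, dam = sim.pedigree.parents(iid)
            pa = 0.5 * (res.ebv_genotyped[sire] + res.ebv_genotyped[dam])
            assert res.ebv_backsolved[iid] == pytest.approx(pa, abs=1e-6)


class TestGblupSnpBlupEquivalence:
    def test_gebv_equal_ridge_regression_predictions(self, allgeno_fixture):
        fx = allgeno_fixture
        G, freqs, ped, ph = fx["G"], fx["freqs"], fx["ped"], fx["phenos"]
        K = vanraden_grm(G, freqs)
        ids = list(G.individual_labels)
        res = ReducedAnimalModel(ph, ped, K, genotyped=set(ids)).fit(VC4, backsolve=False)
        Z = center(G, freqs)
        lam = VC4.sigma_e2 / (VC4.sigma_a2 / vanraden_scale(freqs))
        n, m = Z.shape
        X = np.ones((n, 1))
        C = np.block(
            [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(m)]]
        )
        r = np.concatenate([X.T @ fx["y"], Z.T @ fx["y"]])
        alpha = np.linalg.solve(C, r)[1:]
        gebv = pd.Series(Z @ alpha, index=ids)
        scale = gebv.abs().max()
        assert (res.ebv_genotyped[ids] - gebv).abs().max() / scale < 1e-6


class TestFullAnimalModel:
    def test_balanced_unrelated_groups_recover_group_means(self):
        rng = np.random.default_rng(12)
        n = 40
        ids = [f"i{k}" for k in range(n)]
        ped = Pedigree.from_frame(
            pd.DataFrame(
                {
                    "id": ids,
                    "sire": "0",
                    "dam": "0",
                    "sex": ["M", "F"] * (n // 2),
                    "generation": 1,
                    "hatch": ["h0"] * (n // 2) + ["h1"] * (n // 2),
                }
            )
        )
        y = rng.normal(0, 1, n)
        ph = pd.DataFrame(
            {
                "id": ids,
                "trait": "t",
                "value": y,
                "generation": 1,
                "hatch": ["h0"] * (n // 2) + ["h1"] * (n // 2),
            }
        )
        sol = fit_full_animal_model(ped, ph, VC4)
        # unrelated animals: fixed solutions are shrunken toward group means;
        # with a balanced design the contrast matches the raw mean contrast
        assert sol.b["1:h0"] - sol.b["1:h1"] == pytest.approx(
            y[: n // 2].mean() - y[n // 2 :].mean(), rel=1e-6
        )

    def test_progeny_average_equals_parent_average_without_records(self, trio_pedigree):
        ph = phenos_for(["S", "D"], [1.0, -0.4])
        sol = fit_full_animal_model(trio_pedigree, ph, VC4)
        assert sol.a["O"] == pytest.approx(0.5 * (sol.a["S"] + sol.a["D"]))


class TestEmReml:
    def test_recovers_h2_on_structured_data(self):
        cfg = SimConfig(
            n_generations=2,
            n_sires=20,
            n_dams=100,
            progeny_per_dam=6,
            n_snp=100,
            chrom_length_morgans=0.0,
            ancestral_pool=None,
            traits=(TraitConfig("early", h2=0.5, n_qtl=60),),
            seed=13,
            hatch_sd=0.3,
        )
        sim = simulate_population(cfg)
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        vc = AnimalModel(ph, sim.pedigree).estimate_variances()
        assert vc.converged
        assert abs(vc.h2 - 0.5) < 0.12

    def test_pure_noise_drives_h2_to_boundary(self):
        """Family-structured data with no genetic signal: the additive
        variance heads to the zero boundary."""
        rng = np.random.default_rng(14)
        rows = []
        for fam in range(60):
            rows.append((f"s{fam}", "0", "0", "M"))
            rows.append((f"d{fam}", "0", "0", "F"))
            for k in range(6):
                rows.append((f"o{fam}_{k}", f"s{fam}", f"d{fam}", "F"))
        df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
        df["generation"] = 1
        df["hatch"] = "h0"
        ped = Pedigree.from_frame(df)
        prog = [i for i in ped.ids if i.startswith("o")]
        ph = phenos_for(prog, rng.normal(0, 1, len(prog)))
        vc = AnimalModel(ph, ped).estimate_variances()
        assert vc.h2 < 0.1

    def test_ram_and_full_model_reml_agree(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        ram = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids))
        vc_ram = ram.estimate_variances()
        vc_full = AnimalModel(ph, sim.pedigree).estimate_variances()
        assert vc_ram.sigma_a2 == pytest.approx(vc_full.sigma_a2, abs=5e-4)
        assert vc_ram.sigma_e2 == pytest.approx(vc_full.sigma_e2, abs=5e-4)

    def test_basis_reuse_matches_fresh_computation(self):
        rng = np.random.default_rng(15)
        n = 80
        M = rng.normal(size=(n, 2 * n))
        Ky = M @ M.T / (2 * n)
        X = np.ones((n, 1))
        y = rng.normal(0, 1, n)
        basis = RemlBasis(X, Ky)
        a = em_reml(y, X=X, Ky=Ky)
        b = em_reml(y, basis=basis)
        assert a.sigma_a2 == pytest.approx(b.sigma_a2)
        assert a.sigma_e2 == pytest.approx(b.sigma_e2)


class TestModelObjects:
    def test_summary_contains_key_quantities(self, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        res = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        text = res.summary()
        assert "Reduced animal model" in text
        assert "h2" in text and "EBV" in text

    def test_solution_file_roundtrip(self, tmp_path, equiv_sim):
        sim = equiv_sim
        ph = sim.phenotypes[sim.phenotypes.trait == "early"]
        geno_ids = sorted(sim.genotyped, key=sim.pedigree.index)
        K = numerator_relationship(sim.pedigree).submatrix(geno_ids)
        res = ReducedAnimalModel(ph, sim.pedigree, K, genotyped=set(geno_ids)).fit(VC4)
        path = tmp_path / "sol.tsv"
        res.write_solutions(path)
        df = pd.read_csv(path, sep="\t")
        ebv = df[df.effect_type == "ebv"].set_index("level_or_id")["estimate"]
        assert np.allclose(ebv[res.ebv.index].to_numpy(), res.ebv.to_numpy())
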