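"""SNP QC, allele frequencies, imputation and the VanRaden G."""

import numpy as np
import pandas as pd
import pytest

from ramsel import (
    GenotypeMatrix,
    Pedigree,
    QcThresholds,
    allele_frequencies,
    compare_relationships,
    impute_missing,
    load_genotypes,
    numerator_relationship,
    qc_filter,
    vanraden_grm,
    verify_parentage,
)
from ramsel.grm import MISSING, QcError, center, parent_mismatch_rates
from ramsel.simulate import SimConfig, TraitConfig, simulate_population

from conftest import trio_frame


def geno(ids, calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(ids, [f"s{j}" for j in range(calls.shape[1])], calls)


@pytest.fixture
def trio_geno():
    # SNP0 fine; SNP1 monomorphic; SNP2 opposing homozygotes in both trio pairs
    return geno(["S", "D", "O"], [[1, 2, 0], [1, 2, 0], [2, 2, 2]])


class TestQcFilter:
    def test_low_maf_removed_with_reason(self):
        calls = np.ones((40, 2), dtype=np.int8)
        calls[:, 0] = 0
        calls[0, 0] = 1  # MAF 1/80 = 0.0125 < 0.025
        G = geno([f"i{k}" for k in range(40)], calls)
        kept, report = qc_filter(G)
        assert report.fail_reason[0] == "maf"
        assert kept.snp_labels == ["s1"]

    def test_monomorphic_removed(self, trio_geno):
        ped = Pedigree.from_frame(trio_frame())
        kept, report = qc_filter(trio_geno, ped)
        assert report.fail_reason[1] == "maf"

    def test_opposing_homozygote_snp_removed(self, trio_geno):
        ped = Pedigree.from_frame(trio_frame())
        kept, report = qc_filter(trio_geno, ped)
        # SNP2: parents hom-alt, offspring hom-ref at s2? rates computed per pair
        assert report.mismatch_rate[2] == 1.0
        assert report.fail_reason[2] == "mismatch"
        assert "s2" not in kept.snp_labels

    def test_high_missingness_removed(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
        calls[:6, 0] = MISSING  # 10% missing > 5%
        G = geno([f"i{k}" for k in range(60)], calls)
        kept, report = qc_filter(G)
        assert report.fail_reason[0] == "miss"
        assert kept.snp_labels == ["s1"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, rng.uniform(0.01, 0.5, 30), size=(80, 30)).astype(np.int8)
        G = geno([f"i{k}" for k in range(80)], calls)
        once, r1 = qc_filter(G)
        twice, r2 = qc_filter(once)
        assert once.snp_labels == twice.snp_labels

    def test_all_fail_raises(self):
        G = geno(["a", "b"], [[0, 0], [0, 0]])
        with pytest.raises(QcError):
            qc_filter(G)


class TestAlleleFrequencies:
    def test_basic_and_edge_values(self):
        G = geno(["a", "b", "c"], [[0, 2], [1, 2], [2, 2]])
        p = allele_frequencies(G)
        assert p["s0"] == 0.5
        assert p["s1"] == 1.0

    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        G = geno([f"i{k}" for k in range(50)], calls)
        p = allele_frequencies(G)
        for j in range(20):
            col = calls[:, j]
            obs = col[col != MISSING]
            assert p.iloc[j] == pytest.approx(obs.sum() / (2 * len(obs)))

    def test_all_missing_snp_raises(self):
        calls = np.array([[1, MISSING], [1, MISSING]], dtype=np.int8)
        with pytest.raises(QcError):
            allele_frequencies(geno(["a", "b"], calls))


class TestImputeMissing:
    def test_no_missing_identity(self):
        G = geno(["a", "b"], [[0, 1], [2, 1]])
        out = impute_missing(G, allele_frequencies(G))
        assert np.array_equal(out.calls, G.calls)

    def test_missing_replaced_by_mean_dosage(self):
        calls = np.array([[0, 1], [2, MISSING], [1, 1]], dtype=np.int8)
        G = geno(["a", "b", "c"], calls)
        freqs = pd.Series([0.5, 0.5], index=["s0", "s1"])
        out = impute_missing(G, freqs)
        assert out.calls[1, 1] == 1.0

    def test_column_means_preserved(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(200, 30)).astype(np.int8)
        miss = rng.random(calls.shape) < 0.08
        observed_mean = np.array(
            [calls[~miss[:, j], j].mean() for j in range(30)]
        )
        calls_m = np.where(miss, MISSING, calls).astype(np.int8)
        G = geno([f"i{k}" for k in range(200)], calls_m)
        out = impute_missing(G, allele_frequencies(G))
        # mean imputation keeps observed column means exactly
        assert np.max(np.abs(out.calls.mean(axis=0) - (
            (1 - miss.mean(axis=0)) * observed_mean + miss.mean(axis=0) * observed_mean
        ))) < 1e-12


class TestVanRaden:
    def test_hand_computed_two_animal_example(self):
        G = geno(["a", "b"], [[0], [2]])
        freqs = pd.Series([0.5], index=["s0"])
        grm = vanraden_grm(G, freqs)
        assert np.allclose(grm.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_rows_give_identical_relationships(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        calls[1] = calls[0]
        G = geno([f"i{k}" for k in range(5)], calls)
        grm = vanraden_grm(G, allele_frequencies(G))
        assert np.allclose(grm.values[0], grm.values[1])
        assert np.allclose(grm.values, grm.values.T)

    def test_monomorphic_denominator_raises(self):
        G = geno(["a", "b"], [[2], [2]])
        with pytest.raises(QcError):
            vanraden_grm(G, pd.Series([1.0], index=["s0"]))

    def test_parent_offspring_mean_near_half(self):
        """Expected genomic relationship between parent and offspring is 0.5
        when G is built with founder allele frequencies."""
        cfg = SimConfig(
            n_generations=1,
            n_sires=30,
            n_dams=120,
            progeny_per_dam=2,
            n_snp=5000,
            chrom_length_morgans=0.0,
            ancestral_pool=None,
            traits=(TraitConfig("early", h2=0.4, n_qtl=50),),
            seed=5,
            genotype_final_fraction=1.0,
        )
        sim = simulate_population(cfg)
        grm = vanraden_grm(sim.genotypes, sim.founder_freqs)
        vals = []
        for r in sim.pedigree.records:
            if r.sire != "0" and r.id in sim.genotypes and r.sire in sim.genotypes:
                vals.append(grm.loc(r.id, r.sire))
        assert len(vals) > 100
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_founder_mean_diagonal_near_one(self):
        cfg = SimConfig(
            n_generations=1,
            n_sires=100,
            n_dams=100,
            progeny_per_dam=1,
            n_snp=5000,
            chrom_length_morgans=0.0,
            ancestral_pool=None,
            traits=(TraitConfig("early", h2=0.4, n_qtl=50),),
            seed=6,
        )
        sim = simulate_population(cfg)
        founders = [r.id for r in sim.pedigree.records if r.sire == "0"]
        sub = sim.genotypes.subset_individuals(
            [i for i in founders if i in sim.genotypes]
        )
        grm = vanraden_grm(sub, sim.founder_freqs)
        assert abs(np.diag(grm.values).mean() - 1.0) < 0.05


class TestCompareRelationships:
    def test_identity_and_scaling(self, equiv_sim):
        ped = equiv_sim.pedigree
        ids = sorted(equiv_sim.genotyped, key=ped.index)  # spans generations
        A = numerator_relationship(ped).submatrix(ids)
        same = compare_relationships(A, A)
        assert same["slope"] == pytest.approx(1.0)
        assert same["correlation"] == pytest.approx(1.0)
        from ramsel.pedigree import RelationshipMatrix

        doubled = RelationshipMatrix(list(A.labels), 2 * A.values, "genomic_G")
        assert compare_relationships(doubled, A)["slope"] == pytest.approx(2.0)

    def test_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(8)
        n = 12
        M = rng.normal(size=(n, n))
        A = (M + M.T) / 2
        B = 0.8 * A + rng.normal(0, 0.1, size=(n, n))
        B = (B + B.T) / 2
        from ramsel.pedigree import RelationshipMatrix

        ids = [f"i{k}" for k in range(n)]
        out = compare_relationships(
            RelationshipMatrix(ids, B, "genomic_G"),
            RelationshipMatrix(ids, A, "pedigree_A"),
        )
        iu = np.triu_indices(n, k=1)
        slope_or = np.polyfit(A[iu], B[iu], 1)[0]
        assert out["slope"] == pytest.approx(slope_or, abs=1e-12)
        assert out["n_pairs"] == n * (n - 1) // 2

    def test_g_on_a_regression_in_sanity_band(self):
        """Genomic on pedigree relationships regress near 1 over a
        multi-generation population with many unlinked SNPs."""
        cfg = SimConfig(
            n_generations=3,
            n_sires=10,
            n_dams=40,
            progeny_per_dam=4,
            n_snp=5000,
            chrom_length_morgans=0.0,
            ancestral_pool=None,
            traits=(TraitConfig("early", h2=0.4, n_qtl=50),),
            seed=9,
            genotype_final_fraction=0.5,
        )
        sim = simulate_population(cfg)
        ids = sorted(sim.genotyped, key=sim.pedigree.index)
        Gm = vanraden_grm(sim.genotypes.subset_individuals(ids), sim.founder_freqs)
        Am = numerator_relationship(sim.pedigree).submatrix(ids)
        out = compare_relationships(Gm, Am)
        assert 0.7 < out["slope"] < 1.2
        assert out["correlation"] > 0.5


class TestParentage:
    def test_wrong_parent_flagged(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.8, 500)
        sire = rng.binomial(2, p).astype(np.int8)
        dam = rng.binomial(2, p).astype(np.int8)
        # true offspring: one allele from each parent
        off = (
            (rng.random(500) < sire / 2).astype(np.int8)
            + (rng.random(500) < dam / 2).astype(np.int8)
        )
        stranger = rng.binomial(2, p).astype(np.int8)
        G = GenotypeMatrix(
            ["S", "D", "O", "W"],
            [f"s{j}" for j in range(500)],
            np.stack([sire, dam, off, stranger]),
        )
        df = pd.DataFrame(
            {
                "id": ["S", "D", "O", "W"],
                "sire": ["0", "0", "S", "S"],  # W falsely claims S
                "dam": ["0", "0", "D", "D"],
                "sex": ["M", "F", "F", "F"],
                "generation": [1, 1, 2, 2],
                "hatch": ["h"] * 4,
            }
        )
        ped = Pedigree.from_frame(df)
        rep = verify_parentage(G, ped)
        true_pairs = rep[rep.offspring == "O"]
        false_pairs = rep[rep.offspring == "W"]
        assert not true_pairs["flagged"].any()
        assert false_pairs["flagged"].all()


class TestLoadGenotypes:
    def test_csv_roundtrip(self, tmp_path):
        calls = np.array([[0, 1], [2, MISSING]], dtype=np.int8)
        G = geno(["a", "b"], calls)
        path = tmp_path / "geno.csv"
        G.write_csv(path)
        again = load_genotypes(path)
        assert again.individual_labels == ["a", "b"]
        assert np.array_equal(again.calls, calls)

    def test_plink_raw(self, tmp_path):
        path = tmp_path / "geno.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE snpA snpB\n"
            "f1 a 0 0 1 -9 0 2\n"
            "f1 b 0 0 2 -9 1 NA\n"
        )
        G = load_genotypes(path)
        assert G.individual_labels == ["a", "b"]
        assert G.snp_labels == ["snpA", "snpB"]
        assert G.calls[1, 1] == MISSING
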