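"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ramsel import GenotypeMatrix, Pedigree, allele_frequencies
from ramsel.simulate import SimConfig, TraitConfig, simulate_population


def trio_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ["S", "D", "O"],
            "sire": ["0", "0", "S"],
            "dam": ["0", "0", "D"],
            "sex": ["M", "F", "F"],
            "generation": [1, 1, 2],
            "hatch": ["h0", "h0", "h1"],
        }
    )


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.from_frame(trio_frame())


def random_pedigree(n: int, seed: int = 0) -> Pedigree:
    """Random valid pedigree: each non-founder draws parents from earlier
    individuals of the right sex (or founders)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sex = "M" if i % 2 == 0 else "F"
        sire = dam = "0"
        if i >= 10:
            males = [r["id"] for r in rows if r["sex"] == "M"]
            females = [r["id"] for r in rows if r["sex"] == "F"]
            if males and females and rng.random() < 0.9:
                sire = str(rng.choice(males))
                dam = str(rng.choice(females))
        rows.append(
            {
                "id": f"a{i:03d}",
                "sire": sire,
                "dam": dam,
                "sex": sex,
                "generation": 1 + i // 10,
                "hatch": f"h{i % 3}",
            }
        )
    return Pedigree.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def equiv_sim():
    """Two record cohorts over founder parents: every parent non-inbred, so
    reduced- and full-model solutions must agree exactly."""
    cfg = SimConfig(
        n_generations=2,
        n_sires=8,
        n_dams=30,
        progeny_per_dam=4,
        n_snp=400,
        n_chromosomes=4,
        traits=(TraitConfig("early", h2=0.4, n_qtl=20),),
        seed=11,
        genotype_final_fraction=0.3,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def allgeno_fixture():
    """Unrelated genotyped animals with a sparse-architecture trait; used
    for GBLUP/SNP-BLUP and sampler equivalences."""
    rng = np.random.default_rng(21)
    n, m = 150, 1000
    p = rng.uniform(0.1, 0.9, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    ids = [f"i{k:04d}" for k in range(n)]
    G = GenotypeMatrix(ids, [f"s{j}" for j in range(m)], calls)
    freqs = allele_frequencies(G)
    Z = calls.astype(float) - 2.0 * freqs.to_numpy()
    eff = rng.normal(0, 1, m) * (rng.random(m) < 0.05)
    g = Z @ eff
    g = g / g.std() * np.sqrt(0.4)
    y = g + rng.normal(0, np.sqrt(0.6), n)
    ped = Pedigree.from_frame(
        pd.DataFrame(
            {
                "id": ids,
                "sire": "0",
                "dam": "0",
                "sex": ["M", "F"] * (n // 2),
                "generation": 1,
                "hatch": "h0",
            }
        )
    )
    phenos = pd.DataFrame(
        {"id": ids, "trait": "t", "value": y, "generation": 1, "hatch": "h0"}
    )
    return {"G": G, "freqs": freqs, "Z": Z, "y": y, "ped": ped, "phenos": phenos}
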