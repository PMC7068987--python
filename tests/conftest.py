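import numpy as np
import pandas as pd
import pytest

from giltqg.pedigree_kinship import Pedigree, build_A
from giltqg.synthdata import SimConfig, TraitSpec, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """One small breed with a planted QTL window, reused across tests."""
    cfg = SimConfig(
        label="demo",
        n_sires=20,
        n_dams=60,
        generations=2,
        litter_size=10,
        n_chrom=5,
        n_markers=1000,
        traits={"y": TraitSpec(0.5, 0.05, 0.45)},
        n_qtl=2,
        qtl_total_share=0.5,
        qtl_window=(2, 50),
    )
    return simulate_population(cfg, seed=11)


@pytest.fixture(scope="session")
def small_A(small_population):
    return build_A(small_population.pedigree)


@pytest.fixture()
def tiny_genotypes():
    from giltqg.io_qc import GenotypeData

    mp = pd.DataFrame(
        {"chrom": [1, 1, 2], "pos": [100, 5000, 200]},
        index=pd.Index(["m1", "m2", "m3"], name="marker"),
    )
    calls = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float)
    return GenotypeData(samples=["a", "b", "c", "d"], markers=["m1", "m2", "m3"], calls=calls, map=mp)


def balanced_halfsib(seed, n_sires=50, n_daughters=20, h2=0.3, mu=10.0):
    """Balanced paternal half-sib design: unrelated founder sires, unknown
    dams, phenotypic variance 1."""
    rng = np.random.default_rng(seed)
    recs = [(f"S{i}", None, None) for i in range(n_sires)]
    rows = []
    for i in range(n_sires):
        a_s = rng.normal(0, np.sqrt(h2))
        for j in range(n_daughters):
            aid = f"D{i}_{j}"
            recs.append((aid, f"S{i}", None))
            bv = 0.5 * a_s + rng.normal(0, np.sqrt(0.75 * h2))
            rows.append((aid, f"S{i}", mu + bv + rng.normal(0, np.sqrt(1 - h2))))
    ped = Pedigree.from_records(recs)
    pheno = pd.DataFrame(rows, columns=["animal", "sire", "y"])
    return ped, pheno


def anova_h2(pheno, n_daughters):
    """Closed-form paternal half-sib estimator: 4 x intraclass correlation
    from the one-way ANOVA between/within sire mean squares."""
    g = pheno.groupby("sire")["y"]
    means = g.mean()
    grand = pheno["y"].mean()
    s = len(means)
    msb = n_daughters * ((means - grand) ** 2).sum() / (s - 1)
    msw = ((pheno["y"] - pheno["sire"].map(means)) ** 2).sum() / (len(pheno) - s)
    sigma_b = (msb - msw) / n_daughters
    t = sigma_b / (sigma_b + msw)
    return 4.0 * t
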