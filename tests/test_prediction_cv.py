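import warnings

import numpy as np
import pandas as pd
import pytest

from giltqg._design import FixedDesign
from giltqg.bayes_regression import ChainConfig, fit_bayes
from giltqg.gwas_windows import QTLRegion
from giltqg.pedigree_kinship import Pedigree
from giltqg.prediction_cv import (
    adjust_phenotypes,
    build_snp_sets,
    gpa_cv,
    gpa_single,
    make_folds,
    run_strategy,
)
from giltqg.synthdata import SimConfig, TraitSpec, simulate_population


def _pop(label="p", seed=0, qchrom=2, **kw):
    cfg = SimConfig(
        label=label, n_sires=20, n_dams=60, generations=2, litter_size=10,
        n_chrom=5, n_markers=800, traits={"y": TraitSpec(0.5, 0.05, 0.45)},
        n_qtl=2, qtl_total_share=0.6, qtl_window=(qchrom, 50), **kw,
    )
    return simulate_population(cfg, seed=seed)


@pytest.fixture(scope="module")
def pop():
    return _pop(seed=11)


class TestMakeFolds:
    def test_twenty_sires_five_per_fold_uses_all(self, pop):
        fa = make_folds(pop.phenotypes, pop.pedigree, n_folds=4, sires_per_fold=5, seed=1)
        assert fa.n_folds == 4
        assert sum(len(s) for s in fa.sires.values()) == 20
        assert set(fa.fold.index) == set(pop.phenotypes["animal"])

    def test_same_seed_reproduces_assignment(self, pop):
        fa1 = make_folds(pop.phenotypes, pop.pedigree, 4, 5, seed=9)
        fa2 = make_folds(pop.phenotypes, pop.pedigree, 4, 5, seed=9)
        assert fa1.fold.equals(fa2.fold)

    def test_sire_families_never_split(self, pop):
        for seed in range(3):
            fa = make_folds(pop.phenotypes, pop.pedigree, 3, 5, seed=seed)
            idx = pop.pedigree.index_of(fa.fold.index)
            sires = [pop.pedigree.ids[s] for s in pop.pedigree.sire[idx]]
            df = pd.DataFrame({"sire": sires, "fold": fa.fold.to_numpy()})
            assert (df.groupby("sire")["fold"].nunique() == 1).all()

    def test_unknown_sire_rejected(self):
        ped = Pedigree.from_records([("a", None, None)])
        pheno = pd.DataFrame({"animal": ["a"], "breed": ["x"], "y": [1.0]})
        with pytest.raises(ValueError, match="unknown sire"):
            make_folds(pheno, ped, 1, 1, seed=0)

    def test_too_few_sires_rejected(self, pop):
        with pytest.raises(ValueError, match="at least"):
            make_folds(pop.phenotypes, pop.pedigree, 10, 5, seed=0)


class TestAdjustPhenotypes:
    def test_zero_fixed_effects_identity(self):
        df = pd.DataFrame({"animal": ["a", "b"], "line": ["L1", "L1"], "cg": ["C1", "C1"],
                           "bw": [100.0, 100.0], "y": [3.0, 4.0]})
        design = FixedDesign().fit(df)
        est = pd.Series(0.0, index=design.names)
        out = adjust_phenotypes(df, "y", est, design)
        assert np.allclose(out.to_numpy(), df["y"])

    def test_hand_computed_three_records(self):
        df = pd.DataFrame({
            "animal": ["a", "b", "c"],
            "line": ["L1", "L2", "L1"],
            "cg": ["C1", "C1", "C2"],
            "bw": [100.0, 110.0, 120.0],
            "y": [10.0, 12.0, 14.0],
        })
        design = FixedDesign().fit(df)
        est = pd.Series({"mu": 1.0, "line[L2]": 0.5, "cg[C2]": -0.25, "bw": 0.1})
        out = adjust_phenotypes(df, "y", est, design)
        # centres at mean bw = 110
        expected = [10 - (1 + 0.1 * -10), 12 - (1 + 0.5), 14 - (1 - 0.25 + 0.1 * 10)]
        assert np.allclose(out.to_numpy(), expected)

    def test_unseen_level_warns_and_contributes_zero(self):
        train = pd.DataFrame({"animal": ["a"], "line": ["L1"], "cg": ["C1"], "bw": [100.0], "y": [1.0]})
        design = FixedDesign().fit(train)
        valid = pd.DataFrame({"animal": ["z"], "line": ["L9"], "cg": ["C1"], "bw": [100.0], "y": [2.0]})
        est = pd.Series({"mu": 1.0, "bw": 0.0})
        with pytest.warns(UserWarning, match="unseen"):
            out = adjust_phenotypes(valid, "y", est, design)
        assert out.iloc[0] == pytest.approx(1.0)


class TestGPAFormulas:
    def test_zero_correlation_gives_zero(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=50)
        y = g[::-1].copy()
        y = y - np.polyval(np.polyfit(g, y, 1), g)  # orthogonalise
        assert gpa_single(g, y, 0.25) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_can_exceed_one(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=30)
        assert gpa_single(g, g, 0.46) == pytest.approx(1.0 / np.sqrt(0.46))

    def test_half_correlation_quarter_h2(self):
        # r = 0.5 and h2 = 0.25 gives GPA exactly 1
        n = 10000
        rng = np.random.default_rng(2)
        g = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= np.polyval(np.polyfit(g, e, 1), g)
        y = g / np.std(g) + np.sqrt(3.0) * e / np.std(e)
        r = np.corrcoef(g, y)[0, 1]
        assert gpa_single(g, y, 0.25) == pytest.approx(r / 0.5)

    def test_zero_variance_gebv_flagged_missing(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = gpa_single(np.ones(5), np.arange(5.0), 0.5)
        assert np.isnan(out)

    def test_cv_weighted_average_fixture(self):
        gpa, sd = gpa_cv([(0.4, 100), (0.2, 50)], 0.25)
        assert gpa == pytest.approx((0.4 * 100 + 0.2 * 50) / 150 / 0.5, abs=1e-12)

    def test_cv_reduces_to_single_on_constant_folds(self):
        gpa, _ = gpa_cv([(0.3, 40), (0.3, 40), (0.3, 40)], 0.36)
        assert gpa == pytest.approx(0.3 / 0.6, abs=1e-12)

    def test_cv_permutation_invariant(self):
        folds = [(0.4, 100), (0.2, 50), (-0.1, 80)]
        g1, s1 = gpa_cv(folds, 0.25)
        g2, s2 = gpa_cv(folds[::-1], 0.25)
        assert g1 == pytest.approx(g2) and s1 == pytest.approx(s2)

    def test_single_fold_sd_missing(self):
        gpa, sd = gpa_cv([(0.4, 100)], 0.25)
        assert np.isnan(sd)


class TestSNPSets:
    def test_flank_exclusion_bounds(self, pop):
        mp = pop.genotypes.map
        region = QTLRegion(2, 50.0, 51.0, 1, 40.0, 1.0, 5)
        sets = build_snp_sets([region], mp, flank_mb=3.0)
        rest = sets["REST"].markers
        sub = mp.loc[rest]
        on2 = sub[sub["chrom"] == 2]
        mb = on2["pos"] / 1e6
        assert not ((mb >= 47.0) & (mb < 54.0)).any()

    def test_no_regions_gives_trivial_sets(self, pop):
        sets = build_snp_sets([], pop.genotypes.map, flank_mb=3.0)
        assert sets["QTL"].markers == []
        assert sets["REST"].markers == sets["ALL"].markers

    def test_sets_partition_all_markers(self, pop):
        mp = pop.genotypes.map
        regions = [QTLRegion(2, 50.0, 51.0, 1, 40.0, 1.0, 5), QTLRegion(4, 10.0, 12.0, 2, 8.0, 0.7, 9)]
        sets = build_snp_sets(regions, mp, flank_mb=3.0)
        qtl = set(sets["QTL"].markers)
        rest = set(sets["REST"].markers)
        allm = set(sets["ALL"].markers)
        flank_only = allm - qtl - rest
        assert qtl | rest | flank_only == allm
        assert not qtl & rest
        per = set()
        for k, s in sets.items():
            if k.startswith("per-QTL"):
                per |= set(s.markers)
        assert per == qtl

    def test_gebv_subset_linearity_through_sets(self, pop):
        cfg = ChainConfig(method="BayesB", pi=0.95, n_iter=600, n_burnin=150, seed=5,
                          var_genetic=0.5, var_residual=0.5)
        res = fit_bayes(pop.genotypes, pop.phenotypes, "y", cfg)
        mp = pop.genotypes.map
        sets = build_snp_sets([QTLRegion(2, 50.0, 51.0, 1, 40.0, 1.0, 5)], mp, flank_mb=3.0)
        flank_only = sorted(
            set(sets["ALL"].markers) - set(sets["QTL"].markers) - set(sets["REST"].markers)
        )
        total = (
            res.gebv(snp_set=sets["QTL"].markers).to_numpy()
            + res.gebv(snp_set=sets["REST"].markers).to_numpy()
            + res.gebv(snp_set=flank_only).to_numpy()
        )
        assert np.allclose(total, res.gebv().to_numpy(), atol=1e-12)


@pytest.fixture()
def chain():
    return ChainConfig(method="BayesB", pi=0.99, n_iter=800, n_burnin=200, seed=17,
                       var_genetic=0.5, var_residual=0.5)


class TestRunStrategy:

    def test_within_breed_finds_signal(self, pop, chain):
        fa = make_folds(pop.phenotypes, pop.pedigree, 4, 5, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_strategy("within", {"p": (pop.genotypes, pop.phenotypes)}, "y",
                               {"p": 0.5}, chain, folds={"p": fa})
        assert len(out) == 1
        assert out[0].gpa > 0.2
        assert len(out[0].fold_stats) == 4

    def test_between_breed_disjoint_qtl_near_zero(self, chain):
        a = _pop("a", seed=1, qchrom=1)
        b = _pop("b", seed=2, qchrom=4)
        breeds = {"a": (a.genotypes, a.phenotypes), "b": (b.genotypes, b.phenotypes)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_strategy("between", breeds, "y", {"a": 0.5, "b": 0.5}, chain,
                               validation_breed="a")
        assert abs(out[0].gpa) < 0.35
        assert np.isnan(out[0].sd)

    def test_multi_breed_fold_count_is_sum(self, pop, chain):
        b = _pop("b", seed=2, qchrom=4)
        breeds = {"p": (pop.genotypes, pop.phenotypes), "b": (b.genotypes, b.phenotypes)}
        folds = {
            "p": make_folds(pop.phenotypes, pop.pedigree, 2, 5, seed=1),
            "b": make_folds(b.phenotypes, b.pedigree, 3, 5, seed=1),
        }
        small = ChainConfig(method="BayesC", pi=0.99, n_iter=400, n_burnin=100, seed=3,
                            var_genetic=0.5, var_residual=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_strategy("multi", breeds, "y", {"p": 0.5, "b": 0.5}, small, folds=folds)
        by_breed = {r.validation_breed: r for r in out}
        assert len(by_breed["p"].fold_stats) + len(by_breed["b"].fold_stats) == 5

    def test_unknown_strategy_rejected(self, pop, chain):
        with pytest.raises(ValueError):
            run_strategy("leave-one-out", {}, "y", {}, chain)
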