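import numpy as np
import pandas as pd
import pytest

from giltqg.bayes_regression import (
    BayesAlphabet,
    ChainConfig,
    estimate_pi,
    fit_bayes,
    gebv_from_effects,
)
from giltqg.io_qc import GenotypeData
from giltqg.synthdata import SimConfig, TraitSpec, simulate_population


def _sim(seed=7, n_markers=200, share=0.4, sigma2_d=0.05, n_qtl=2, **kw):
    cfg = SimConfig(
        label="b",
        n_sires=10,
        n_dams=30,
        generations=2,
        litter_size=6,
        n_chrom=2,
        n_markers=n_markers,
        traits={"y": TraitSpec(0.5, sigma2_d, 0.5)},
        n_qtl=n_qtl,
        qtl_total_share=share,
        **kw,
    )
    return simulate_population(cfg, seed=seed)


@pytest.fixture(scope="module")
def sim():
    return _sim()


def _cfg(**kw):
    base = dict(
        method="BayesC",
        pi=0.9,
        n_iter=800,
        n_burnin=200,
        seed=13,
        var_genetic=0.5,
        var_residual=0.5,
    )
    base.update(kw)
    return ChainConfig(**base)


class TestChainConfig:
    def test_bayesc0_forces_pi_zero(self):
        assert ChainConfig(method="BayesC0", pi=0.7, var_genetic=1, var_residual=1).pi == 0.0

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            ChainConfig(method="BayesC", n_iter=100, n_burnin=100)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(method="BayesA")


class TestSampler:
    def test_chain_reproducible_bit_for_bit(self, sim):
        r1 = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg())
        r2 = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg())
        assert np.array_equal(r1.effects, r2.effects)
        assert np.array_equal(r1.sigma2_e, r2.sigma2_e)

    def test_indicator_zero_iff_effect_zero(self, sim):
        r = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(method="BayesB", pi=0.95))
        assert np.all((r.effects == 0.0) == (r.include == 0))

    def test_retained_draw_count_honours_thinning(self, sim):
        r = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(n_iter=900, n_burnin=300, thinning=3))
        assert r.n_draws == 200

    def test_pi_one_excludes_every_marker(self, sim):
        r = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(pi=1.0))
        assert np.all(r.effects == 0.0)
        assert np.allclose(r.gebv().to_numpy(), 0.0)

    def test_bayesc0_matches_closed_form_gblup(self, sim):
        cfg = _cfg(method="BayesC0", n_iter=3000, n_burnin=300)
        model = BayesAlphabet(sim.genotypes, sim.phenotypes, "y", cfg)
        res = model.fit()
        Z, W, y = model.Z, model.W, model.y
        het = float(np.sum(2 * model.p_train * (1 - model.p_train)))
        lam = cfg.var_residual / (cfg.var_genetic / het)
        p, m = W.shape[1], Z.shape[1]
        C = np.block([[W.T @ W, W.T @ Z], [Z.T @ W, Z.T @ Z + lam * np.eye(m)]])
        rhs = np.concatenate([W.T @ y, Z.T @ y])
        sol = np.linalg.solve(C + 1e-8 * np.eye(len(rhs)), rhs)
        gebv_mme = Z @ sol[p:]
        r = np.corrcoef(gebv_mme, res.gebv().to_numpy())[0, 1]
        assert r >= 0.98

    def test_planted_qtl_marker_gets_top_inclusion(self):
        hits = 0
        for seed in range(5):
            res = _sim(seed=seed, n_markers=500, share=0.5, qtl_window=(1, 30), n_qtl=1)
            r = fit_bayes(
                res.genotypes, res.phenotypes, "y",
                _cfg(method="BayesB", pi=0.99, n_iter=1200, n_burnin=300, seed=seed + 1),
            )
            freq = r.inclusion_frequency()
            top5 = set(freq.sort_values(ascending=False).head(5).index)
            if set(res.truth.qtl_markers) & top5:
                hits += 1
        assert hits >= 4

    def test_residual_variance_recovered_on_pure_noise(self):
        rng = np.random.default_rng(0)
        n, m = 150, 100
        mp = pd.DataFrame(
            {"chrom": np.ones(m, dtype=int), "pos": np.arange(1, m + 1) * 1000},
            index=pd.Index([f"m{j}" for j in range(m)], name="marker"),
        )
        g = GenotypeData(
            samples=[f"s{i}" for i in range(n)],
            markers=list(mp.index),
            calls=rng.integers(0, 3, size=(n, m)).astype(float),
            map=mp,
        )
        pheno = pd.DataFrame({"animal": g.samples, "y": rng.normal(0, 2.0, n)})
        r = fit_bayes(
            g, pheno, "y",
            _cfg(method="BayesC", pi=0.99, n_iter=2000, n_burnin=500, var_residual=4.0, var_genetic=0.5),
            fixed=(), covariates=(),
        )
        assert r.sigma2_e.mean() == pytest.approx(4.0, rel=0.10)

    def test_unmatched_animals_rejected(self, sim):
        bad = sim.phenotypes.copy()
        bad.loc[bad.index[0], "animal"] = "nobody"
        with pytest.raises(ValueError):
            fit_bayes(sim.genotypes.take_samples(sim.phenotypes["animal"].tolist()[1:]), bad, "y", _cfg())


class TestEstimatePi:
    def test_sparse_architecture_gives_pi_near_one(self):
        # two causal markers out of 200, no off-marker polygenic variance
        res = _sim(seed=7, share=1.0, sigma2_d=0.02)
        pi_hat, chain = estimate_pi(
            res.genotypes, res.phenotypes, "y",
            _cfg(method="BayesCpi", pi=0.5, n_iter=1500, n_burnin=300),
        )
        assert 0.85 <= pi_hat <= 1.0
        assert len(chain) == 1200

    def test_dense_strong_signal_gives_low_pi(self):
        # every marker causal, strong effects, n >> m
        rng = np.random.default_rng(5)
        n, m = 400, 30
        mp = pd.DataFrame(
            {"chrom": np.ones(m, dtype=int), "pos": np.arange(1, m + 1) * 1000},
            index=pd.Index([f"m{j}" for j in range(m)], name="marker"),
        )
        calls = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.normal(0, 1.0, m)
        y = (calls - calls.mean(0)) @ beta + rng.normal(0, 0.5, n)
        g = GenotypeData(samples=[f"s{i}" for i in range(n)], markers=list(mp.index), calls=calls, map=mp)
        pheno = pd.DataFrame({"animal": g.samples, "y": y})
        pi_hat, _ = estimate_pi(
            g, pheno, "y",
            _cfg(method="BayesCpi", pi=0.5, n_iter=1500, n_burnin=300,
                 var_genetic=float(np.var(y)) * 0.9, var_residual=0.25),
            fixed=(), covariates=(),
        )
        assert pi_hat < 0.5

    def test_requires_bayescpi_method(self, sim):
        with pytest.raises(ValueError):
            estimate_pi(sim.genotypes, sim.phenotypes, "y", _cfg(method="BayesC"))


class TestGEBV:
    def test_full_set_matches_chain_posterior_mean(self, sim):
        r = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg())
        full = r.gebv().to_numpy()
        via_effects = gebv_from_effects(
            r.posterior_mean_effects(), r._Z, markers=r.markers, samples=r.samples
        ).to_numpy()
        assert np.allclose(full, via_effects)
        assert np.allclose(full, r.gebv_draws().mean(axis=0))

    def test_zero_effects_give_zero_gebv(self, sim):
        eff = pd.Series(0.0, index=sim.genotypes.markers)
        out = gebv_from_effects(eff, sim.genotypes)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_disjoint_snp_sets_sum_to_full_gebv(self, sim):
        r = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(method="BayesB", pi=0.9))
        markers = r.markers
        half = len(markers) // 2
        g1 = r.gebv(snp_set=markers[:half]).to_numpy()
        g2 = r.gebv(snp_set=markers[half:]).to_numpy()
        assert np.allclose(g1 + g2, r.gebv().to_numpy(), atol=1e-12)

    def test_empty_snp_set_rejected(self, sim):
        with pytest.raises(ValueError, match="empty"):
            gebv_from_effects(pd.Series(0.0, index=sim.genotypes.markers), sim.genotypes, snp_set=[])


def test_bayesb_collapses_to_bayesc_distributionally(sim):
    """With a high effect-variance df the per-marker variances concentrate
    at the common prior scale, so BayesB's posterior summaries approach
    BayesC's on matched data."""
    kw = dict(pi=0.9, n_iter=2500, n_burnin=500)
    rb = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(method="BayesB", nu_effect=500.0, **kw))
    rc = fit_bayes(sim.genotypes, sim.phenotypes, "y", _cfg(method="BayesC", nu_effect=500.0, **kw))
    assert rb.sigma2_e.mean() == pytest.approx(rc.sigma2_e.mean(), rel=0.10)
    assert np.corrcoef(rb.gebv().to_numpy(), rc.gebv().to_numpy())[0, 1] > 0.95
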