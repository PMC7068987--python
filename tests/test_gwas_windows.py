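import numpy as np
import pandas as pd
import pytest

from giltqg.bayes_regression import BayesResults, ChainConfig, fit_bayes
from giltqg.gwas_windows import (
    QTLRegion,
    assign_windows,
    call_qtl,
    cross_trait_overlap,
    window_ppi,
    window_variance,
)


def _map(positions):
    return pd.DataFrame(
        {"chrom": [c for c, _ in positions], "pos": [p for _, p in positions]},
        index=pd.Index([f"m{i}" for i in range(len(positions))], name="marker"),
    )


class TestAssignWindows:
    def test_same_mb_bin_shares_window(self):
        mp = _map([(2, 154_000_001), (2, 154_999_999)])
        win = assign_windows(mp)
        assert win.iloc[0] == win.iloc[1] == (2, 154)

    def test_half_open_boundary_starts_new_window(self):
        mp = _map([(2, 154_999_999), (2, 155_000_000)])
        win = assign_windows(mp)
        assert win.iloc[0] == (2, 154) and win.iloc[1] == (2, 155)

    def test_windows_partition_markers(self):
        rng = np.random.default_rng(0)
        mp = _map(sorted((int(c), int(p)) for c, p in zip(rng.integers(1, 6, 200), rng.integers(1, int(1e8), 200))))
        win = assign_windows(mp)
        assert len(win) == 200
        assert win.groupby(win).size().sum() == 200
        # never spans chromosomes
        for (chrom, k), members in win.groupby(win):
            assert (mp.loc[members.index, "chrom"] == chrom).all()


def _fake_results(effects, include, Z, positions):
    """Hand-built minimal posterior for window computations."""
    mp = _map(positions)
    n_draws, m = effects.shape
    cfg = ChainConfig(method="BayesC", pi=0.5, n_iter=n_draws + 1, n_burnin=1,
                      var_genetic=1.0, var_residual=1.0)
    return (
        BayesResults(
            config=cfg,
            samples=[f"s{i}" for i in range(Z.shape[0])],
            markers=list(mp.index),
            effects=effects,
            include=include.astype(np.int8),
            fixed=np.zeros((n_draws, 1)),
            fixed_names=["mu"],
            sigma2_e=np.ones(n_draws),
            sigma2_b=np.ones(n_draws),
            pi=np.full(n_draws, 0.5),
            center_freqs=np.full(m, 0.5),
            design=None,
            _Z=Z,
        ),
        mp,
    )


class TestWindowVariance:
    def test_single_window_takes_all_variance(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(30, 4))
        eff = rng.normal(size=(120, 4))
        res, mp = _fake_results(eff, np.ones_like(eff), Z, [(1, 100 + i) for i in range(4)])
        out = window_variance(res, mp, min_draws=100)
        assert len(out) == 1
        assert out["tgvm_pct"].iloc[0] == pytest.approx(100.0)

    def test_tgvm_sums_to_hundred(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(40, 10))
        eff = rng.normal(size=(150, 10)) * (rng.random((150, 10)) < 0.4)
        pos = [(1, 500_000 * (i + 1)) for i in range(5)] + [(2, 300_000 * (i + 1)) for i in range(5)]
        res, mp = _fake_results(eff, (eff != 0), Z, pos)
        out = window_variance(res, mp, min_draws=100)
        assert out["tgvm_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_draw_matches_direct_variance_computation(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(25, 6))
        eff = np.tile(rng.normal(size=6), (100, 1))  # deterministic chain
        pos = [(1, 100), (1, 200), (1, 2_000_001), (1, 2_000_002), (3, 50), (3, 60)]
        res, mp = _fake_results(eff, np.ones_like(eff), Z, pos)
        out = window_variance(res, mp, min_draws=100)
        direct = []
        for cols in ([0, 1], [2, 3], [4, 5]):
            direct.append(np.var(Z[:, cols] @ eff[0, cols]))
        direct = 100 * np.array(direct) / sum(direct)
        assert np.allclose(np.sort(out["tgvm_pct"].to_numpy()), np.sort(direct))

    def test_all_zero_draws_skipped_and_counted(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(20, 4))
        eff = rng.normal(size=(110, 4))
        eff[:10] = 0.0
        res, mp = _fake_results(eff, (eff != 0), Z, [(1, i + 1) for i in range(4)])
        out = window_variance(res, mp, min_draws=100)
        assert out.attrs["n_draws_skipped"] == 10

    def test_too_few_draws_rejected(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(10, 2))
        eff = rng.normal(size=(50, 2))
        res, mp = _fake_results(eff, np.ones_like(eff), Z, [(1, 1), (1, 2)])
        with pytest.raises(ValueError, match="draws"):
            window_variance(res, mp, min_draws=100)


class TestWindowPPI:
    def test_never_included_window_has_zero_ppi(self):
        Z = np.ones((5, 2))
        eff = np.zeros((100, 2))
        inc = np.zeros((100, 2))
        res, mp = _fake_results(eff, inc, Z, [(1, 1), (2, 1)])
        assert (window_ppi(res, mp) == 0).all()

    def test_always_included_window_has_unit_ppi(self):
        Z = np.ones((5, 2))
        eff = np.ones((100, 2))
        inc = np.ones((100, 2))
        res, mp = _fake_results(eff, inc, Z, [(1, 1), (2, 1)])
        assert (window_ppi(res, mp) == 1).all()

    def test_hand_counted_fixture(self):
        # 10 draws; marker 0 or 1 (same window) included in 7 of them
        inc = np.zeros((10, 3))
        inc[[0, 1, 2], 0] = 1
        inc[[2, 3, 4, 5, 6], 1] = 1
        eff = inc * 0.5
        Z = np.ones((4, 3))
        res, mp = _fake_results(eff, inc, Z, [(1, 100), (1, 200), (2, 100)])
        ppi = window_ppi(res, mp)
        assert ppi[(1, 0)] == pytest.approx(0.7)
        assert ppi[(2, 0)] == pytest.approx(0.0)

    def test_ppi_monotone_under_window_union(self):
        rng = np.random.default_rng(6)
        inc = (rng.random((200, 4)) < 0.3).astype(float)
        eff = inc * rng.normal(size=(200, 4))
        Z = rng.normal(size=(10, 4))
        # markers 0,1 in window (1,0); 2,3 in (1,1)
        res, mp = _fake_results(eff, inc, Z, [(1, 10), (1, 20), (1, 1_000_010), (1, 1_000_020)])
        ppi_split = window_ppi(res, mp)
        # same markers, now all in a single window: PPI >= each split PPI
        res2, mp2 = _fake_results(eff, inc, Z, [(1, 10), (1, 20), (1, 30), (1, 40)])
        ppi_union = window_ppi(res2, mp2)
        assert ppi_union[(1, 0)] >= ppi_split.max() - 1e-12


class TestCallQTL:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start_mb", "end_mb", "n_snp", "tgvm_pct", "ppi"])

    def test_no_window_above_threshold_gives_empty_list(self):
        res = self._frame([(1, 10.0, 11.0, 5, 1.0, 0.2)])
        assert call_qtl(res, tgvm_min=4.0) == []

    def test_adjacent_windows_merge_into_one_region(self):
        res = self._frame(
            [
                (2, 154.0, 155.0, 40, 5.0, 0.9),
                (2, 155.0, 156.0, 39, 4.5, 0.7),
                (2, 156.0, 157.0, 40, 4.2, 0.8),
            ]
        )
        regions = call_qtl(res, tgvm_min=4.0, merge_gap_mb=1.0)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_mb, r.end_mb) == (154.0, 157.0)
        assert r.tgvm_pct == pytest.approx(13.7)
        assert r.ppi == pytest.approx(0.9)

    def test_distant_windows_stay_separate(self):
        res = self._frame([(2, 10.0, 11.0, 5, 6.0, 0.9), (2, 21.0, 22.0, 5, 6.0, 0.9)])
        assert len(call_qtl(res, tgvm_min=4.0, merge_gap_mb=1.0)) == 2

    def test_cross_trait_overlap_report(self):
        r1 = QTLRegion(2, 154.0, 157.0, 3, 12.9, 0.9, 119)
        r2 = QTLRegion(2, 156.0, 158.0, 2, 6.2, 0.6, 80)
        r3 = QTLRegion(7, 107.0, 110.0, 3, 14.0, 0.7, 64)
        out = cross_trait_overlap({"va": [r1, r3], "vh": [r2]})
        assert len(out) == 1
        assert out.iloc[0]["chrom"] == 2


def test_window_pipeline_on_fitted_chain(small_population):
    sim = small_population
    r = fit_bayes(
        sim.genotypes, sim.phenotypes, "y",
        ChainConfig(method="BayesB", pi=0.99, n_iter=800, n_burnin=200, seed=3,
                    var_genetic=0.5, var_residual=0.5),
    )
    win = window_variance(r, sim.genotypes.map, min_draws=100)
    assert win["tgvm_pct"].sum() == pytest.approx(100.0, abs=1e-9)
    assert ((win["ppi"] >= 0) & (win["ppi"] <= 1)).all()
    assert (win["n_snp"] >= 1).all()
    # the planted window should top the table
    top = win.sort_values("tgvm_pct", ascending=False).iloc[0]
    assert (top["chrom"], top["start_mb"]) == (2, 50.0)
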