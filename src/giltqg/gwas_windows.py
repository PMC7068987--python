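"""1-Mb window summaries of whole-genome regression posteriors.

Markers are binned into non-overlapping, half-open 1-Mb windows per
chromosome. For each retained MCMC draw the genomic value contributed by
a window's markers is computed across animals; the window's share of the
total marker-explained ("genic") variance in that draw is the ratio of
its empirical variance to the sum over windows. The posterior mean of
that share, in percent, is %TGVM (so %TGVM sums to 100 over windows by
construction). PPI is the fraction of retained draws in which at least
one marker in the window carries a nonzero effect. Windows with %TGVM
above a threshold are merged into QTL regions when adjacent or within a
configurable gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_regression import BayesResults

__all__ = [
    "assign_windows",
    "window_variance",
    "window_ppi",
    "window_results",
    "call_qtl",
    "QTLRegion",
    "manhattan_plot",
]

WINDOW_BP = 1_000_000


def assign_windows(marker_map: pd.DataFrame, window_mb: float = 1.0) -> pd.Series:
    """Window ID (chrom, floor(pos / window)) per marker.

    Windows are half-open [k*window, (k+1)*window) in bp and never span
    chromosomes.
    """
    size = int(window_mb * 1e6)
    wid = list(
        zip(marker_map["chrom"].to_numpy(), marker_map["pos"].to_numpy() // size)
    )
    return pd.Series(wid, index=marker_map.index, name="window")


def _window_columns(markers, marker_map, window_mb):
    win = assign_windows(marker_map.loc[markers], window_mb)
    groups: dict = {}
    for j, w in enumerate(win.to_numpy()):
        groups.setdefault(w, []).append(j)
    return dict(sorted(groups.items()))


def window_variance(
    samples: BayesResults,
    marker_map: pd.DataFrame | None = None,
    window_mb: float = 1.0,
    min_draws: int = 100,
    per_draw_ratio: bool = True,
) -> pd.DataFrame:
    """%TGVM (and PPI) per 1-Mb window from retained draws.

    ``per_draw_ratio=True`` (default) averages the draw-level variance
    shares, propagating the joint posterior uncertainty; ``False``
    instead takes the ratio of posterior-mean window variances.
    Draws in which no marker is included have undefined shares and are
    skipped (their count is in the ``n_draws_skipped`` attribute of the
    returned frame).
    """
    if marker_map is None:
        raise ValueError("marker_map required (chrom, pos indexed by marker)")
    if samples.n_draws < min_draws:
        raise ValueError(
            f"only {samples.n_draws} retained draws; need at least {min_draws}"
        )
    groups = _window_columns(samples.markers, marker_map, window_mb)
    Z = samples._Z
    n_draws = samples.n_draws
    n_win = len(groups)
    win_var = np.zeros((n_draws, n_win))
    for w, (key, cols) in enumerate(groups.items()):
        U = samples.effects[:, cols] @ Z[:, cols].T  # draws x animals
        win_var[:, w] = U.var(axis=1)
    tot = win_var.sum(axis=1)
    valid = tot > 0
    n_skipped = int((~valid).sum())
    if per_draw_ratio:
        shares = win_var[valid] / tot[valid, None]
        tgvm = 100.0 * shares.mean(axis=0)
    else:
        mv = win_var[valid].mean(axis=0)
        tgvm = 100.0 * mv / mv.sum()
    ppi = np.zeros(n_win)
    for w, (key, cols) in enumerate(groups.items()):
        ppi[w] = (samples.include[:, cols].max(axis=1) > 0).mean()
    rows = []
    for w, (key, cols) in enumerate(groups.items()):
        chrom, k = key
        rows.append(
            {
                "chrom": int(chrom),
                "start_mb": float(k * window_mb),
                "end_mb": float((k + 1) * window_mb),
                "n_snp": len(cols),
                "tgvm_pct": tgvm[w],
                "ppi": ppi[w],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_draws_skipped"] = n_skipped
    return out


def window_ppi(samples: BayesResults, marker_map: pd.DataFrame, window_mb: float = 1.0) -> pd.Series:
    """Posterior probability of inclusion per window: fraction of
    retained draws with >= 1 nonzero-effect marker in the window."""
    groups = _window_columns(samples.markers, marker_map, window_mb)
    out = {}
    for key, cols in groups.items():
        out[key] = float((samples.include[:, cols].max(axis=1) > 0).mean())
    return pd.Series(out, name="ppi")


def window_results(samples, marker_map, window_mb=1.0, **kw) -> pd.DataFrame:
    """Alias for :func:`window_variance` (full window table)."""
    return window_variance(samples, marker_map, window_mb, **kw)


@dataclass
class QTLRegion:
    chrom: int
    start_mb: float
    end_mb: float
    n_windows: int
    tgvm_pct: float  # summed over constituent windows
    ppi: float  # max over constituent windows
    n_snp: int

    @property
    def interval(self):
        return (self.chrom, self.start_mb, self.end_mb)

    def __str__(self):
        return (
            f"SSC{self.chrom} {self.start_mb:g}-{self.end_mb:g} Mb "
            f"({self.n_snp} SNPs, {self.tgvm_pct:.1f}% TGVM, PPI {self.ppi:.2f})"
        )


def call_qtl(results: pd.DataFrame, tgvm_min: float = 4.0, merge_gap_mb: float = 1.0) -> list:
    """QTL regions from a window table: seed with windows at or above
    ``tgvm_min`` %TGVM, merge same-chromosome seeds separated by at most
    ``merge_gap_mb``. Region %TGVM sums constituent windows; PPI is the
    max."""
    seeds = results[results["tgvm_pct"] >= tgvm_min].sort_values(["chrom", "start_mb"])
    regions = []
    cur = None
    for _, row in seeds.iterrows():
        if cur is not None and row["chrom"] == cur["chrom"] and row["start_mb"] - cur["end_mb"] <= merge_gap_mb:
            cur["end_mb"] = row["end_mb"]
            cur["tgvm"] += row["tgvm_pct"]
            cur["ppi"] = max(cur["ppi"], row["ppi"])
            cur["n"] += 1
            cur["n_snp"] += row["n_snp"]
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": int(row["chrom"]),
                "start_mb": row["start_mb"],
                "end_mb": row["end_mb"],
                "tgvm": row["tgvm_pct"],
                "ppi": row["ppi"],
                "n": 1,
                "n_snp": int(row["n_snp"]),
            }
    if cur is not None:
        regions.append(cur)
    return [
        QTLRegion(
            chrom=r["chrom"],
            start_mb=r["start_mb"],
            end_mb=r["end_mb"],
            n_windows=r["n"],
            tgvm_pct=r["tgvm"],
            ppi=r["ppi"],
            n_snp=r["n_snp"],
        )
        for r in regions
    ]


def cross_trait_overlap(regions_by_trait: dict) -> pd.DataFrame:
    """Regions sharing any interval across traits (same chromosome,
    overlapping Mb spans)."""
    rows = []
    traits = list(regions_by_trait)
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            for r1 in regions_by_trait[t1]:
                for r2 in regions_by_trait[t2]:
                    if r1.chrom == r2.chrom and r1.start_mb < r2.end_mb and r2.start_mb < r1.end_mb:
                        rows.append(
                            {
                                "chrom": r1.chrom,
                                "trait_1": t1,
                                "trait_2": t2,
                                "start_mb": max(r1.start_mb, r2.start_mb),
                                "end_mb": min(r1.end_mb, r2.end_mb),
                            }
                        )
    return pd.DataFrame(rows, columns=["chrom", "trait_1", "trait_2", "start_mb", "end_mb"])


def manhattan_plot(results: pd.DataFrame, ax=None, tgvm_min: float | None = 4.0):
    """Manhattan-style plot of %TGVM by 1-Mb window position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, sub in results.groupby("chrom"):
        x = offset + sub["start_mb"].to_numpy()
        ax.scatter(x, sub["tgvm_pct"], s=8, label=None)
        ticks.append(offset + sub["start_mb"].max() / 2)
        labels.append(str(chrom))
        offset += sub["end_mb"].max() + 5
    if tgvm_min is not None:
        ax.axhline(tgvm_min, ls="--", lw=0.8, color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome / 1-Mb window")
    ax.set_ylabel("%TGVM")
    return ax
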