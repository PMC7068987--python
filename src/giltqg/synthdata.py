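"""Synthetic breeding-population generator with known ground truth.

Emulates the data structure of a purebred pig breeding program: a
multi-generation pedigree with discrete generations and litters, SNP
genotypes produced by gene dropping founder haplotypes down the pedigree
(recombination at 1 cM/Mb between adjacent markers), and phenotypes built
from the same linear model the analysis assumes:

    y = mu + line + contemporary group + b * BW + breeding value
        + litter effect + residual

The breeding value has a sparse-QTL component (a configurable number of
markers carrying fixed shares of the additive variance) plus a polygenic
remainder transmitted as parent average + Mendelian sampling. Founder
haplotypes get block-wise LD through a Gaussian-copula latent variable
shared within marker blocks. Every random draw is recorded in a
:class:`GroundTruth` so parameter-recovery tests can compare estimates
with the simulated truth.

Presets ``landrace_like`` and ``yorkshire_like`` reproduce the scale and
variance structure of the two gilt populations analysed by the package
(cohorts of ~475 and ~708 phenotyped females, vulva height and width as
correlated traits with vulva area their product); ``*_va_direct`` presets
simulate vulva area as a single trait with its published variance
components for clean univariate recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_qc import GenotypeData
from .pedigree_kinship import Pedigree, build_A

__all__ = [
    "TraitSpec",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "landrace_like",
    "yorkshire_like",
    "va_direct_config",
]


@dataclass
class TraitSpec:
    """Variance components and covariate slope for one simulated trait."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    mean: float = 0.0
    bw_coef: float = 0.0  # trait units per kg of body weight

    @property
    def sigma2_p(self):
        return self.sigma2_a + self.sigma2_d + self.sigma2_e

    @property
    def h2(self):
        return self.sigma2_a / self.sigma2_p

    @property
    def c2(self):
        return self.sigma2_d / self.sigma2_p


@dataclass
class SimConfig:
    label: str = "breed"
    # pedigree
    n_sires: int = 20
    n_dams: int = 60
    generations: int = 3
    litter_size: int = 10
    poisson_litters: bool = False
    # genome
    n_chrom: int = 5
    chrom_length_mb: float = 100.0
    n_markers: int = 2000
    maf_range: tuple = (0.05, 0.5)
    ld_block_markers: int = 20
    ld_corr: float = 0.6
    # genetic architecture
    traits: dict = field(default_factory=lambda: {"trait": TraitSpec(0.3, 0.1, 0.6)})
    genetic_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    n_qtl: int = 20
    qtl_total_share: float = 0.5  # share of sigma2_a carried by QTL markers
    qtl_shares: list | None = None  # explicit per-QTL shares (overrides n_qtl split)
    qtl_window: tuple | None = None  # (chrom, mb) to concentrate all QTL in one 1-Mb window
    fix_qtl_magnitude: bool = True
    # fixed effects
    n_lines: int = 2
    n_cg: int = 5
    line_sd: float = 0.5  # in phenotypic-SD units per trait
    cg_sd: float = 0.5
    bw_mean: float = 120.0
    bw_sd: float = 12.0


@dataclass
class SimPedigree:
    ped: Pedigree
    meta: pd.DataFrame  # animal, sire, dam, sex, generation, litter

    @property
    def cohort(self) -> list:
        """Phenotyped cohort: females of the final generation."""
        m = self.meta
        last = m["generation"].max()
        return m.loc[(m["generation"] == last) & (m["sex"] == "F"), "animal"].tolist()


@dataclass
class GroundTruth:
    breeding_values: pd.DataFrame  # animals x traits (cohort)
    litter_effects: pd.DataFrame  # litter x traits
    marker_effects: pd.DataFrame  # markers x traits (zeros off-QTL)
    qtl_markers: list
    realized: pd.DataFrame  # per-trait realized var components, h2, c2

    def window_shares(self, g: GenotypeData, window_mb: float = 1.0) -> pd.DataFrame:
        """Realized per-window share of marker-explained genetic variance."""
        Z = g.calls - g.calls.mean(axis=0)
        win = list(
            zip(g.map["chrom"].to_numpy(), (g.map["pos"].to_numpy() // int(window_mb * 1e6)))
        )
        out = {}
        for t in self.marker_effects.columns:
            beta = self.marker_effects[t].to_numpy()
            shares = {}
            for w in sorted(set(win)):
                cols = [j for j, ww in enumerate(win) if ww == w]
                u = Z[:, cols] @ beta[cols]
                shares[w] = float(np.var(u))
            tot = sum(shares.values())
            out[t] = {w: (100.0 * v / tot if tot > 0 else 0.0) for w, v in shares.items()}
        return pd.DataFrame(out)


@dataclass
class SimResult:
    config: SimConfig
    simped: SimPedigree
    genotypes_all: GenotypeData
    genotypes: GenotypeData  # phenotyped cohort only
    phenotypes: pd.DataFrame
    truth: GroundTruth

    @property
    def pedigree(self) -> Pedigree:
        return self.simped.ped

    def save(self, outdir):
        """Emit the file dialects the io_qc readers accept, plus ground truth."""
        import json
        import os

        from .io_qc import write_genotypes

        os.makedirs(outdir, exist_ok=True)
        self.simped.ped.to_dataframe().fillna(0).to_csv(f"{outdir}/pedigree.csv", index=False)
        write_genotypes(self.genotypes, f"{outdir}/genotypes.tsv", f"{outdir}/markers.tsv")
        self.phenotypes.to_csv(f"{outdir}/phenotypes.csv", index=False)
        self.truth.breeding_values.to_csv(f"{outdir}/true_breeding_values.csv")
        self.truth.marker_effects.to_csv(f"{outdir}/true_marker_effects.csv")
        with open(f"{outdir}/realized_components.json", "w") as fh:
            json.dump(self.truth.realized.to_dict(), fh, indent=1)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_pedigree(cfg: SimConfig, seed=0) -> SimPedigree:
    """Discrete-generation pedigree: each dam produces one litter per
    generation with a single randomly assigned sire; final-generation
    females are the phenotyped cohort."""
    rng = _rng(seed)
    if cfg.n_sires < 1 or cfg.n_dams < 1:
        raise ValueError("need at least one sire and one dam")
    rows = []
    counter = 0

    def new_id(prefix):
        nonlocal counter
        counter += 1
        return f"{cfg.label}_{prefix}{counter:05d}"

    sires = [new_id("S") for _ in range(cfg.n_sires)]
    dams = [new_id("D") for _ in range(cfg.n_dams)]
    for a in sires:
        rows.append((a, None, None, "M", 0, None))
    for a in dams:
        rows.append((a, None, None, "F", 0, None))
    litter_no = 0
    for gen in range(1, cfg.generations + 1):
        offspring_m, offspring_f = [], []
        # every sire serves at least one dam (when dams suffice); the
        # remaining dams draw sires at random
        order = list(rng.permutation(len(dams)))
        sire_of = {}
        for rank, di in enumerate(order):
            sire_of[di] = sires[rank] if rank < len(sires) else sires[rng.integers(len(sires))]
        for di, dam in enumerate(dams):
            sire = sire_of[di]
            litter_no += 1
            lid = f"{cfg.label}_L{litter_no:05d}"
            size = (
                max(1, int(rng.poisson(cfg.litter_size))) if cfg.poisson_litters else cfg.litter_size
            )
            for _ in range(size):
                sex = "M" if rng.random() < 0.5 else "F"
                a = new_id("A")
                rows.append((a, sire, dam, sex, gen, lid))
                (offspring_m if sex == "M" else offspring_f).append(a)
        if gen < cfg.generations:
            if len(offspring_m) < cfg.n_sires or len(offspring_f) < cfg.n_dams:
                raise ValueError(
                    f"infeasible mating counts at generation {gen}: "
                    f"{len(offspring_m)} males / {len(offspring_f)} females available"
                )
            sires = list(rng.choice(offspring_m, size=cfg.n_sires, replace=False))
            dams = list(rng.choice(offspring_f, size=cfg.n_dams, replace=False))
    meta = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation", "litter"])
    ped = Pedigree.from_records(meta[["animal", "sire", "dam"]].itertuples(index=False, name=None))
    return SimPedigree(ped=ped, meta=meta)


def _marker_map(cfg: SimConfig, rng) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per_chrom[: cfg.n_markers % cfg.n_chrom] += 1
    rows = []
    k = 0
    for c in range(1, cfg.n_chrom + 1):
        pos = np.sort(
            rng.integers(1, int(cfg.chrom_length_mb * 1e6), size=per_chrom[c - 1])
        )
        pos = np.unique(pos)
        while len(pos) < per_chrom[c - 1]:  # rare collision top-up
            extra = rng.integers(1, int(cfg.chrom_length_mb * 1e6), size=per_chrom[c - 1])
            pos = np.unique(np.concatenate([pos, extra]))[: per_chrom[c - 1]]
        pos = np.sort(pos)
        if cfg.qtl_window is not None and c == cfg.qtl_window[0]:
            # guarantee enough markers inside the planted-QTL window
            lo = int(cfg.qtl_window[1] * 1e6)
            hi = lo + 1_000_000
            need = max(cfg.n_qtl, len(cfg.qtl_shares or []), 3)
            inside = (pos >= lo) & (pos < hi)
            deficit = need - int(inside.sum())
            if deficit > 0:
                outside = np.flatnonzero(~inside)
                move = outside[np.argsort(np.abs(pos[outside] - (lo + hi) // 2))][:deficit]
                pos[move] = rng.integers(lo, hi, size=deficit)
                pos = np.sort(np.unique(pos))
                while len(pos) < per_chrom[c - 1]:
                    pos = np.unique(np.append(pos, rng.integers(lo, hi)))
                pos = np.sort(pos)
        for p in pos:
            rows.append((f"M{k:06d}", c, int(p)))
            k += 1
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"]).set_index("marker")


def simulate_genotypes(simped: SimPedigree, cfg: SimConfig, seed=0) -> GenotypeData:
    """Founder haplotypes with block LD, gene-dropped down the pedigree.

    Founder allele at marker k is 1 when a latent Gaussian (shared within
    LD blocks with correlation ``ld_corr``) falls below the quantile of
    the marker's target allele frequency. Each meiosis recombines between
    adjacent markers with probability 0.01 x distance(Mb), capped at 0.5.
    Returns dosages for every animal in the pedigree.
    """
    rng = _rng(seed)
    if cfg.n_markers < 1:
        raise ValueError("need at least one marker")
    mp = _marker_map(cfg, rng)
    m = len(mp)
    ped = simped.ped
    n = len(ped)
    freqs = rng.uniform(*cfg.maf_range, size=m)

    chrom = mp["chrom"].to_numpy()
    pos = mp["pos"].to_numpy()
    # per-interval recombination probability (Haldane-free linear map, capped)
    d_mb = np.diff(pos) / 1e6
    rec = np.minimum(0.5, 0.01 * d_mb)
    rec[np.diff(chrom) != 0] = 0.5  # independent chromosomes

    block = np.arange(m) // max(1, cfg.ld_block_markers)
    # block index restarts at chromosome boundaries so LD never spans them
    block = block + chrom * (block.max() + 1)
    _, block = np.unique(block, return_inverse=True)
    n_blocks = block.max() + 1
    thresh = norm.ppf(freqs)
    c = np.clip(cfg.ld_corr, 0.0, 0.999)

    hap = np.zeros((n, 2, m), dtype=np.int8)

    def founder_gamete(size):
        z = rng.standard_normal((size, n_blocks))[:, block]
        e = rng.standard_normal((size, m))
        x = np.sqrt(c) * z + np.sqrt(1.0 - c) * e
        return (x < thresh).astype(np.int8)

    def meiosis(parent_idx):
        cross = rng.random(m - 1) < rec
        source = np.zeros(m, dtype=np.int64)
        source[1:] = np.cumsum(cross)
        source = (source + rng.integers(2)) % 2
        return np.where(source == 0, hap[parent_idx, 0], hap[parent_idx, 1])

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        hap[i, 0] = meiosis(s) if s >= 0 else founder_gamete(1)[0]
        hap[i, 1] = meiosis(d) if d >= 0 else founder_gamete(1)[0]

    calls = hap.sum(axis=1).astype(float)
    return GenotypeData(samples=list(ped.ids), markers=mp.index.tolist(), calls=calls, map=mp)


def _corr_or_identity(mat, k):
    if mat is None:
        return np.eye(k)
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh(mat)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    return mat


def simulate_phenotypes(
    simped: SimPedigree, g: GenotypeData, cfg: SimConfig, seed=0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Phenotypes for the final-generation females, with full ground truth.

    Breeding value = QTL component (marker effects x dosages) + polygenic
    remainder bred down the pedigree (parent average + Mendelian sampling
    with variance 0.5*(1 - mean parental F)*sigma2_poly). Litter effects
    are shared within litter; residuals are independent across animals.
    """
    rng = _rng(seed)
    ped = simped.ped
    meta = simped.meta.set_index("animal")
    traits = list(cfg.traits)
    k = len(traits)
    Rg = _corr_or_identity(cfg.genetic_corr, k)
    Re = _corr_or_identity(cfg.residual_corr, k)
    m = g.n_markers
    gpos = {a: i for i, a in enumerate(g.samples)}

    # --- QTL selection ---
    if cfg.qtl_shares is not None:
        shares = np.asarray(cfg.qtl_shares, dtype=float)
    else:
        shares = np.full(cfg.n_qtl, cfg.qtl_total_share / max(1, cfg.n_qtl))
    n_qtl = len(shares)
    if shares.sum() > 1.0 + 1e-9:
        raise ValueError("per-QTL shares of sigma2_a sum to more than 1")
    poly_share = 1.0 - shares.sum()
    p = g.allele_freq()
    seg = np.flatnonzero((p > 0.01) & (p < 0.99))
    if cfg.qtl_window is not None:
        wchrom, wmb = cfg.qtl_window
        inwin = (g.map["chrom"].to_numpy() == wchrom) & (
            g.map["pos"].to_numpy() // 1_000_000 == wmb
        )
        pool = np.flatnonzero(inwin & np.isin(np.arange(m), seg))
        if len(pool) < n_qtl:
            raise ValueError("QTL window holds fewer segregating markers than n_qtl")
    else:
        pool = seg
    qtl_idx = rng.choice(pool, size=n_qtl, replace=False) if n_qtl else np.array([], dtype=int)

    # --- marker effects (traits correlated via Rg) ---
    beta = np.zeros((m, k))
    L = np.linalg.cholesky(Rg + 1e-12 * np.eye(k))
    for q, j in enumerate(qtl_idx):
        v = L @ rng.standard_normal(k)
        u = np.sign(v) if cfg.fix_qtl_magnitude else v
        het = 2.0 * p[j] * (1.0 - p[j])
        for t, name in enumerate(traits):
            beta[j, t] = u[t] * np.sqrt(shares[q] * cfg.traits[name].sigma2_a / het)

    Zall = g.calls - 2.0 * p  # centred dosages for BV construction
    bv_qtl = Zall @ beta  # all animals x traits

    # --- polygenic remainder down the pedigree ---
    sig_poly = np.array([cfg.traits[t].sigma2_a * poly_share for t in traits])
    C_poly = np.sqrt(np.outer(sig_poly, sig_poly)) * Rg
    Lp = np.linalg.cholesky(C_poly + 1e-12 * np.eye(k)) if poly_share > 0 else np.zeros((k, k))
    n = len(ped)
    F = np.diag(build_A(ped).values) - 1.0 if n <= 4000 else np.zeros(n)
    a_poly = np.zeros((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a_poly[i] = Lp @ rng.standard_normal(k)
        else:
            pa = 0.0
            msv = 1.0
            if s >= 0 and d >= 0:
                pa = 0.5 * (a_poly[s] + a_poly[d])
                msv = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
            elif s >= 0:
                pa = 0.5 * a_poly[s]
                msv = 0.75
            else:
                pa = 0.5 * a_poly[d]
                msv = 0.75
            a_poly[i] = pa + np.sqrt(msv) * (Lp @ rng.standard_normal(k))

    ped_index = {a: i for i, a in enumerate(ped.ids)}
    cohort = simped.cohort
    ci = [ped_index[a] for a in cohort]
    gi = [gpos[a] for a in cohort]
    bv_cohort = bv_qtl[gi] + a_poly[ci]

    # --- litter, fixed effects, residual ---
    litters = meta.loc[cohort, "litter"]
    uniq_litters = litters.dropna().unique().tolist()
    sd_d = np.array([np.sqrt(cfg.traits[t].sigma2_d) for t in traits])
    lit_eff = pd.DataFrame(
        rng.standard_normal((len(uniq_litters), k)) * sd_d, index=uniq_litters, columns=traits
    )
    sd_e = np.array([np.sqrt(cfg.traits[t].sigma2_e) for t in traits])
    Le = np.linalg.cholesky(Re + 1e-12 * np.eye(k))
    resid = (rng.standard_normal((len(cohort), k)) @ Le.T) * sd_e

    sigma_p = np.array([np.sqrt(cfg.traits[t].sigma2_p) for t in traits])
    line_eff = rng.standard_normal((cfg.n_lines, k)) * cfg.line_sd * sigma_p
    cg_eff = rng.standard_normal((cfg.n_cg, k)) * cfg.cg_sd * sigma_p
    line = rng.integers(cfg.n_lines, size=len(cohort))
    cg = rng.integers(cfg.n_cg, size=len(cohort))
    bw = rng.normal(cfg.bw_mean, cfg.bw_sd, size=len(cohort))
    bw_coef = np.array([cfg.traits[t].bw_coef for t in traits])
    mu = np.array([cfg.traits[t].mean for t in traits])

    y = (
        mu
        + line_eff[line]
        + cg_eff[cg]
        + np.outer(bw - cfg.bw_mean, bw_coef)
        + bv_cohort
        + lit_eff.loc[litters].to_numpy()
        + resid
    )

    pheno = pd.DataFrame(
        {
            "animal": cohort,
            "breed": cfg.label,
            "line": [f"L{x+1}" for x in line],
            "cg": [f"CG{x+1}" for x in cg],
            "litter": litters.to_numpy(),
            "bw": bw,
        }
    )
    for t, name in enumerate(traits):
        pheno[name] = y[:, t]
    if {"vh", "vw"} <= set(traits):
        pheno["va"] = pheno["vh"] * pheno["vw"]

    realized = pd.DataFrame(index=traits, columns=["var_a", "var_d", "var_e", "h2", "c2"], dtype=float)
    for t, name in enumerate(traits):
        va_r = float(np.var(bv_cohort[:, t]))
        vd_r = float(np.var(lit_eff.loc[litters, name]))
        ve_r = float(np.var(resid[:, t]))
        tot = va_r + vd_r + ve_r
        realized.loc[name] = [va_r, vd_r, ve_r, va_r / tot, vd_r / tot]

    truth = GroundTruth(
        breeding_values=pd.DataFrame(bv_cohort, index=cohort, columns=traits),
        litter_effects=lit_eff,
        marker_effects=pd.DataFrame(beta, index=g.markers, columns=traits),
        qtl_markers=[g.markers[j] for j in qtl_idx],
        realized=realized,
    )
    return pheno, truth


def simulate_population(cfg: SimConfig, seed=0) -> SimResult:
    """End-to-end simulation of one breed; deterministic given seed."""
    rng = _rng(seed)
    s1, s2, s3 = rng.integers(0, 2**31 - 1, size=3)
    simped = simulate_pedigree(cfg, int(s1))
    g_all = simulate_genotypes(simped, cfg, int(s2))
    pheno, truth = simulate_phenotypes(simped, g_all, cfg, int(s3))
    g_cohort = g_all.take_samples(simped.cohort)
    return SimResult(
        config=cfg,
        simped=simped,
        genotypes_all=g_all,
        genotypes=g_cohort,
        phenotypes=pheno,
        truth=truth,
    )


def _vs_traits(vh: TraitSpec, vw: TraitSpec, r_g: float, r_e: float):
    R = np.array([[1.0, r_g], [r_g, 1.0]])
    Re = np.array([[1.0, r_e], [r_e, 1.0]])
    return {"vh": vh, "vw": vw}, R, Re


def landrace_like(**overrides) -> SimConfig:
    """~475 phenotyped gilts; vulva height/width with the published
    Landrace variance components (VH: a=11.2, e=30.5, c2=0.10;
    VW: a=2.5, e=20.8, c2=0.22; r_G(VH,VW)=0.67); VA = VH x VW."""
    traits, Rg, Re = _vs_traits(
        TraitSpec(11.2, 4.633, 30.5, mean=36.2, bw_coef=0.20),
        TraitSpec(2.5, 6.572, 20.8, mean=27.3, bw_coef=0.15),
        r_g=0.67,
        r_e=0.60,
    )
    cfg = SimConfig(
        label="landrace",
        fix_qtl_magnitude=False,
        n_sires=20,
        n_dams=95,
        generations=3,
        litter_size=10,
        traits=traits,
        genetic_corr=Rg,
        residual_corr=Re,
        n_qtl=8,
        qtl_total_share=0.5,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def yorkshire_like(**overrides) -> SimConfig:
    """~708 phenotyped gilts; vulva height/width with the published
    Yorkshire variance components (VH: a=27.1, e=20.1, c2=0.04;
    VW: a=10.8, e=22.6, c2=0.06; r_G(VH,VW)=0.73); VA = VH x VW."""
    traits, Rg, Re = _vs_traits(
        TraitSpec(27.1, 1.967, 20.1, mean=35.9, bw_coef=0.20),
        TraitSpec(10.8, 2.132, 22.6, mean=26.8, bw_coef=0.15),
        r_g=0.73,
        r_e=0.60,
    )
    cfg = SimConfig(
        label="yorkshire",
        fix_qtl_magnitude=False,
        n_sires=30,
        n_dams=140,
        generations=3,
        litter_size=10,
        traits=traits,
        genetic_corr=Rg,
        residual_corr=Re,
        n_qtl=8,
        qtl_total_share=0.5,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def va_direct_config(breed="yorkshire", **overrides) -> SimConfig:
    """Single-trait vulva-area simulation with the published components
    (Yorkshire: a=69,807.7, d=9,050.9, e=71,990.1, h2=0.46, c2=0.06;
    Landrace: a=21,953.3, d=22,759.4, e=89,166.2, h2=0.16, c2=0.17)."""
    if breed == "yorkshire":
        base = yorkshire_like()
        spec = TraitSpec(69807.7, 9050.9, 71990.1, mean=984.5, bw_coef=10.0)
    else:
        base = landrace_like()
        spec = TraitSpec(21953.3, 22759.4, 89166.2, mean=1014.7, bw_coef=10.0)
    base.traits = {"va": spec}
    base.genetic_corr = None
    base.residual_corr = None
    for key, val in overrides.items():
        setattr(base, key, val)
    return base
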