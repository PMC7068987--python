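"""Cross-validated genomic prediction and genomic prediction accuracy.

Folds follow sire families: sires are shuffled with a seed and grouped
(5 per fold by default); every daughter inherits her sire's fold, so a
paternal half-sib family is never split between training and validation.
Three training/validation strategies are supported:

* **within** — n-fold cross-validation inside one breed;
* **between** — train on the full other breed, validate once on this
  breed (a single split, so no across-fold SD);
* **multi** — train on both breeds jointly, validate one within-breed
  fold at a time (fold count is the sum of the within-breed folds).

Genomic prediction accuracy (GPA) divides the correlation of GEBVs with
fixed-effect-adjusted phenotypes (y*) by the square root of the
validation breed's pedigree heritability: a single split gives
GPA = r(GEBV, y*) / sqrt(h2); cross-validation gives the fold-size-
weighted mean, GPA = (sum n_i r_i / sum n_i) / sqrt(h2), with the
across-fold SD of r_i / sqrt(h2) as its spread.

QTL-subset prediction trains on ALL markers and restricts only the
prediction step to a SNP set: per-QTL sets, their union (QTL), or the
complement with a 3-Mb flank around every region excluded (REST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes_regression import BayesAlphabet, ChainConfig
from .pedigree_kinship import Pedigree

__all__ = [
    "FoldAssignment",
    "SNPSet",
    "GPAResult",
    "make_folds",
    "adjust_phenotypes",
    "gpa_single",
    "gpa_cv",
    "build_snp_sets",
    "run_strategy",
]


@dataclass
class FoldAssignment:
    fold: pd.Series  # animal -> fold id
    sires: dict  # fold id -> list of sires
    seed: int
    breed: str | None = None

    @property
    def n_folds(self):
        return len(self.sires)

    def animals(self, fold_id) -> list:
        return self.fold.index[self.fold == fold_id].tolist()


def make_folds(pheno: pd.DataFrame, pedigree: Pedigree, n_folds: int,
               sires_per_fold: int = 5, seed: int = 0, breed: str | None = None) -> FoldAssignment:
    """Sire-family cross-validation folds.

    Sires of the phenotyped animals are shuffled by ``seed`` and grouped
    ``sires_per_fold`` per fold; daughters inherit their sire's fold.
    Leftover sires (when the sire count is not a multiple) have their
    daughters attached to the currently smallest folds.
    """
    sub = pheno if breed is None else pheno[pheno["breed"] == breed]
    ids = sub["animal"].tolist()
    idx = pedigree.index_of(ids)
    sire_idx = pedigree.sire[idx]
    if (sire_idx < 0).any():
        bad = [a for a, s in zip(ids, sire_idx) if s < 0]
        raise ValueError(f"animals with unknown sire cannot be folded: {bad[:5]}")
    sires = pd.Series([pedigree.ids[s] for s in sire_idx], index=ids, name="sire")
    uniq = sorted(set(sires))
    if n_folds * sires_per_fold > len(uniq):
        raise ValueError(
            f"{n_folds} folds x {sires_per_fold} sires requires at least "
            f"{n_folds * sires_per_fold} sires; only {len(uniq)} available"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(uniq))
    fold_sires = {f: shuffled[f * sires_per_fold : (f + 1) * sires_per_fold] for f in range(n_folds)}
    assign = {}
    for f, ss in fold_sires.items():
        for s in ss:
            assign[s] = f
    leftovers = shuffled[n_folds * sires_per_fold :]
    if leftovers:
        sizes = {f: int((sires.map(assign) == f).sum()) for f in range(n_folds)}
        for s in leftovers:
            f = min(sizes, key=sizes.get)
            assign[s] = f
            fold_sires[f].append(s)
            sizes[f] += int((sires == s).sum())
    fold = sires.map(assign).astype(int)
    fold.index.name = "animal"
    return FoldAssignment(fold=fold, sires=fold_sires, seed=seed, breed=breed)


def adjust_phenotypes(pheno: pd.DataFrame, trait: str, fixed_effects: pd.Series,
                      design) -> pd.Series:
    """y* = y - (mu + line + CG + b*BW), using fixed-effect solutions and
    the design (level maps, covariate centres) from the TRAINING fit.
    Unseen factor levels contribute zero with a warning."""
    X = design.build(pheno, warn_unseen=True)
    est = fixed_effects.reindex(design.names).to_numpy()
    ystar = pheno[trait].to_numpy(dtype=float) - X @ est
    return pd.Series(ystar, index=pheno["animal"].to_numpy(), name="ystar")


def gpa_single(gebv, ystar, h2_validation: float) -> float:
    """GPA for one train/validation split: r(GEBV, y*) / sqrt(h2)."""
    if not 0.0 < h2_validation <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(ystar, dtype=float)
    if len(g) < 3:
        raise ValueError("need at least 3 animals")
    if np.std(g) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance GEBV or y*: GPA undefined", stacklevel=2)
        return np.nan
    r = float(np.corrcoef(g, y)[0, 1])
    return r / np.sqrt(h2_validation)


def gpa_cv(fold_stats, h2_validation: float) -> tuple[float, float]:
    """Cross-validated GPA: fold-size-weighted mean correlation over
    sqrt(h2), plus the across-fold SD of r_i/sqrt(h2) (NaN for a single
    fold). ``fold_stats`` is an iterable of (r_i, n_i)."""
    if not 0.0 < h2_validation <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    stats = [(float(r), int(n)) for r, n in fold_stats]
    if any(n < 3 for _, n in stats):
        raise ValueError("every fold needs at least 3 animals")
    rs = np.array([r for r, _ in stats])
    ns = np.array([n for _, n in stats])
    root = np.sqrt(h2_validation)
    gpa = float((rs * ns).sum() / ns.sum() / root)
    sd = float(np.std(rs / root, ddof=1)) if len(stats) > 1 else np.nan
    return gpa, sd


@dataclass
class SNPSet:
    label: str
    markers: list
    regions: list = field(default_factory=list)
    flank_mb: float = 0.0

    def __len__(self):
        return len(self.markers)


def build_snp_sets(qtl_regions, marker_map: pd.DataFrame, flank_mb: float = 3.0) -> dict:
    """SNP sets from called QTL regions.

    Returns {"ALL", "QTL", "REST", "per-QTL:<SSCc:a-b>": ...}. Per-QTL
    sets are the markers inside each region; QTL is their union; REST is
    ALL minus markers inside any region expanded by ``flank_mb`` on both
    sides. A region containing zero markers is kept as an (empty,
    flagged) set.
    """
    all_markers = marker_map.index.tolist()
    chrom = marker_map["chrom"].to_numpy()
    mb = marker_map["pos"].to_numpy() / 1e6
    sets = {"ALL": SNPSet("ALL", all_markers)}
    union = np.zeros(len(all_markers), dtype=bool)
    flanked = np.zeros(len(all_markers), dtype=bool)
    for r in qtl_regions:
        inside = (chrom == r.chrom) & (mb >= r.start_mb) & (mb < r.end_mb)
        wide = (chrom == r.chrom) & (mb >= r.start_mb - flank_mb) & (mb < r.end_mb + flank_mb)
        union |= inside
        flanked |= wide
        label = f"per-QTL:SSC{r.chrom}:{r.start_mb:g}-{r.end_mb:g}"
        members = [m for m, keep in zip(all_markers, inside) if keep]
        if not members:
            warnings.warn(f"QTL region {label} contains no markers", stacklevel=2)
        sets[label] = SNPSet(label, members, regions=[r])
    sets["QTL"] = SNPSet("QTL", [m for m, keep in zip(all_markers, union) if keep],
                         regions=list(qtl_regions))
    sets["REST"] = SNPSet("REST", [m for m, keep in zip(all_markers, ~flanked) if keep],
                          regions=list(qtl_regions), flank_mb=flank_mb)
    return sets


@dataclass
class GPAResult:
    strategy: str
    validation_breed: str
    trait: str
    snp_set: str
    gpa: float
    sd: float
    fold_stats: list  # (fold id, r_i, n_i)

    def to_dict(self):
        return {
            "strategy": self.strategy,
            "breed": self.validation_breed,
            "trait": self.trait,
            "snp_set": self.snp_set,
            "gpa": self.gpa,
            "sd": self.sd,
            "n_folds": len(self.fold_stats),
        }


def _fit_and_predict(genotypes, pheno_train, pheno_valid, genotypes_valid, trait,
                     config, snp_markers):
    model = BayesAlphabet(genotypes, pheno_train, trait, config)
    res = model.fit()
    gebv = res.predict(genotypes_valid.take_samples(pheno_valid["animal"].tolist()),
                       snp_set=snp_markers)
    ystar = adjust_phenotypes(pheno_valid, trait, res.posterior_mean_fixed(), res.design)
    return gebv.to_numpy(), ystar.to_numpy()


def run_strategy(
    strategy: str,
    breeds: dict,
    trait: str,
    h2: dict,
    config: ChainConfig,
    folds: dict | None = None,
    snp_sets: dict | None = None,
    validation_breed: str | None = None,
) -> list:
    """Run one prediction strategy and return a list of GPAResult.

    ``breeds`` maps breed label -> (GenotypeData, phenotype DataFrame);
    ``h2`` maps breed -> pedigree heritability (the validation breed's
    estimate is always the GPA denominator); ``folds`` maps breed ->
    FoldAssignment (required for within/multi). ``snp_sets`` maps label
    -> SNPSet; default is ALL markers. Training always uses all markers;
    the SNP set restricts prediction only. Marker effects in between/
    multi runs are trained on the breeds' common marker panel.
    """
    if strategy not in ("within", "between", "multi"):
        raise ValueError(f"unknown strategy {strategy!r}")
    labels = list(breeds)
    out = []
    targets = [validation_breed] if validation_breed else labels

    def seed_for(tag):
        # process-stable seed derivation (crc32, not Python's salted hash)
        import zlib

        return (config.seed * 1_000_003 + zlib.crc32(repr(tag).encode())) % (2**31 - 1)

    for vb in targets:
        g_v, ph_v = breeds[vb]
        sets = snp_sets or {"ALL": SNPSet("ALL", list(g_v.markers))}
        for set_label, sset in sets.items():
            if strategy == "within":
                fa = folds[vb]
                stats = []
                for f in range(fa.n_folds):
                    va = fa.animals(f)
                    tr_ph = ph_v[~ph_v["animal"].isin(va)]
                    va_ph = ph_v[ph_v["animal"].isin(va)].dropna(subset=[trait])
                    cfg = replace(config, seed=seed_for((vb, set_label, f)))
                    gebv, ystar = _fit_and_predict(
                        g_v.take_samples(tr_ph["animal"].tolist()), tr_ph, va_ph, g_v,
                        trait, cfg, sset.markers,
                    )
                    if np.std(gebv) == 0:
                        warnings.warn(f"fold {f}: zero-variance GEBV", stacklevel=2)
                        continue
                    stats.append((f, float(np.corrcoef(gebv, ystar)[0, 1]), len(va_ph)))
                gpa, sd = gpa_cv([(r, n) for _, r, n in stats], h2[vb])
                out.append(GPAResult(strategy, vb, trait, set_label, gpa, sd, stats))
            elif strategy == "between":
                tb = [b for b in labels if b != vb]
                if len(tb) != 1:
                    raise ValueError("between-breed strategy needs exactly two breeds")
                g_t, ph_t = breeds[tb[0]]
                common = [m for m in g_t.markers if m in set(g_v.markers)]
                if not common:
                    raise ValueError("no common markers between breeds")
                mpos_t = {m: i for i, m in enumerate(g_t.markers)}
                mpos_v = {m: i for i, m in enumerate(g_v.markers)}
                g_t2 = g_t.subset(marker_idx=[mpos_t[m] for m in common])
                g_v2 = g_v.subset(marker_idx=[mpos_v[m] for m in common])
                va_ph = ph_v.dropna(subset=[trait])
                cfg = replace(config, seed=seed_for((vb, set_label, "between")))
                snps = [m for m in sset.markers if m in set(common)]
                gebv, ystar = _fit_and_predict(
                    g_t2.take_samples(ph_t["animal"].tolist()), ph_t, va_ph, g_v2,
                    trait, cfg, snps,
                )
                gpa = gpa_single(gebv, ystar, h2[vb])
                out.append(
                    GPAResult(strategy, vb, trait, set_label, gpa, np.nan,
                              [(0, gpa * np.sqrt(h2[vb]), len(va_ph))])
                )
            else:  # multi
                fa = folds[vb]
                stats = []
                for f in range(fa.n_folds):
                    va = fa.animals(f)
                    va_ph = ph_v[ph_v["animal"].isin(va)].dropna(subset=[trait])
                    # training: both breeds minus the validation fold
                    tr_parts, g_parts = [], []
                    for b in labels:
                        g_b, ph_b = breeds[b]
                        keep = ph_b[~ph_b["animal"].isin(va)]
                        tr_parts.append(keep)
                        g_parts.append(g_b)
                    common = set(g_parts[0].markers)
                    for gp in g_parts[1:]:
                        common &= set(gp.markers)
                    common = [m for m in g_parts[0].markers if m in common]
                    calls = []
                    samples = []
                    for gp, php in zip(g_parts, tr_parts):
                        mpos = {m: i for i, m in enumerate(gp.markers)}
                        sub = gp.take_samples(php["animal"].tolist()).subset(
                            marker_idx=[mpos[m] for m in common]
                        )
                        calls.append(sub.calls)
                        samples.extend(sub.samples)
                    from .io_qc import GenotypeData

                    mpos0 = {m: i for i, m in enumerate(g_parts[0].markers)}
                    map_common = g_parts[0].map.iloc[[mpos0[m] for m in common]]
                    g_train = GenotypeData(
                        samples=samples, markers=common,
                        calls=np.vstack(calls), map=map_common,
                    )
                    ph_train = pd.concat(tr_parts, ignore_index=True)
                    mpos_v = {m: i for i, m in enumerate(g_v.markers)}
                    g_v2 = g_v.subset(marker_idx=[mpos_v[m] for m in common])
                    cfg = replace(config, seed=seed_for((vb, set_label, "multi", f)))
                    snps = [m for m in sset.markers if m in set(common)]
                    gebv, ystar = _fit_and_predict(
                        g_train, ph_train, va_ph, g_v2, trait, cfg, snps,
                    )
                    if np.std(gebv) == 0:
                        warnings.warn(f"fold {f}: zero-variance GEBV", stacklevel=2)
                        continue
                    stats.append((f, float(np.corrcoef(gebv, ystar)[0, 1]), len(va_ph)))
                gpa, sd = gpa_cv([(r, n) for _, r, n in stats], h2[vb])
                out.append(GPAResult(strategy, vb, trait, set_label, gpa, sd, stats))
    return out


def results_frame(results: list) -> pd.DataFrame:
    """GPAResult list -> tidy DataFrame (one row per strategy/breed/set)."""
    return pd.DataFrame([r.to_dict() for r in results])
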