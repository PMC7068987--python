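"""File I/O and genotype quality control.

Supported dialects
------------------
* PLINK-1 ped/map: whitespace-separated, two allele columns per marker
  with A/C/G/T calls and ``0`` for missing; positions are 1-based bp.
* TSV dosage matrix: header row of marker IDs, one row per animal, cells
  are dosages in {0, 1, 2} (or real-valued after imputation), ``NA`` for
  missing; an accompanying map TSV gives (marker, chrom, pos).
* Pedigree CSV: columns animal,sire,dam with 0/empty for unknown founders.
* Phenotype CSV: named columns animal,breed,line,cg,litter,bw,vh,vw[,va].

QC pipeline
-----------
:func:`apply_genotype_qc` applies, in order: (1) replacement of low-
quality calls (GenCall score below a threshold) by the within-breed mean
dosage of the marker, (2) removal of samples with low call rate,
(3) removal of markers with low call rate, (4) removal of markers with
minor allele frequency below a floor, computed on the retained samples.
Imputed dosages are real-valued means (variance-preserving for
mixed-model use); MAF is computed from the dosage mean p = mean/2 over
non-missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree_csv",
    "read_phenotypes",
    "apply_genotype_qc",
    "derive_va",
]


class ParseError(ValueError):
    pass


@dataclass
class GenotypeData:
    """SNP genotypes for a set of animals.

    ``calls`` is an (n_samples, n_markers) float array of allele dosages
    in {0, 1, 2} (real-valued after mean imputation) with NaN for missing.
    ``map`` is a DataFrame indexed like ``markers`` with integer columns
    ``chrom`` (1-18 for the pig autosomes) and ``pos`` (bp, 1-based),
    sorted by (chrom, pos). ``quality`` optionally holds per-call scores
    in [0, 1] (e.g. Illumina GenCall).
    """

    samples: list
    markers: list
    calls: np.ndarray
    map: pd.DataFrame
    quality: np.ndarray | None = None

    def __post_init__(self):
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError("calls dimensions do not match samples x markers")
        if len(self.map) != m:
            raise ValueError("map length does not match markers")
        if not (self.map.index == pd.Index(self.markers)).all():
            raise ValueError("map index must parallel markers")
        key = self.map[["chrom", "pos"]].to_numpy()
        if len(key) > 1 and not all(
            tuple(key[i]) <= tuple(key[i + 1]) for i in range(len(key) - 1)
        ):
            raise ValueError("map must be sorted by (chrom, pos)")
        if self.quality is not None and self.quality.shape != self.calls.shape:
            raise ValueError("quality dimensions do not match calls")

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_markers(self):
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Per-marker allele frequency p = mean(dosage)/2 over non-missing calls."""
        return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeData":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeData(
            samples=[self.samples[i] for i in si],
            markers=[self.markers[j] for j in mi],
            calls=self.calls[np.ix_(si, mi)],
            map=self.map.iloc[mi],
            quality=None if self.quality is None else self.quality[np.ix_(si, mi)],
        )

    def take_samples(self, animals) -> "GenotypeData":
        pos = {a: i for i, a in enumerate(self.samples)}
        return self.subset(sample_idx=[pos[a] for a in animals])


@dataclass
class QCReport:
    n_samples_in: int
    n_markers_in: int
    calls_imputed_low_quality: int = 0
    samples_removed_call_rate: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_all_missing: int = 0
    markers_removed_maf: int = 0
    n_samples_out: int = 0
    n_markers_out: int = 0

    def check(self):
        assert self.n_samples_in - self.samples_removed_call_rate == self.n_samples_out
        assert (
            self.n_markers_in
            - self.markers_removed_call_rate
            - self.markers_removed_all_missing
            - self.markers_removed_maf
            == self.n_markers_out
        )


_ALLELES = {"A", "C", "G", "T"}


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 map columns, got {len(parts)}")
            try:
                chrom = int(parts[0])
                pos = int(parts[3])
            except ValueError:
                raise ParseError(f"{map_path}:{lineno}: non-integer chromosome or position") from None
            if pos < 0:
                raise ParseError(f"{map_path}:{lineno}: negative position")
            rows.append((parts[1], chrom, pos))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "pos"]).set_index("marker")
    return df


def read_genotypes(path, format="ped", map_path=None) -> GenotypeData:
    """Read genotypes from disk.

    ``format="ped"``: ``path`` is the .ped file; ``map_path`` defaults to
    the same stem with .map. Dosage is the count of the marker's minor
    allele (alleles ranked by frequency, ties broken alphabetically);
    ``0 0`` (or one ``0``) is missing.

    ``format="dosage"``: ``path`` is a TSV with header ``animal`` then
    marker IDs; ``map_path`` is a TSV with columns marker, chrom, pos.
    """
    if format == "ped":
        map_path = map_path or str(path).rsplit(".", 1)[0] + ".map"
        mp = _read_map(map_path)
        m = len(mp)
        samples, raw = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 6 + 2 * m:
                    raise ParseError(
                        f"{path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                    )
                animal = parts[1]
                if animal in samples:
                    raise ParseError(f"{path}:{lineno}: duplicate animal ID {animal!r}")
                alleles = parts[6:]
                for a in alleles:
                    if a not in _ALLELES and a != "0":
                        raise ParseError(f"{path}:{lineno}: bad allele code {a!r}")
                samples.append(animal)
                raw.append(alleles)
        raw = np.array(raw).reshape(len(samples), m, 2) if samples else np.empty((0, m, 2), dtype="U1")
        calls = np.full((len(samples), m), np.nan)
        for j in range(m):
            pair = raw[:, j, :]
            missing = (pair == "0").any(axis=1)
            present = pair[~missing]
            counts: dict = {}
            for a in present.ravel():
                counts[a] = counts.get(a, 0) + 1
            if counts:
                # dosage counts the minor allele; ties broken alphabetically
                minor = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))[0][0]
                calls[~missing, j] = (present == minor).sum(axis=1)
        order = np.lexsort((mp["pos"].to_numpy(), mp["chrom"].to_numpy()))
        mp = mp.iloc[order]
        calls = calls[:, order]
        return GenotypeData(samples=samples, markers=mp.index.tolist(), calls=calls, map=mp)
    elif format == "dosage":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        if df.index.duplicated().any():
            raise ParseError("duplicate animal ID in dosage matrix")
        mp = pd.read_csv(map_path, sep="\t").set_index("marker")[["chrom", "pos"]]
        mp = mp.loc[df.columns]
        order = np.lexsort((mp["pos"].to_numpy(), mp["chrom"].to_numpy()))
        mp = mp.iloc[order]
        df = df[mp.index]
        return GenotypeData(
            samples=df.index.tolist(),
            markers=df.columns.tolist(),
            calls=df.to_numpy(dtype=float),
            map=mp,
        )
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeData, path, map_path) -> None:
    """Write the TSV dosage dialect (round-trips through read_genotypes)."""
    df = pd.DataFrame(g.calls, index=pd.Index(g.samples, name="animal"), columns=g.markers)
    df.to_csv(path, sep="\t", na_rep="NA")
    g.map.rename_axis("marker").to_csv(map_path, sep="\t")


def read_pedigree_csv(path):
    """Pedigree CSV (animal,sire,dam; 0/empty = unknown) -> Pedigree."""
    from .pedigree_kinship import Pedigree

    df = pd.read_csv(path, dtype=str).fillna("")
    return Pedigree.from_records(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))


PHENO_COLUMNS = ["animal", "breed", "line", "cg", "litter", "bw", "vh", "vw"]


def read_phenotypes(path, require_va=False) -> pd.DataFrame:
    """Phenotype CSV -> validated DataFrame.

    Checks that VA = VH x VW wherever all three are present, that VH/VW
    are non-negative, and that no animal is duplicated.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype file missing columns: {missing}")
    validate_phenotypes(df, require_va=require_va)
    return df


def validate_phenotypes(df: pd.DataFrame, require_va=False) -> None:
    if df["animal"].duplicated().any():
        dups = df.loc[df["animal"].duplicated(), "animal"].tolist()
        raise ValueError(f"duplicate phenotype records for animals: {dups[:5]}")
    for col in ("vh", "vw"):
        if col in df and (df[col].dropna() < 0).any():
            raise ValueError(f"negative {col.upper()} values")
    if require_va and "va" not in df.columns:
        raise ValueError("va column required but absent")
    if "va" in df.columns and {"vh", "vw"} <= set(df.columns):
        ok = df[["va", "vh", "vw"]].dropna()
        if not np.allclose(ok["va"], ok["vh"] * ok["vw"], rtol=1e-6, atol=1e-6):
            raise ValueError("VA != VH x VW for some records")


def derive_va(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite the vulva-area column as the product VH x VW (mm^2)."""
    if not {"vh", "vw"} <= set(pheno.columns):
        raise ValueError("vh and vw columns required")
    if (pheno["vh"].dropna() < 0).any() or (pheno["vw"].dropna() < 0).any():
        raise ValueError("negative VH or VW")
    out = pheno.copy()
    out["va"] = out["vh"] * out["vw"]
    return out


def apply_genotype_qc(
    g: GenotypeData,
    gencall_min: float | None = 0.20,
    maf_min: float = 0.01,
    call_rate_min: float = 0.8,
    group: dict | pd.Series | None = None,
) -> tuple[GenotypeData, QCReport]:
    """Apply genotype QC; see the module docstring for the step order.

    ``group`` maps animal ID -> breed label for within-breed imputation of
    low-quality calls; when omitted all samples form one group. A marker
    with every call missing within a group cannot be imputed there and is
    dropped (tallied separately in the report).
    """
    report = QCReport(n_samples_in=g.n_samples, n_markers_in=g.n_markers)
    calls = g.calls.copy()

    if group is None:
        glabels = np.zeros(g.n_samples, dtype=int)
    else:
        getter = group.get if hasattr(group, "get") else group.__getitem__
        labels = [getter(a) for a in g.samples]
        if any(l is None for l in labels):
            raise ValueError("group does not cover all samples")
        _, glabels = np.unique(np.array(labels, dtype=object), return_inverse=True)

    # (1) replace low-GenCall calls with the within-group mean dosage
    if gencall_min is not None and g.quality is not None:
        low = (g.quality < gencall_min) & ~np.isnan(calls)
        for grp in np.unique(glabels):
            rows = glabels == grp
            sub = calls[rows]
            sub_low = low[rows]
            with np.errstate(invalid="ignore"):
                means = np.nanmean(np.where(sub_low, np.nan, sub), axis=0)
            filled = np.where(sub_low, means[None, :], sub)
            report.calls_imputed_low_quality += int(sub_low.sum())
            calls[rows] = filled
        # calls that had no clean within-group mean remain NaN and fall to
        # the call-rate / all-missing filters below

    # (2) drop samples with low call rate
    sample_cr = 1.0 - np.isnan(calls).mean(axis=1)
    keep_s = sample_cr >= call_rate_min
    report.samples_removed_call_rate = int((~keep_s).sum())
    calls = calls[keep_s]
    glabels = glabels[keep_s]

    # (3) drop markers with low call rate (on retained samples)
    if calls.shape[0] == 0:
        marker_cr = np.zeros(calls.shape[1])
    else:
        marker_cr = 1.0 - np.isnan(calls).mean(axis=0)
    keep_m = marker_cr >= call_rate_min
    report.markers_removed_call_rate = int((~keep_m).sum())
    calls = calls[:, keep_m]

    # remaining missing calls: impute within-group mean; markers fully
    # missing within a group are dropped (cannot impute)
    drop_all_missing = np.zeros(calls.shape[1], dtype=bool)
    for grp in np.unique(glabels):
        rows = glabels == grp
        sub = calls[rows]
        if sub.shape[0] == 0:
            continue
        all_missing = np.isnan(sub).all(axis=0)
        drop_all_missing |= all_missing
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=0)
        nanmask = np.isnan(sub)
        sub[nanmask] = np.broadcast_to(means, sub.shape)[nanmask]
        calls[rows] = sub
    report.markers_removed_all_missing = int(drop_all_missing.sum())
    calls = calls[:, ~drop_all_missing]

    # (4) MAF filter on the final sample set
    if calls.shape[0]:
        p = calls.mean(axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
    else:
        maf = np.zeros(calls.shape[1])
    keep_maf = maf >= maf_min
    report.markers_removed_maf = int((~keep_maf).sum())
    calls = calls[:, keep_maf]

    marker_keep = np.flatnonzero(keep_m)
    marker_keep = marker_keep[~drop_all_missing]
    marker_keep = marker_keep[keep_maf]
    out = GenotypeData(
        samples=[s for s, k in zip(g.samples, keep_s) if k],
        markers=[g.markers[j] for j in marker_keep],
        calls=calls,
        map=g.map.iloc[marker_keep],
        quality=None,
    )
    report.n_samples_out = out.n_samples
    report.n_markers_out = out.n_markers
    report.check()
    return out, report
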