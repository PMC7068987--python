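"""Pedigree and genomic relationship machinery.

The additive (numerator) relationship matrix **A** encodes the expected
proportion of alleles shared identical-by-descent between every pair of
animals in a pedigree; its diagonal is 1 + F_i where F_i is the inbreeding
coefficient. **A** is the covariance structure of the additive-genetic
random effect in the animal model. The marker-based analogue **G**
(VanRaden method 1) is the centred cross-product of allele dosages scaled
by the expected heterozygosity, and is used here only for descriptive
summaries of relatedness within and between cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "build_A",
    "inbreeding",
    "build_G",
    "fold_relationship_summary",
]

UNKNOWN = 0  # internal code for an unknown founder parent


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """An ordered pedigree: parents precede offspring.

    Animals are identified by arbitrary hashable IDs. Unknown parents are
    ``None`` (missing founders). Construction topologically sorts the
    records and rejects cycles and references to absent animals.
    """

    ids: list
    sire: np.ndarray  # int index into ids, or -1 for unknown
    dam: np.ndarray
    generation: np.ndarray | None = None
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._pos = {a: i for i, a in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise PedigreeError("duplicate animal IDs in pedigree")

    @classmethod
    def from_records(cls, records, generation=None) -> "Pedigree":
        """Build from an iterable of (animal, sire, dam) triples.

        ``sire``/``dam`` may be None, 0, "" or "0" for unknown. Records are
        topologically sorted so parents precede offspring; a cycle raises
        with the offending animals named.
        """
        recs = []
        for a, s, d in records:
            s = None if s in (None, 0, "", "0") or (isinstance(s, float) and np.isnan(s)) else s
            d = None if d in (None, 0, "", "0") or (isinstance(d, float) and np.isnan(d)) else d
            recs.append((a, s, d))
        parents = {a: (s, d) for a, s, d in recs}
        if len(parents) != len(recs):
            raise PedigreeError("duplicate animal IDs in pedigree")
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None and p not in parents:
                    raise PedigreeError(f"animal {a!r} references unknown parent {p!r}")
        # Kahn-style topological sort, stable in input order
        order: list = []
        state: dict = {}

        def visit(a, stack):
            st = state.get(a)
            if st == 2:
                return
            if st == 1:
                cyc = stack[stack.index(a):] + [a]
                raise PedigreeError(f"pedigree cycle detected: {' -> '.join(map(repr, cyc))}")
            state[a] = 1
            stack.append(a)
            s, d = parents[a]
            for p in (s, d):
                if p is not None:
                    visit(p, stack)
            stack.pop()
            state[a] = 2
            order.append(a)

        for a, _, _ in recs:
            visit(a, [])
        pos = {a: i for i, a in enumerate(order)}
        sire = np.array([pos[parents[a][0]] if parents[a][0] is not None else -1 for a in order])
        dam = np.array([pos[parents[a][1]] if parents[a][1] is not None else -1 for a in order])
        gen = None
        if generation is not None:
            gen = np.array([generation[a] for a in order])
        return cls(ids=order, sire=sire, dam=dam, generation=gen)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal="animal", sire="sire", dam="dam") -> "Pedigree":
        return cls.from_records(df[[animal, sire, dam]].itertuples(index=False, name=None))

    def __len__(self):
        return len(self.ids)

    def index_of(self, animals) -> np.ndarray:
        try:
            return np.array([self._pos[a] for a in animals])
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.ids
        return pd.DataFrame(
            {
                "animal": ids,
                "sire": [ids[s] if s >= 0 else None for s in self.sire],
                "dam": [ids[d] if d >= 0 else None for d in self.dam],
            }
        )


@dataclass
class RelationshipMatrix:
    """A square relationship matrix indexed by animal ID.

    ``kind`` records provenance: ``"A"`` (pedigree numerator) or ``"G"``
    (marker-based).
    """

    values: np.ndarray
    ids: list
    kind: str = "A"

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of IDs")
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, animals) -> np.ndarray:
        idx = np.array([self._pos[a] for a in animals])
        return self.values[np.ix_(idx, idx)]

    def to_csv(self, path):
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    def save(self, path_prefix):
        """Persist as a .npy array plus an ID-index sidecar CSV."""
        np.save(f"{path_prefix}.npy", self.values)
        pd.Series(self.ids, name="animal").to_csv(f"{path_prefix}.ids.csv", index=False)

    @classmethod
    def load(cls, path_prefix, kind="A"):
        values = np.load(f"{path_prefix}.npy")
        ids = pd.read_csv(f"{path_prefix}.ids.csv")["animal"].tolist()
        return cls(values=values, ids=ids, kind=kind)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 a_{sire,dam}; a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)}),
    with an unknown parent contributing zero. Requires the pedigree's
    topological order (guaranteed by :class:`Pedigree`).
    """
    n = len(ped)
    if n == 0:
        raise PedigreeError("empty pedigree")
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        asd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(values=A, ids=list(ped.ids), kind="A")


def inbreeding(ped: Pedigree) -> tuple[pd.Series, float]:
    """Per-animal inbreeding coefficients F_i = a_ii - 1.

    Returns the per-animal series and the mean F over animals with F > 0
    (the convention of reporting mean inbreeding among inbred animals
    only). If no animal is inbred the mean is reported as 0.0.
    """
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    A = build_A(ped)
    F = pd.Series(np.diag(A.values) - 1.0, index=pd.Index(ped.ids, name="animal"), name="F")
    inbred = F[F > 1e-12]
    mean_inbred = float(inbred.mean()) if len(inbred) else 0.0
    return F, mean_inbred


def build_G(genotypes, samples=None) -> RelationshipMatrix:
    """Genomic relationship matrix (VanRaden method 1).

    ``genotypes`` is a GenotypeData (from :mod:`giltqg.io_qc`) or a plain
    (n_samples, n_markers) dosage array. Allele frequencies are taken from
    the analysed samples: G = Z Z' / (2 sum p_k (1-p_k)) with
    Z = M - 2p.
    """
    if hasattr(genotypes, "calls"):
        M = np.asarray(genotypes.calls, dtype=float)
        ids = list(genotypes.samples)
    else:
        M = np.asarray(genotypes, dtype=float)
        ids = list(samples) if samples is not None else list(range(M.shape[0]))
    if np.isnan(M).any():
        raise ValueError("missing calls present; run QC/imputation first")
    p = M.mean(axis=0) / 2.0
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0:
        raise ValueError("all markers monomorphic: G denominator is zero")
    Z = M - 2.0 * p
    G = Z @ Z.T / het
    return RelationshipMatrix(values=G, ids=ids, kind="G")


def fold_relationship_summary(R: RelationshipMatrix, folds: dict) -> pd.DataFrame:
    """Mean relationship within and between cross-validation folds.

    ``folds`` maps fold label -> list of animal IDs; the folds must
    partition (a subset of) the matrix's animals. Within-fold entries
    average off-diagonal pairs only (relationships among distinct
    animals); self-relationships would inflate the within-fold mean and
    are reported separately via the matrix diagonal. A fold with fewer
    than two animals has an undefined within-fold mean (NaN).
    """
    labels = list(folds)
    seen: set = set()
    for f in labels:
        members = set(folds[f])
        if members & seen:
            raise ValueError("folds overlap")
        seen |= members
    idx = {f: np.array([R._pos[a] for a in folds[f]]) for f in labels}
    out = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, f in enumerate(labels):
        for g in labels[i:]:
            block = R.values[np.ix_(idx[f], idx[g])]
            if f == g:
                n = len(idx[f])
                if n < 2:
                    val = np.nan
                else:
                    off = block[~np.eye(n, dtype=bool)]
                    val = float(off.mean())
            else:
                val = float(block.mean())
            out.loc[f, g] = val
            out.loc[g, f] = val
    return out
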