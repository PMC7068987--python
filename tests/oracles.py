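"""Independent oracles used by the tests.

The Wright path-coefficient computation of additive relationships is a
different algorithm from the tabular recursion it checks: it enumerates
all non-overlapping ancestral path pairs through common ancestors,
a_ij = sum over paths (1/2)^(n1+n2) (1 + F_A), with the common
ancestor's own inbreeding computed recursively the same way. Only
feasible for tiny pedigrees, which is the point.
"""

import numpy as np


def _paths_up(x, parents):
    """All ascending paths from x: lists [x, parent, ..., ancestor]."""
    out = [[x]]
    s, d = parents[x]
    for p in (s, d):
        if p is not None:
            out.extend([[x] + path for path in _paths_up(p, parents)])
    return out


def wright_relationship(i, j, parents, _fmemo=None):
    """Numerator relationship a_ij by Wright's path counting."""
    if _fmemo is None:
        _fmemo = {}

    def F(x):
        if x not in _fmemo:
            s, d = parents[x]
            _fmemo[x] = 0.0 if s is None or d is None else 0.5 * a(s, d)
        return _fmemo[x]

    def a(x, y):
        if x == y:
            return 1.0 + F(x)
        total = 0.0
        for p1 in _paths_up(x, parents):
            for p2 in _paths_up(y, parents):
                if p1[-1] != p2[-1]:
                    continue
                anc = p1[-1]
                if set(p1) & set(p2) != {anc}:
                    continue
                total += 0.5 ** (len(p1) - 1 + len(p2) - 1) * (1.0 + F(anc))
        return total

    return a(i, j)


def wright_A(records):
    """Full A matrix by path counting for a tiny pedigree.

    ``records``: iterable of (animal, sire-or-None, dam-or-None) in any
    valid order.
    """
    parents = {a: (s, d) for a, s, d in records}
    ids = list(parents)
    n = len(ids)
    A = np.zeros((n, n))
    fmemo = {}
    for x in range(n):
        for y in range(x, n):
            A[x, y] = A[y, x] = wright_relationship(ids[x], ids[y], parents, fmemo)
    return ids, A


def random_pedigree(rng, n_max=12):
    """A random valid pedigree of at most n_max animals (founder-biased;
    parents always earlier animals, sire != dam)."""
    n = int(rng.integers(3, n_max + 1))
    recs = []
    for i in range(n):
        aid = f"x{i}"
        sire = dam = None
        if i >= 2 and rng.random() < 0.7:
            k = rng.choice(i, size=2, replace=False)
            sire, dam = f"x{k[0]}", f"x{k[1]}"
        elif i >= 1 and rng.random() < 0.2:
            sire = f"x{int(rng.integers(i))}"
        recs.append((aid, sire, dam))
    return recs
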