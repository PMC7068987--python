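"""Fixed-effects design matrices shared by the Gibbs samplers and the
prediction pipeline (intercept + treatment-coded factors + centred
covariates), with stable level maps so a design fitted on training data
can be re-applied to validation animals."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class FixedDesign:
    def __init__(self, factors=("line", "cg"), covariates=("bw",)):
        self.factors = tuple(factors)
        self.covariates = tuple(covariates)
        self.levels: dict = {}
        self.centers: dict = {}
        self.names: list = []

    def fit(self, df: pd.DataFrame) -> "FixedDesign":
        self.names = ["mu"]
        for f in self.factors:
            levs = list(pd.unique(df[f].dropna()))
            self.levels[f] = levs
            self.names += [f"{f}[{lev}]" for lev in levs[1:]]
        for cv in self.covariates:
            self.centers[cv] = float(np.nanmean(df[cv].to_numpy(dtype=float)))
            self.names.append(cv)
        return self

    def build(self, df: pd.DataFrame, warn_unseen=True) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        for f in self.factors:
            levs = self.levels[f]
            vals = df[f].to_numpy()
            unseen = set(vals) - set(levs)
            if unseen and warn_unseen:
                warnings.warn(
                    f"factor {f!r}: unseen level(s) {sorted(map(str, unseen))} treated as reference",
                    stacklevel=2,
                )
            for lev in levs[1:]:
                cols.append((vals == lev).astype(float))
        for cv in self.covariates:
            cols.append(df[cv].to_numpy(dtype=float) - self.centers[cv])
        return np.column_stack(cols)
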