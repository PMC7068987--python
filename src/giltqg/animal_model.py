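"""Pedigree-based mixed ("animal") model fitted by REML.

The model for a vulva-size trait y of animal k is

    y_ijkl = mu + L_i + CG_j + b*BW_k + a_k + d_l + e_ijkl

with line L and contemporary group CG as fixed factors, body weight BW a
fixed covariate, a ~ N(0, A sigma2_a) the additive-genetic effect (A the
pedigree numerator relationship matrix), d ~ N(0, I sigma2_d) the common
litter environment, and e ~ N(0, I sigma2_e). Heritability is
h2 = sigma2_a / (sigma2_a + sigma2_d + sigma2_e) and the litter
(common-environment) ratio c2 = sigma2_d / (same denominator).

Estimation is restricted maximum likelihood with average-information (AI)
updates and a guarded fallback: steps that leave the parameter space or
reduce the likelihood are halved, and if that fails a multiplicative
fixed-point step (an expectation-maximisation-style update, positive by
construction) is taken on the variance parameters. Standard errors of
ratios and correlations come from the delta method on the inverse AI
matrix. Bivariate fits estimate 2x2 genetic, litter, and residual
covariance matrices (constrained positive semi-definite by eigenvalue
clipping) and report genetic (r_G) and phenotypic (r_P) correlations.

The implementation is dense linear algebra on the phenotyped animals
(the additive covariance among them is the corresponding submatrix of
A), appropriate for cohorts of a few thousand records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree_kinship import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "AnimalModel",
    "AnimalModelResults",
    "heritability_from_components",
]


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


def heritability_from_components(sigma2_a: float, sigma2_e: float, c2: float) -> float:
    """Heritability implied by additive and residual variances and the
    litter ratio: sigma2_p = (sigma2_a + sigma2_e)/(1 - c2),
    h2 = sigma2_a / sigma2_p.

    This back-computes h2 from the components as they are conventionally
    tabulated (variances in trait units squared, c2 as a ratio).
    """
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    if not 0.0 <= c2 < 1.0:
        raise ValueError("c2 must be in [0, 1)")
    sigma2_p = (sigma2_a + sigma2_e) / (1.0 - c2)
    return sigma2_a / sigma2_p


@dataclass
class ModelSpec:
    """Specification of the animal-model design.

    ``traits`` holds one trait name (univariate) or two (bivariate).
    Fixed factors and covariates name phenotype-table columns; covariates
    are centred before fitting (numerical conditioning only — variance
    estimates are unchanged).
    """

    traits: tuple
    fixed: tuple = ("line", "cg")
    covariates: tuple = ("bw",)
    include_litter: bool = True
    animal: str = "animal"
    litter: str = "litter"

    def __post_init__(self):
        if isinstance(self.traits, str):
            self.traits = (self.traits,)
        self.traits = tuple(self.traits)
        if len(self.traits) not in (1, 2):
            raise ValueError("one (univariate) or two (bivariate) traits required")


@dataclass
class AnimalModelResults:
    """REML estimates with delta-method uncertainty.

    ``varcomp`` maps component name ("animal", "litter", "residual") to a
    scalar (univariate) or 2x2 covariance matrix (bivariate). Ratios
    (h2, c2) and correlations (r_g, r_p) always recompute exactly from
    ``varcomp``.
    """

    spec: ModelSpec
    params: np.ndarray
    param_names: list
    cov_params: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    fixed_effects: pd.Series
    fixed_cov: np.ndarray
    boundary: list = field(default_factory=list)
    trace: list = field(default_factory=list)

    # -- component access -------------------------------------------------
    def _theta(self, name):
        return {n: v for n, v in zip(self.param_names, self.params)}[name]

    @property
    def bivariate(self):
        return len(self.spec.traits) == 2

    def varcomp(self) -> dict:
        comps = ["animal", "litter", "residual"] if self.spec.include_litter else ["animal", "residual"]
        out = {}
        for c in comps:
            if self.bivariate:
                out[c] = np.array(
                    [
                        [self._theta(f"{c}_11"), self._theta(f"{c}_12")],
                        [self._theta(f"{c}_12"), self._theta(f"{c}_22")],
                    ]
                )
            else:
                out[c] = self._theta(f"{c}_11")
        return out

    def _ratio(self, which, trait_idx=0):
        vc = self.varcomp()
        suffix = "_11" if trait_idx == 0 else "_22"
        comps = list(vc)
        vals = {c: (vc[c][trait_idx, trait_idx] if self.bivariate else vc[c]) for c in comps}
        total = sum(vals.values())
        num = vals["animal"] if which == "h2" else vals.get("litter", 0.0)
        ratio = num / total
        # delta method on the parameter vector
        grad = np.zeros(len(self.params))
        for i, name in enumerate(self.param_names):
            if not name.endswith(suffix):
                continue
            comp = name.rsplit("_", 1)[0]
            d_num = 1.0 if comp == ("animal" if which == "h2" else "litter") else 0.0
            grad[i] = (d_num * total - num) / total**2
        se = float(np.sqrt(max(0.0, grad @ self.cov_params @ grad)))
        return ratio, se

    @property
    def h2(self):
        if self.bivariate:
            return tuple(self._ratio("h2", t)[0] for t in range(2))
        return self._ratio("h2")[0]

    @property
    def h2_se(self):
        if self.bivariate:
            return tuple(self._ratio("h2", t)[1] for t in range(2))
        return self._ratio("h2")[1]

    @property
    def c2(self):
        if not self.spec.include_litter:
            return (0.0, 0.0) if self.bivariate else 0.0
        if self.bivariate:
            return tuple(self._ratio("c2", t)[0] for t in range(2))
        return self._ratio("c2")[0]

    @property
    def c2_se(self):
        if not self.spec.include_litter:
            return (0.0, 0.0) if self.bivariate else 0.0
        if self.bivariate:
            return tuple(self._ratio("c2", t)[1] for t in range(2))
        return self._ratio("c2")[1]

    def _corr(self, names11, names12, names22):
        """Correlation c12/sqrt(c11*c22) over summed components, with SE."""
        idx = {n: i for i, n in enumerate(self.param_names)}
        c11 = sum(self.params[idx[n]] for n in names11)
        c12 = sum(self.params[idx[n]] for n in names12)
        c22 = sum(self.params[idx[n]] for n in names22)
        denom = np.sqrt(c11 * c22)
        r = c12 / denom
        grad = np.zeros(len(self.params))
        for n in names12:
            grad[idx[n]] += 1.0 / denom
        for n in names11:
            grad[idx[n]] += -0.5 * c12 / (c11 * denom)
        for n in names22:
            grad[idx[n]] += -0.5 * c12 / (c22 * denom)
        se = float(np.sqrt(max(0.0, grad @ self.cov_params @ grad)))
        return float(r), se

    @property
    def r_g(self):
        if not self.bivariate:
            raise AttributeError("r_g requires a bivariate fit")
        return self._corr(["animal_11"], ["animal_12"], ["animal_22"])[0]

    @property
    def r_g_se(self):
        return self._corr(["animal_11"], ["animal_12"], ["animal_22"])[1]

    @property
    def r_p(self):
        if not self.bivariate:
            raise AttributeError("r_p requires a bivariate fit")
        comps = ["animal", "litter", "residual"] if self.spec.include_litter else ["animal", "residual"]
        return self._corr(
            [f"{c}_11" for c in comps], [f"{c}_12" for c in comps], [f"{c}_22" for c in comps]
        )[0]

    @property
    def r_p_se(self):
        comps = ["animal", "litter", "residual"] if self.spec.include_litter else ["animal", "residual"]
        return self._corr(
            [f"{c}_11" for c in comps], [f"{c}_12" for c in comps], [f"{c}_22" for c in comps]
        )[1]

    def estimate_correlation(self, comp_a="animal", comp_b="litter") -> float:
        """Sampling correlation between two variance estimates (from the
        inverse AI matrix) — a diagnostic for how separable the additive
        and litter components are in the data at hand."""
        idx = {n: i for i, n in enumerate(self.param_names)}
        i, j = idx[f"{comp_a}_11"], idx[f"{comp_b}_11"]
        d = np.sqrt(self.cov_params[i, i] * self.cov_params[j, j])
        return float(self.cov_params[i, j] / d) if d > 0 else np.nan

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per trait with variances, c2, h2 (and
        r_G/r_P for bivariate fits)."""
        vc = self.varcomp()
        rows = []
        for t, trait in enumerate(self.spec.traits):
            get = (lambda c: vc[c][t, t]) if self.bivariate else (lambda c: vc[c])
            h2 = self.h2[t] if self.bivariate else self.h2
            h2se = self.h2_se[t] if self.bivariate else self.h2_se
            c2 = self.c2[t] if self.bivariate else self.c2
            c2se = self.c2_se[t] if self.bivariate else self.c2_se
            rows.append(
                {
                    "trait": trait,
                    "sigma2_e": get("residual"),
                    "sigma2_a": get("animal"),
                    "sigma2_d": get("litter") if self.spec.include_litter else 0.0,
                    "c2": c2,
                    "c2_se": c2se,
                    "h2": h2,
                    "h2_se": h2se,
                }
            )
        df = pd.DataFrame(rows)
        if self.bivariate:
            df["r_g"] = self.r_g
            df["r_g_se"] = self.r_g_se
            df["r_p"] = self.r_p
            df["r_p_se"] = self.r_p_se
        return df

    def summary(self) -> str:
        lines = [
            "Animal model (REML)",
            f"  traits: {', '.join(self.spec.traits)}   n_obs: {self.n_obs}",
            f"  logL: {self.loglik:.4f}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
        ]
        if self.boundary:
            lines.append(f"  components at boundary: {', '.join(self.boundary)}")
        lines.append(self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class AnimalModel:
    """Mixed animal model ready to fit by REML.

    Construct via :meth:`from_dataframe` with a phenotype table and the
    pedigree relationship matrix. ``fit`` returns
    :class:`AnimalModelResults`.
    """

    def __init__(self, y, X, K_list, param_names, components, spec, fixed_names):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.K_list = K_list
        self.param_names = param_names
        self.components = components  # component name -> list of param indices
        self.spec = spec
        self.fixed_names = fixed_names

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, pheno: pd.DataFrame, A: RelationshipMatrix, spec: ModelSpec
    ) -> "AnimalModel":
        traits = spec.traits
        k = len(traits)
        sub = pheno.dropna(subset=[spec.animal]).copy()
        obs_rows = []  # (row index into sub, trait index)
        for t, trait in enumerate(traits):
            ok = sub[trait].notna()
            for ridx in np.flatnonzero(ok.to_numpy()):
                obs_rows.append((ridx, t))
        if not obs_rows:
            raise ValueError("no observations for requested trait(s)")
        ridx = np.array([r for r, _ in obs_rows])
        tidx = np.array([t for _, t in obs_rows])
        animals = sub[spec.animal].to_numpy()[ridx]
        y = np.concatenate([sub[traits[t]].to_numpy()[ridx[tidx == t]] for t in range(k)])
        # reorder observations trait-block-wise for readability
        order = np.argsort(tidx, kind="stable")
        ridx, tidx = ridx[order], tidx[order]
        animals = sub[spec.animal].to_numpy()[ridx]
        for t, trait in enumerate(traits):
            if np.std(sub.loc[sub[trait].notna(), trait]) == 0:
                raise ValueError(f"trait {trait!r} is constant")

        # fixed design per trait (separate fixed effects for each trait)
        blocks = []
        names = []
        for t, trait in enumerate(traits):
            rows = np.flatnonzero(tidx == t)
            dat = sub.iloc[ridx[rows]]
            cols = [np.ones(len(rows))]
            bnames = [f"{trait}:mu"]
            for f in spec.fixed:
                levels = pd.unique(sub[f].dropna())
                for lev in levels[1:]:  # first level absorbed in the mean
                    cols.append((dat[f] == lev).to_numpy(dtype=float))
                    bnames.append(f"{trait}:{f}[{lev}]")
            for cv in spec.covariates:
                x = dat[cv].to_numpy(dtype=float)
                cols.append(x - np.nanmean(sub[cv].to_numpy(dtype=float)))
                bnames.append(f"{trait}:{cv}")
            blocks.append(np.column_stack(cols))
            names.extend(bnames)
        n_obs = len(tidx)
        X = np.zeros((n_obs, sum(b.shape[1] for b in blocks)))
        c0 = 0
        for t, b in enumerate(blocks):
            rows = np.flatnonzero(tidx == t)
            X[rows, c0 : c0 + b.shape[1]] = b
            c0 += b.shape[1]
        # drop collinear columns (rank-deficient factor codings)
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        if not keep.all():
            X = X[:, keep]
            names = [n for n, k_ in zip(names, keep) if k_]

        # covariance bases
        A_sub = A.submatrix(animals)
        w = np.linalg.eigvalsh(A_sub)
        if w.min() < -1e-6:
            raise ValueError("relationship matrix is not positive semi-definite")
        same_animal = (animals[:, None] == animals[None, :]).astype(float)
        if spec.include_litter:
            lit = sub[spec.litter].to_numpy()[ridx]
            same_litter = (lit[:, None] == lit[None, :]).astype(float)
        bases = {"animal": A_sub, "residual": same_animal}
        if spec.include_litter:
            bases["litter"] = same_litter
        comp_order = ["animal", "litter", "residual"] if spec.include_litter else ["animal", "residual"]

        K_list, param_names, components = [], [], {}
        for comp in comp_order:
            B = bases[comp]
            components[comp] = []
            if k == 1:
                K_list.append(B)
                param_names.append(f"{comp}_11")
                components[comp].append(len(K_list) - 1)
            else:
                for (t, u) in ((0, 0), (0, 1), (1, 1)):
                    mask = ((tidx[:, None] == t) & (tidx[None, :] == u)).astype(float)
                    if t != u:
                        mask = mask + mask.T
                    K_list.append(B * mask)
                    param_names.append(f"{comp}_{t+1}{u+1}")
                    components[comp].append(len(K_list) - 1)
        return cls(y, X, K_list, param_names, components, spec, names)

    # -- REML internals ---------------------------------------------------
    def _fit_eigen(self, max_iter=100, tol=1e-6, start=None, verbose=False) -> AnimalModelResults:
        n = len(self.y)
        lam, Q = np.linalg.eigh(self.K_list[0])
        lam = np.maximum(lam, 0.0)
        yt = Q.T @ self.y
        Xt = Q.T @ self.X
        vary = float(np.var(self.y))
        floor = 1e-8 * max(vary, 1e-12)
        theta = np.array([vary / 2, vary / 2]) if start is None else np.asarray(start, float).copy()
        theta, ll, AI, trace, converged, beta, fixed_cov = _fit_eigen_loop(
            lam, yt, Xt, theta, floor, max_iter, tol, verbose
        )
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)
        boundary = [
            name for name, idxs in self.components.items() if theta[idxs[0]] <= floor * 1.5
        ]
        return AnimalModelResults(
            spec=self.spec,
            params=theta,
            param_names=list(self.param_names),
            cov_params=cov,
            loglik=ll,
            n_iter=len(trace),
            converged=converged,
            n_obs=n,
            fixed_effects=pd.Series(beta, index=self.fixed_names),
            fixed_cov=fixed_cov,
            boundary=boundary,
            trace=trace,
        )

    def _neg2_profile(self, V):
        n, p = self.X.shape
        cf = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv_y = linalg.cho_solve(cf, self.y)
        Vinv_X = linalg.cho_solve(cf, self.X)
        XtVX = self.X.T @ Vinv_X
        cfx = linalg.cho_factor(XtVX, lower=True)
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        beta = linalg.cho_solve(cfx, self.X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ beta
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetX + yPy)
        return ll, Py, Vinv_X, cfx, cf, beta

    def _project(self, theta, floor):
        """Clip each component's covariance block to the PSD cone (with a
        small positive floor on variances)."""
        theta = theta.copy()
        clipped = []
        for comp, idxs in self.components.items():
            if len(idxs) == 1:
                if theta[idxs[0]] < floor:
                    theta[idxs[0]] = floor
                    clipped.append(comp)
            else:
                i11, i12, i22 = idxs
                M = np.array([[theta[i11], theta[i12]], [theta[i12], theta[i22]]])
                w, v = np.linalg.eigh(M)
                if w.min() < floor:
                    w = np.maximum(w, floor)
                    M = v @ np.diag(w) @ v.T
                    theta[i11], theta[i12], theta[i22] = M[0, 0], M[0, 1], M[1, 1]
                    clipped.append(comp)
        return theta, clipped

    def fit(self, max_iter=100, tol=1e-6, start=None, verbose=False) -> AnimalModelResults:
        nparam = len(self.K_list)
        n, p = self.X.shape
        if nparam == 2 and np.array_equal(self.K_list[1], np.eye(n)):
            # two-component univariate model: rotate to the eigenbasis of
            # the relationship matrix so V is diagonal (O(n) per iteration
            # after one decomposition)
            return self._fit_eigen(max_iter=max_iter, tol=tol, start=start, verbose=verbose)
        vary = float(np.var(self.y))
        floor = 1e-8 * max(vary, 1e-12)
        ncomp = len(self.components)
        if start is None:
            theta = np.zeros(nparam)
            for comp, idxs in self.components.items():
                if len(idxs) == 1:
                    theta[idxs[0]] = vary / ncomp
                else:
                    i11, i12, i22 = idxs
                    theta[i11] = theta[i22] = vary / ncomp
                    theta[i12] = 0.1 * vary / ncomp
        else:
            theta = np.asarray(start, dtype=float).copy()

        trace = []
        ll_old = -np.inf
        best_ll, best_theta = -np.inf, theta.copy()
        stall = 0
        AI = np.eye(nparam)
        converged = False
        warned_psd = False
        for it in range(1, max_iter + 1):
            V = sum(t * K for t, K in zip(theta, self.K_list))
            try:
                ll, Py, Vinv_X, cfx, cf, beta = self._neg2_profile(V)
            except np.linalg.LinAlgError:
                theta, _ = self._project(theta * 1.05 + floor, floor)
                continue
            # score and AI
            score = np.zeros(nparam)
            t_vecs = []
            trPK = np.zeros(nparam)
            for r, K in enumerate(self.K_list):
                KPy = K @ Py
                t_vecs.append(KPy)
                VinvK = linalg.cho_solve(cf, K)
                tr1 = np.trace(VinvK)
                W = Vinv_X.T @ K @ Vinv_X
                tr2 = np.trace(linalg.cho_solve(cfx, W))
                trPK[r] = tr1 - tr2
                score[r] = -0.5 * (trPK[r] - Py @ KPy)
            Pt = []
            for tv in t_vecs:
                Vt = linalg.cho_solve(cf, tv)
                Pt.append(Vt - Vinv_X @ linalg.cho_solve(cfx, self.X.T @ Vt))
            AI = 0.5 * np.array([[t_vecs[r] @ Pt[s] for s in range(nparam)] for r in range(nparam)])
            trace.append((it, ll, theta.copy()))
            if verbose:
                print(f"iter {it}: logL={ll:.6f} theta={theta}")
            # converge when the likelihood stops improving beyond tol;
            # near-optimum AI steps can dither at round-off level, so a
            # short stall window ends the loop at the best iterate seen
            if ll > best_ll + tol:
                best_ll, best_theta = ll, theta.copy()
                stall = 0
            else:
                stall += 1
            if it > 1 and (abs(ll - ll_old) < tol or stall >= 3):
                converged = True
                theta = best_theta
                break

            # AI step with step-halving; EM-style multiplicative fallback.
            # Variance parameters pinned at the floor with a negative score
            # are frozen out of the Newton system (active set), otherwise
            # the near-singular AI matrix stalls the remaining updates.
            var_idx = set()
            for idxs in self.components.values():
                var_idx.update((idxs[0], idxs[-1]))
            free = np.array(
                [
                    not (r in var_idx and theta[r] <= floor * 1.5 and score[r] < 0)
                    for r in range(nparam)
                ]
            )
            delta = np.zeros(nparam)
            try:
                sub = AI[np.ix_(free, free)] + 1e-10 * np.eye(int(free.sum()))
                delta[free] = np.linalg.solve(sub, score[free])
            except np.linalg.LinAlgError:
                delta = score / max(1.0, np.abs(score).max())
            stepped = False
            step = 1.0
            for _ in range(12):
                cand, clipped = self._project(theta + step * delta, floor)
                Vc = sum(t * K for t, K in zip(cand, self.K_list))
                try:
                    llc = self._neg2_profile(Vc)[0]
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if llc >= ll - 1e-10:
                    if clipped and not warned_psd:
                        warnings.warn(
                            f"covariance component(s) {clipped} projected to the PSD cone",
                            stacklevel=2,
                        )
                        warned_psd = True
                    theta = cand
                    stepped = True
                    break
                step *= 0.5
            if not stepped:
                # EM-style fixed point on variance parameters
                cand = theta.copy()
                for r in range(nparam):
                    if trPK[r] > 0 and t_vecs[r] @ Py >= 0 and theta[r] > 0:
                        cand[r] = theta[r] * np.sqrt(max(floor, (Py @ t_vecs[r]) / trPK[r]))
                cand, _ = self._project(cand, floor)
                theta = cand
            ll_old = ll

        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations", trace=trace
            )

        # covariance of estimates from the inverse AI matrix at the optimum
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)
        boundary = [
            name
            for name, idxs in self.components.items()
            if any(theta[i] <= floor * 1.5 for i in idxs[:1])
        ]
        V = sum(t * K for t, K in zip(theta, self.K_list))
        ll, Py, Vinv_X, cfx, cf, beta = self._neg2_profile(V)
        fixed_cov = np.linalg.inv(self.X.T @ Vinv_X)
        return AnimalModelResults(
            spec=self.spec,
            params=theta,
            param_names=list(self.param_names),
            cov_params=cov,
            loglik=ll,
            n_iter=len(trace),
            converged=converged,
            n_obs=n,
            fixed_effects=pd.Series(beta, index=self.fixed_names),
            fixed_cov=fixed_cov,
            boundary=boundary,
            trace=trace,
        )


def _fit_eigen_loop(lam, yt, Xt, theta, floor, max_iter, tol, verbose):
    """AI-REML on a diagonalised two-component model; returns
    (theta, loglik, AI, trace, converged, beta, XtVX_inv)."""
    trace = []
    ll_old = -np.inf
    best_ll, best_theta = -np.inf, theta.copy()
    stall = 0
    AI = np.eye(2)
    converged = False

    def profile(th):
        d = th[0] * lam + th[1]
        if d.min() <= 0:
            raise np.linalg.LinAlgError
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        cfx = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve(cfx, Xd.T @ yt)
        w = yt / d - Xd @ beta
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        ll = -0.5 * (np.sum(np.log(d)) + logdetX + yt @ w)
        return ll, w, d, Xd, cfx, beta, XtVX

    for it in range(1, max_iter + 1):
        try:
            ll, w, d, Xd, cfx, beta, XtVX = profile(theta)
        except np.linalg.LinAlgError:
            theta = np.maximum(theta * 1.05 + floor, floor)
            continue
        bases = (lam, np.ones_like(lam))
        trPK = np.zeros(2)
        score = np.zeros(2)
        tvecs = []
        for r, b in enumerate(bases):
            trPK[r] = np.sum(b / d) - np.trace(linalg.cho_solve(cfx, Xt.T @ (Xt * (b / d**2)[:, None])))
            score[r] = -0.5 * (trPK[r] - w @ (b * w))
            tvecs.append(b * w)
        Pt = []
        for t in tvecs:
            Pt.append(t / d - Xd @ linalg.cho_solve(cfx, Xd.T @ t))
        AI = 0.5 * np.array([[tvecs[r] @ Pt[s] for s in range(2)] for r in range(2)])
        trace.append((it, ll, theta.copy()))
        if verbose:
            print(f"iter {it}: logL={ll:.6f} theta={theta}")
        if ll > best_ll + tol:
            best_ll, best_theta = ll, theta.copy()
            stall = 0
        else:
            stall += 1
        if it > 1 and (abs(ll - ll_old) < tol or stall >= 3):
            converged = True
            theta = best_theta
            break
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(2), score)
        except np.linalg.LinAlgError:
            delta = score / max(1.0, np.abs(score).max())
        step = 1.0
        stepped = False
        for _ in range(12):
            cand = np.maximum(theta + step * delta, floor)
            try:
                llc = profile(cand)[0]
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if llc >= ll - 1e-10:
                theta = cand
                stepped = True
                break
            step *= 0.5
        if not stepped:
            cand = theta.copy()
            for r in range(2):
                num = w @ (bases[r] * w)
                if trPK[r] > 0 and num >= 0 and theta[r] > 0:
                    cand[r] = theta[r] * np.sqrt(max(floor, num / trPK[r]))
            theta = np.maximum(cand, floor)
        ll_old = ll
    if not converged:
        raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trace=trace)
    ll, w, d, Xd, cfx, beta, XtVX = profile(theta)
    return theta, ll, AI, trace, converged, beta, np.linalg.inv(XtVX)


def fit_univariate(pheno, A, spec=None, trait="va", **fit_kw) -> AnimalModelResults:
    """Convenience wrapper: univariate REML fit of one trait."""
    if spec is None:
        spec = ModelSpec(traits=(trait,))
    return AnimalModel.from_dataframe(pheno, A, spec).fit(**fit_kw)


def fit_bivariate(pheno, A, traits, spec=None, **fit_kw) -> AnimalModelResults:
    """Convenience wrapper: bivariate REML fit of a trait pair."""
    if spec is None:
        spec = ModelSpec(traits=tuple(traits))
    return AnimalModel.from_dataframe(pheno, A, spec).fit(**fit_kw)
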