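"""Whole-genome regression by Bayes-alphabet Gibbs sampling.

All methods fit the multi-locus model

    y = W b + sum_k z_k alpha_k delta_k + e

with W the fixed-effects design (line, contemporary group, centred body
weight; flat priors), z_k the centred dosage of marker k, delta_k a
Bernoulli inclusion indicator with prior P(delta_k = 0) = pi, and
e ~ N(0, I sigma2_e). The priors differ by method:

* **BayesB** — each included marker has its own effect variance with a
  scaled-inverse-chi-square prior.
* **BayesC** — all included markers share one effect variance.
* **BayesCpi** — as BayesC, with pi itself given a uniform prior and
  sampled (conjugate Beta posterior on the zero-effect count).
* **BayesC0** — pi = 0: every marker in the model, shared variance
  (the ridge/GBLUP limit).

Single-site Gibbs updates throughout, with the inclusion indicator drawn
from the marginalised (effect-integrated-out) likelihood ratio. Effect-
and residual-variance hyperpriors are scaled-inverse-chi-square with the
scale set so the prior mean equals the value implied by the pedigree
REML estimates: effect variance sigma2_a / ((1 - pi) * sum 2 p_k (1-p_k))
with nu = 4.2, residual sigma2_e with nu = 10.

Chains are reproducible bit-for-bit for a given seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from ._design import FixedDesign
from .io_qc import GenotypeData

__all__ = [
    "ChainConfig",
    "BayesAlphabet",
    "BayesResults",
    "fit_bayes",
    "estimate_pi",
    "gebv_from_effects",
]

_METHOD_CODES = {"BayesC0": 0, "BayesC": 1, "BayesB": 2, "BayesCpi": 3}


@dataclass
class ChainConfig:
    method: str = "BayesB"
    pi: float = 0.99
    n_iter: int = 50_000
    n_burnin: int = 5_000
    thinning: int = 1
    seed: int = 1
    var_genetic: float = 1.0  # prior additive variance (from the REML fit)
    var_residual: float = 1.0  # prior residual variance (from the REML fit)
    nu_effect: float = 4.2
    nu_residual: float = 10.0

    def __post_init__(self):
        if self.method not in _METHOD_CODES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "BayesC0":
            self.pi = 0.0
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.var_genetic <= 0 or self.var_residual <= 0:
            raise ValueError("prior variances must be positive")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@njit(cache=True)
def _gibbs_kernel(
    Z,
    W,
    y,
    method,
    pi0,
    n_iter,
    burnin,
    thin,
    seed,
    nu_b,
    S_b,
    nu_e,
    S_e,
    eff_out,
    inc_out,
    fix_out,
    s2e_out,
    s2b_out,
    pi_out,
):
    np.random.seed(seed)
    n, m = Z.shape
    p = W.shape[1]
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        xtx[j] = s
    wtw = np.empty(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, l] * W[i, l]
        wtw[l] = s

    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    bfix = np.zeros(p)
    s2b = np.empty(m)
    prior_mean_b = nu_b * S_b / (nu_b - 2.0)
    for j in range(m):
        s2b[j] = prior_mean_b
    s2b_common = prior_mean_b
    s2e = nu_e * S_e / (nu_e - 2.0)
    pi = pi0
    e = y.copy()

    stored = 0
    for it in range(n_iter):
        # fixed effects, flat priors
        for l in range(p):
            if wtw[l] <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += W[i, l] * (e[i] + W[i, l] * bfix[l])
            mean = rhs / wtw[l]
            new = mean + np.random.standard_normal() * np.sqrt(s2e / wtw[l])
            diff = new - bfix[l]
            for i in range(n):
                e[i] -= W[i, l] * diff
            bfix[l] = new

        # marker effects
        n_in = 0
        ssq_in = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                alpha[j] = 0.0
                delta[j] = 0
                continue
            rhs = 0.0
            if delta[j] == 1:
                for i in range(n):
                    rhs += Z[i, j] * (e[i] + Z[i, j] * alpha[j])
            else:
                for i in range(n):
                    rhs += Z[i, j] * e[i]
            vj = s2b[j] if method == 2 else s2b_common
            include = True
            if method != 0 and pi > 0.0:
                if pi >= 1.0:
                    include = False
                else:
                    v0 = xtx[j] * s2e
                    v1 = xtx[j] * (xtx[j] * vj + s2e)
                    log_bf = 0.5 * (np.log(v0 / v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1))
                    if log_bf > 50.0:
                        prob = 1.0
                    elif log_bf < -50.0:
                        prob = 0.0
                    else:
                        prob = (1.0 - pi) / ((1.0 - pi) + pi * np.exp(-log_bf))
                    include = np.random.random() < prob
            old = alpha[j] if delta[j] == 1 else 0.0
            if include:
                C = xtx[j] + s2e / vj
                newa = rhs / C + np.random.standard_normal() * np.sqrt(s2e / C)
                diff = newa - old
                if diff != 0.0:
                    for i in range(n):
                        e[i] -= Z[i, j] * diff
                alpha[j] = newa
                delta[j] = 1
                n_in += 1
                ssq_in += newa * newa
            else:
                if old != 0.0:
                    for i in range(n):
                        e[i] += Z[i, j] * old
                alpha[j] = 0.0
                delta[j] = 0

        # effect variances
        if method == 2:  # BayesB: per-marker
            for j in range(m):
                if delta[j] == 1:
                    s2b[j] = (nu_b * S_b + alpha[j] * alpha[j]) / np.random.chisquare(nu_b + 1.0)
                else:
                    s2b[j] = nu_b * S_b / np.random.chisquare(nu_b)
        else:  # shared variance
            k_eff = n_in if method != 0 else m
            s2b_common = (nu_b * S_b + ssq_in) / np.random.chisquare(nu_b + k_eff)

        # pi (BayesCpi)
        if method == 3:
            pi = np.random.beta(m - n_in + 1.0, n_in + 1.0)

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + nu_e * S_e) / np.random.chisquare(n + nu_e)
        if not np.isfinite(s2e) or s2e > 1e300:
            return -1  # divergence

        if it >= burnin and (it - burnin) % thin == 0:
            for j in range(m):
                eff_out[stored, j] = alpha[j]
                inc_out[stored, j] = delta[j]
            for l in range(p):
                fix_out[stored, l] = bfix[l]
            s2e_out[stored] = s2e
            if method == 2:
                sm = 0.0
                for j in range(m):
                    sm += s2b[j]
                s2b_out[stored] = sm / m
            else:
                s2b_out[stored] = s2b_common
            pi_out[stored] = pi
            stored += 1
    return stored


@dataclass
class BayesResults:
    """Retained MCMC draws from a Bayes-alphabet fit.

    Effects and inclusion indicators satisfy indicator == 0 iff
    effect == 0 within every draw. GEBVs are linear in the marker
    effects: for any partition of the markers, the per-subset GEBVs sum
    to the full-model GEBV.
    """

    config: ChainConfig
    samples: list
    markers: list
    effects: np.ndarray  # (n_draws, m)
    include: np.ndarray  # (n_draws, m) int8
    fixed: np.ndarray  # (n_draws, p)
    fixed_names: list
    sigma2_e: np.ndarray
    sigma2_b: np.ndarray
    pi: np.ndarray
    center_freqs: np.ndarray  # training allele frequencies used for centring
    design: FixedDesign
    _Z: np.ndarray = field(repr=False, default=None)

    @property
    def n_draws(self):
        return self.effects.shape[0]

    def posterior_mean_effects(self) -> pd.Series:
        return pd.Series(self.effects.mean(axis=0), index=self.markers, name="effect")

    def inclusion_frequency(self) -> pd.Series:
        return pd.Series(self.include.mean(axis=0), index=self.markers, name="ppi_snp")

    def posterior_mean_fixed(self) -> pd.Series:
        return pd.Series(self.fixed.mean(axis=0), index=self.fixed_names)

    def pi_mean(self) -> float:
        return float(self.pi.mean())

    def gebv(self, snp_set=None) -> pd.Series:
        """Posterior-mean GEBVs of the training animals."""
        eff = self.posterior_mean_effects()
        return gebv_from_effects(
            eff, self._Z, self.markers, self.samples, snp_set=snp_set
        )

    def gebv_draws(self) -> np.ndarray:
        """(n_draws, n_animals) GEBV per retained draw."""
        return self.effects @ self._Z.T

    def predict(self, g: GenotypeData, snp_set=None) -> pd.Series:
        """GEBVs for new animals, centring their dosages with the
        training allele frequencies."""
        pos = {mk: i for i, mk in enumerate(self.markers)}
        idx = [pos[mk] for mk in g.markers if mk in pos]
        keep = [mk for mk in g.markers if mk in pos]
        gidx = [g.markers.index(mk) for mk in keep]
        Z = g.calls[:, gidx] - 2.0 * self.center_freqs[idx]
        eff = self.posterior_mean_effects().to_numpy()[idx]
        if snp_set is not None:
            mask = np.isin(np.array(keep), np.asarray(list(snp_set)))
            if not mask.any():
                raise ValueError("empty SNP set for prediction")
            eff = np.where(mask, eff, 0.0)
        return pd.Series(Z @ eff, index=g.samples, name="gebv")

    def to_frame(self) -> pd.DataFrame:
        """Per-marker summary: posterior mean effect, inclusion
        frequency, posterior mean effect variance share."""
        return pd.DataFrame(
            {
                "effect": self.effects.mean(axis=0),
                "incl_freq": self.include.mean(axis=0),
                "effect_var": self.effects.var(axis=0),
            },
            index=pd.Index(self.markers, name="marker"),
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            f"Bayes-alphabet fit: {cfg.method}  (pi={cfg.pi:.4g})",
            f"  chain: {cfg.n_iter} iterations, {cfg.n_burnin} burn-in, "
            f"thinning {cfg.thinning} -> {self.n_draws} retained draws  (seed {cfg.seed})",
            f"  posterior mean sigma2_e: {self.sigma2_e.mean():.4g}",
            f"  posterior mean pi: {self.pi_mean():.4g}",
            f"  markers with inclusion frequency > 0.5: "
            f"{int((self.include.mean(axis=0) > 0.5).sum())} / {len(self.markers)}",
        ]
        return "\n".join(lines)

    def save(self, path):
        """Persist chains plus config to an .npz container."""
        np.savez_compressed(
            path,
            effects=self.effects,
            include=self.include,
            fixed=self.fixed,
            sigma2_e=self.sigma2_e,
            sigma2_b=self.sigma2_b,
            pi=self.pi,
            center_freqs=self.center_freqs,
            markers=np.array(self.markers),
            samples=np.array(self.samples),
            fixed_names=np.array(self.fixed_names),
            config=np.array(
                [
                    self.config.method,
                    str(self.config.pi),
                    str(self.config.n_iter),
                    str(self.config.n_burnin),
                    str(self.config.seed),
                ]
            ),
        )


class BayesAlphabet:
    """Bayes-alphabet whole-genome regression model.

    Parameters
    ----------
    genotypes : GenotypeData
        QC'd genotypes (no missing calls).
    pheno : DataFrame
        Phenotype table with the trait column and fixed-effect columns.
    trait : str
        Trait column to analyse.
    config : ChainConfig
        Sampler settings; set ``var_genetic``/``var_residual`` from the
        pedigree REML fit.
    fixed, covariates : tuple
        Fixed-effect factor and covariate columns (litter is deliberately
        not part of this model).
    """

    def __init__(self, genotypes: GenotypeData, pheno: pd.DataFrame, trait: str,
                 config: ChainConfig, fixed=("line", "cg"), covariates=("bw",)):
        self.config = config
        ids = set(genotypes.samples)
        sub = pheno.dropna(subset=[trait])
        missing = set(sub["animal"]) - ids
        if missing:
            raise ValueError(f"animals without genotypes: {sorted(missing)[:5]}")
        if len(sub) == 0:
            raise ValueError("no phenotyped, genotyped animals")
        g = genotypes.take_samples(sub["animal"].tolist())
        if np.isnan(g.calls).any():
            raise ValueError("genotypes contain missing calls; run QC first")
        self.genotypes = g
        self.pheno = sub.reset_index(drop=True)
        self.trait = trait
        self.design = FixedDesign(fixed, covariates).fit(self.pheno)
        self.W = self.design.build(self.pheno)
        self.y = self.pheno[trait].to_numpy(dtype=float)
        self.p_train = g.calls.mean(axis=0) / 2.0
        self.Z = g.calls - 2.0 * self.p_train

    def fit(self) -> BayesResults:
        cfg = self.config
        Z, W, y = self.Z, self.W, self.y
        n, m = Z.shape
        het = float(np.sum(2.0 * self.p_train * (1.0 - self.p_train)))
        if het <= 0:
            raise ValueError("no polymorphic markers in the training set")
        pi_for_scale = min(cfg.pi, 0.999) if cfg.method != "BayesC0" else 0.0
        mean_b = cfg.var_genetic / ((1.0 - pi_for_scale) * het)
        S_b = mean_b * (cfg.nu_effect - 2.0) / cfg.nu_effect
        S_e = cfg.var_residual * (cfg.nu_residual - 2.0) / cfg.nu_residual
        n_store = (cfg.n_iter - cfg.n_burnin + cfg.thinning - 1) // cfg.thinning
        eff = np.zeros((n_store, m))
        inc = np.zeros((n_store, m), dtype=np.int8)
        fix = np.zeros((n_store, W.shape[1]))
        s2e = np.zeros(n_store)
        s2b = np.zeros(n_store)
        pis = np.zeros(n_store)
        stored = _gibbs_kernel(
            np.ascontiguousarray(Z),
            np.ascontiguousarray(W),
            y,
            _METHOD_CODES[cfg.method],
            float(cfg.pi),
            cfg.n_iter,
            cfg.n_burnin,
            cfg.thinning,
            cfg.seed % (2**31 - 1),
            float(cfg.nu_effect),
            float(S_b),
            float(cfg.nu_residual),
            float(S_e),
            eff,
            inc,
            fix,
            s2e,
            s2b,
            pis,
        )
        if stored < 0:
            raise RuntimeError(
                "residual variance diverged; check trait scaling and priors"
            )
        return BayesResults(
            config=cfg,
            samples=list(self.genotypes.samples),
            markers=list(self.genotypes.markers),
            effects=eff[:stored],
            include=inc[:stored],
            fixed=fix[:stored],
            fixed_names=list(self.design.names),
            sigma2_e=s2e[:stored],
            sigma2_b=s2b[:stored],
            pi=pis[:stored],
            center_freqs=self.p_train,
            design=self.design,
            _Z=Z,
        )


def fit_bayes(genotypes, pheno, trait, config, fixed=("line", "cg"), covariates=("bw",)) -> BayesResults:
    """One-call fit of a Bayes-alphabet model."""
    return BayesAlphabet(genotypes, pheno, trait, config, fixed, covariates).fit()


def estimate_pi(genotypes, pheno, trait, config=None, **kw) -> tuple[float, np.ndarray]:
    """BayesCpi run returning (posterior mean pi, pi chain after burn-in);
    the mean is the fixed pi for subsequent BayesB/BayesC analyses."""
    if config is None:
        config = ChainConfig(method="BayesCpi")
    elif config.method != "BayesCpi":
        raise ValueError("estimate_pi requires method='BayesCpi'")
    res = fit_bayes(genotypes, pheno, trait, config, **kw)
    return res.pi_mean(), res.pi


def gebv_from_effects(effects, Z_or_genotypes, markers=None, samples=None, snp_set=None,
                      center_freqs=None) -> pd.Series:
    """GEBV_i = sum over the SNP set of centred dosage x effect.

    ``effects`` is a Series indexed by marker (or array parallel to
    ``markers``). Accepts a GenotypeData (centred by ``center_freqs`` or
    its own allele frequencies) or an already-centred dosage matrix.
    """
    if hasattr(Z_or_genotypes, "calls"):
        g = Z_or_genotypes
        markers = list(g.markers)
        samples = list(g.samples)
        p = g.calls.mean(axis=0) / 2.0 if center_freqs is None else np.asarray(center_freqs)
        Z = g.calls - 2.0 * p
    else:
        Z = np.asarray(Z_or_genotypes)
        markers = list(markers)
        samples = list(samples) if samples is not None else list(range(Z.shape[0]))
    if isinstance(effects, pd.Series):
        eff = effects.reindex(markers).fillna(0.0).to_numpy()
    else:
        eff = np.asarray(effects, dtype=float)
    if snp_set is not None:
        snp_set = set(snp_set)
        if not snp_set:
            raise ValueError("empty SNP set")
        mask = np.array([mk in snp_set for mk in markers])
        if not mask.any():
            raise ValueError("SNP set shares no markers with the genotypes")
        eff = np.where(mask, eff, 0.0)
    return pd.Series(Z @ eff, index=samples, name="gebv")
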