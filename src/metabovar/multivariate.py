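"""Multivariate Bayesian mixed model over all metabolites jointly.

Model:  Y = X beta + Z u + eps, with Y the (rows x M) response matrix,
beta the (L+1) x M fixed-effect matrix, u_i ~ Normal_M(0, G) the individual
random effects and eps rows ~ Normal_M(0, R).  Dense G and R carry the
between-metabolite dependence; both get conjugate inverse-Wishart priors
with scale matrices built empirically from the univariate stage.

The sampler is a systematic-scan Gibbs sampler over the exact conjugate
full conditionals; each conditional is exposed as a module function so it
can be validated against its closed form in isolation.

Conventions (used consistently here and in the tests):

* vec-ordering of beta is metabolite-major: the sampled vector is
  ``beta.ravel()`` (C order), i.e. blocks per fixed-effect coefficient,
  metabolite index varying fastest within a block.
* inverse-Wishart(nu, S) has density proportional to
  ``|W|^{-(nu+M+1)/2} exp(-tr(S W^{-1})/2)`` and prior mean
  ``S / (nu - M - 1)`` for nu > M + 1 (scipy's parameterisation).
* chain ``c`` draws from the stream ``SeedSequence(seed).spawn(...)[c]``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data_model import DesignMatrices
from .univariate import MCMCConfig, PriorSummaries

logger = logging.getLogger("metabovar")

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "ConvergenceReport",
    "build_prior",
    "gibbs_fit",
    "independent_to_draws",
    "psrf",
    "sample_beta",
    "sample_u",
    "sample_G",
    "sample_R",
    "save_draws",
    "load_draws",
]


def _assert_spd(A: np.ndarray, name: str) -> None:
    try:
        linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(f"{name} is not symmetric positive definite") from err


@dataclass
class PriorSpec:
    """Hyperparameters of the multivariate prior.

    beta0 and B_diag are (L+1, M) arrays in the model's beta layout; B is
    diagonal, stored as its diagonal.  Sigma2 / SigmaEps2 are the M x M
    inverse-Wishart scale matrices for G and R; a single degrees-of-freedom
    ``nu`` is shared by both.
    """

    beta0: np.ndarray
    B_diag: np.ndarray
    Sigma2: np.ndarray
    SigmaEps2: np.ndarray
    nu: float

    def __post_init__(self):
        self.beta0 = np.atleast_2d(np.asarray(self.beta0, dtype=float))
        self.B_diag = np.atleast_2d(np.asarray(self.B_diag, dtype=float))
        if (self.B_diag <= 0).any():
            raise ValueError("B diagonal entries must be strictly positive")
        M = self.Sigma2.shape[0]
        _assert_spd(self.Sigma2, "Sigma2")
        _assert_spd(self.SigmaEps2, "SigmaEps2")
        if self.nu <= M - 1:
            raise ValueError(f"nu={self.nu} must exceed M-1={M - 1}")

    @property
    def n_metabolites(self) -> int:
        return self.Sigma2.shape[0]

    def fingerprint(self) -> str:
        h = np.concatenate([self.beta0.ravel(), self.B_diag.ravel(),
                            self.Sigma2.ravel(), self.SigmaEps2.ravel(),
                            [self.nu]])
        return f"{hash(h.tobytes()) & 0xFFFFFFFF:08x}"


def _repair_positive_definite(S: np.ndarray, name: str) -> np.ndarray:
    """Halve off-diagonal magnitudes until the matrix admits a Cholesky factor."""
    out = S.copy()
    mag = None
    for _ in range(60):
        try:
            linalg.cholesky(out, lower=True)
            if mag is not None:
                warnings.warn(
                    f"{name}: off-diagonal magnitude shrunk to {mag:.6g} "
                    "to restore positive definiteness"
                )
            return out
        except linalg.LinAlgError:
            off = out - np.diag(np.diag(out))
            mag = float(np.max(np.abs(off))) / 2.0
            out = np.diag(np.diag(out)) + off / 2.0
    raise ValueError(f"{name}: could not repair positive definiteness")


def build_prior(
    summaries: PriorSummaries,
    sign_matrix: np.ndarray,
    nu_factor: float = 1.5,
    offdiag_magnitude: float = 0.1,
) -> PriorSpec:
    """Empirical-Bayes prior for the multivariate model.

    beta0 / B stack the univariate posterior means and variances of the
    fixed effects.  The scale-matrix diagonals take the univariate posterior
    means of sigma2_u (for Sigma2) and sigma2_e (for SigmaEps2); every
    off-diagonal entry has magnitude ``offdiag_magnitude`` (default 0.1)
    with its sign taken from the observed pooled correlation of Y.  Degrees
    of freedom: ``nu = ceil(nu_factor * M)``, default 150% of M.  A scale
    matrix that is not positive definite has its off-diagonal magnitudes
    halved until it is, with a warning.
    """
    M = summaries.n_metabolites
    sign_matrix = np.asarray(sign_matrix, dtype=float)
    if sign_matrix.shape != (M, M):
        raise ValueError("sign matrix dimension mismatch")
    if (summaries.sigma2_u_mean <= 0).any() or (summaries.sigma2_e_mean <= 0).any():
        raise ValueError("scale-matrix diagonal entries must be positive")
    if (summaries.beta_var <= 0).any():
        raise ValueError("B diagonal entries must be positive")
    nu = math.ceil(nu_factor * M)
    if nu <= M - 1:
        raise ValueError(f"nu={nu} from nu_factor={nu_factor} is <= M-1")

    off = offdiag_magnitude * np.sign(sign_matrix)
    np.fill_diagonal(off, 0.0)
    Sigma2 = np.diag(summaries.sigma2_u_mean) + off
    SigmaEps2 = np.diag(summaries.sigma2_e_mean) + off
    Sigma2 = _repair_positive_definite(Sigma2, "Sigma2")
    SigmaEps2 = _repair_positive_definite(SigmaEps2, "SigmaEps2")
    return PriorSpec(
        beta0=summaries.beta_mean.copy(),
        B_diag=summaries.beta_var.copy(),
        Sigma2=Sigma2,
        SigmaEps2=SigmaEps2,
        nu=float(nu),
    )


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in chains of the multivariate sampler.

    Arrays indexed (chain, draw, ...); ``*_pooled`` concatenate chains.
    """

    beta_draws: np.ndarray  # (C, S, L+1, M)
    u_draws: np.ndarray     # (C, S, N, M)
    G_draws: np.ndarray     # (C, S, M, M)
    R_draws: np.ndarray     # (C, S, M, M)
    individuals: list
    metabolites: list[str]
    covariates: list[str]
    config: MCMCConfig | None = None
    prior_fingerprint: str = ""

    def __post_init__(self):
        shapes = {a.shape[:2] for a in
                  (self.beta_draws, self.u_draws, self.G_draws, self.R_draws)}
        if len(shapes) != 1:
            raise ValueError("draw counts differ across parameters")

    @property
    def n_chains(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.beta_draws.shape[1]

    @property
    def beta_pooled(self) -> np.ndarray:
        return self.beta_draws.reshape(-1, *self.beta_draws.shape[2:])

    @property
    def u_pooled(self) -> np.ndarray:
        return self.u_draws.reshape(-1, *self.u_draws.shape[2:])

    @property
    def G_pooled(self) -> np.ndarray:
        return self.G_draws.reshape(-1, *self.G_draws.shape[2:])

    @property
    def R_pooled(self) -> np.ndarray:
        return self.R_draws.reshape(-1, *self.R_draws.shape[2:])


# ----------------------------------------------------------------------
# Full conditionals.  Each takes the current state of the other blocks and
# returns one exact draw; gibbs_fit cycles them in a systematic scan.
# ----------------------------------------------------------------------

def sample_beta(
    Y: np.ndarray, X: np.ndarray, u: np.ndarray, indiv_idx: np.ndarray,
    R: np.ndarray, prior: PriorSpec, rng: np.random.Generator,
    it: int = -1,
) -> np.ndarray:
    """Draw beta | u, R, Y from its matrix-normal full conditional.

    Working in the metabolite-major vec layout b = beta.ravel(), the
    precision is diag(1/B) + (X'X) kron R^{-1} and the linear term is
    b0/B + vec(X'(Y - U) R^{-1}).
    """
    p, M = prior.beta0.shape
    Rinv = linalg.inv(R)
    resid = Y - u[indiv_idx]
    prec = np.kron(X.T @ X, Rinv) + np.diag(1.0 / prior.B_diag.ravel())
    lin = (X.T @ resid @ Rinv).ravel() + prior.beta0.ravel() / prior.B_diag.ravel()
    try:
        L = linalg.cholesky(prec, lower=True)
    except linalg.LinAlgError as err:
        raise RuntimeError(f"beta conditional not positive definite "
                           f"(iteration {it})") from err
    mean = linalg.cho_solve((L, True), lin)
    b = mean + linalg.solve_triangular(L.T, rng.standard_normal(p * M), lower=False)
    return b.reshape(p, M)


def sample_u(
    Y: np.ndarray, X: np.ndarray, beta: np.ndarray, indiv_idx: np.ndarray,
    n_individuals: int, G: np.ndarray, R: np.ndarray,
    rng: np.random.Generator, it: int = -1,
) -> np.ndarray:
    """Draw all u_i | beta, G, R, Y.

    u_i has precision G^{-1} + T_i R^{-1} and linear term
    R^{-1} sum_t (y_it - beta' x_it); individuals sharing an observation
    count T_i share the precision factor, so the draw vectorises per count.
    """
    M = G.shape[0]
    resid = Y - X @ beta
    sums = np.zeros((n_individuals, M))
    np.add.at(sums, indiv_idx, resid)
    counts = np.bincount(indiv_idx, minlength=n_individuals)
    Ginv = linalg.inv(G)
    Rinv = linalg.inv(R)
    lin = sums @ Rinv  # R^{-1} symmetric
    u = np.empty((n_individuals, M))
    for c in np.unique(counts):
        sel = counts == c
        prec = Ginv + c * Rinv
        try:
            L = linalg.cholesky(prec, lower=True)
        except linalg.LinAlgError as err:
            raise RuntimeError(f"u conditional not positive definite "
                               f"(iteration {it})") from err
        mean = linalg.cho_solve((L, True), lin[sel].T).T
        z = rng.standard_normal((int(sel.sum()), M))
        u[sel] = mean + linalg.solve_triangular(L.T, z.T, lower=False).T
    return u


def sample_G(
    u: np.ndarray, prior: PriorSpec, rng: np.random.Generator, it: int = -1,
) -> np.ndarray:
    """Draw G | u ~ InvWishart(nu + N, Sigma2 + sum_i u_i u_i')."""
    N = u.shape[0]
    scale = prior.Sigma2 + u.T @ u
    draw = stats.invwishart.rvs(df=prior.nu + N, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


def sample_R(
    Y: np.ndarray, X: np.ndarray, beta: np.ndarray, u: np.ndarray,
    indiv_idx: np.ndarray, prior: PriorSpec, rng: np.random.Generator,
    it: int = -1,
) -> np.ndarray:
    """Draw R | beta, u, Y ~ InvWishart(nu + n_rows, SigmaEps2 + sum_rows e e')."""
    e = Y - X @ beta - u[indiv_idx]
    scale = prior.SigmaEps2 + e.T @ e
    draw = stats.invwishart.rvs(df=prior.nu + Y.shape[0], scale=scale,
                                random_state=rng)
    return np.atleast_2d(draw)


def gibbs_step(
    state: dict, Y: np.ndarray, X: np.ndarray, indiv_idx: np.ndarray,
    n_individuals: int, prior: PriorSpec, rng: np.random.Generator,
    it: int = -1,
) -> dict:
    """One systematic Gibbs scan: beta, u, G, R in that order."""
    beta = sample_beta(Y, X, state["u"], indiv_idx, state["R"], prior, rng, it)
    u = sample_u(Y, X, beta, indiv_idx, n_individuals, state["G"], state["R"],
                 rng, it)
    G = sample_G(u, prior, rng, it)
    R = sample_R(Y, X, beta, u, indiv_idx, prior, rng, it)
    return {"beta": beta, "u": u, "G": G, "R": R}


def gibbs_fit(
    design: DesignMatrices, prior: PriorSpec, config: MCMCConfig,
) -> PosteriorDraws:
    """Fit the multivariate model by Gibbs sampling.

    Initialisation is deterministic: beta at the per-metabolite OLS
    estimates, u at 0, G and R at their prior means (or the scale matrices
    when nu <= M + 1 leaves the prior mean undefined).  NaNs in Y must have
    been filtered upstream.
    """
    Y, X, idx = design.Y, design.X, design.indiv_idx
    if not np.isfinite(Y).all():
        raise ValueError("Y contains NaN/inf; use complete-case build_design")
    M = design.n_metabolites
    if prior.n_metabolites != M or prior.beta0.shape[0] != design.n_fixed:
        raise ValueError("prior and design dimensions disagree")
    N = design.n_individuals

    beta_init, *_ = np.linalg.lstsq(X, Y, rcond=None)
    denom = prior.nu - M - 1
    G_init = prior.Sigma2 / denom if denom > 0 else prior.Sigma2.copy()
    R_init = prior.SigmaEps2 / denom if denom > 0 else prior.SigmaEps2.copy()

    C, S = config.n_chains, config.n_retained
    p = design.n_fixed
    out = PosteriorDraws(
        beta_draws=np.empty((C, S, p, M)),
        u_draws=np.empty((C, S, N, M)),
        G_draws=np.empty((C, S, M, M)),
        R_draws=np.empty((C, S, M, M)),
        individuals=list(design.individuals),
        metabolites=list(design.metabolites),
        covariates=list(design.covariates),
        config=config,
        prior_fingerprint=prior.fingerprint(),
    )
    for c, rng in enumerate(config.chain_rngs()):
        state = {"beta": beta_init.copy(), "u": np.zeros((N, M)),
                 "G": G_init.copy(), "R": R_init.copy()}
        k = 0
        for it in range(config.n_iter):
            state = gibbs_step(state, Y, X, idx, N, prior, rng, it)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                    and k < S:
                out.beta_draws[c, k] = state["beta"]
                out.u_draws[c, k] = state["u"]
                out.G_draws[c, k] = state["G"]
                out.R_draws[c, k] = state["R"]
                k += 1
    return out


def independent_to_draws(fits, design: DesignMatrices,
                         config: MCMCConfig | None = None) -> PosteriorDraws:
    """Assemble univariate fits into the multivariate draw container.

    G and R draws are diagonal (sigma2_u and sigma2_e per metabolite), so
    the independent model feeds the same predictive/flagging/replication
    operations as the multivariate one.
    """
    C, S, p = fits[0].beta_draws.shape
    M = len(fits)
    N = design.n_individuals
    beta = np.stack([f.beta_draws for f in fits], axis=-1)  # (C,S,p,M)
    u = np.zeros((C, S, N, M))
    pos = {v: k for k, v in enumerate(design.individuals)}
    for m, f in enumerate(fits):
        cols = [pos[i] for i in f.individuals]
        u[:, :, cols, m] = f.u_draws
    G = np.zeros((C, S, M, M))
    R = np.zeros((C, S, M, M))
    for m, f in enumerate(fits):
        G[:, :, m, m] = f.sigma2_u_draws
        R[:, :, m, m] = f.sigma2_e_draws
    return PosteriorDraws(
        beta_draws=beta, u_draws=u, G_draws=G, R_draws=R,
        individuals=list(design.individuals),
        metabolites=[f.metabolite for f in fits],
        covariates=list(design.covariates),
        config=config,
        prior_fingerprint="independent",
    )


@dataclass
class ConvergenceReport:
    """Per-parameter potential scale reduction factors and a verdict."""

    psrf: pd.Series
    threshold: float

    @property
    def mean(self) -> float:
        return float(self.psrf.dropna().mean())

    @property
    def sd(self) -> float:
        return float(self.psrf.dropna().std(ddof=1))

    @property
    def max(self) -> float:
        return float(self.psrf.dropna().max())

    @property
    def converged(self) -> bool:
        return bool(self.max <= self.threshold)

    def summary(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "max": self.max,
                "converged": self.converged, "threshold": self.threshold}


def _psrf_scalar(chains: np.ndarray) -> float:
    """Gelman-Rubin PSRF for one scalar parameter, chains shaped (C, S)."""
    C, S = chains.shape
    W = float(chains.var(axis=1, ddof=1).mean())
    if W == 0.0:
        return float("nan")
    means = chains.mean(axis=1)
    B_over_S = float(means.var(ddof=1))  # = B / S in the classic notation
    var_plus = (S - 1) / S * W + B_over_S
    return math.sqrt(var_plus / W)


def psrf(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """Potential scale reduction factor for every beta, G and R entry.

    Requires at least two chains with at least 50 retained draws each.  A
    parameter with zero within-chain variance gets an undefined (NaN) PSRF
    with a warning.
    """
    if draws.n_chains < 2:
        raise ValueError("PSRF needs >= 2 chains; rerun with a multi-chain config")
    if draws.n_retained < 50:
        raise ValueError("PSRF needs >= 50 retained draws per chain")
    vals: dict[str, float] = {}
    p, M = draws.beta_draws.shape[2:]
    mets = draws.metabolites
    coefs = ["intercept", *draws.covariates]
    for j in range(p):
        for m in range(M):
            vals[f"beta[{coefs[j]},{mets[m]}]"] = _psrf_scalar(
                draws.beta_draws[:, :, j, m])
    for name, arr in (("G", draws.G_draws), ("R", draws.R_draws)):
        for a in range(M):
            for b in range(a, M):
                vals[f"{name}[{mets[a]},{mets[b]}]"] = _psrf_scalar(
                    arr[:, :, a, b])
    series = pd.Series(vals)
    if series.isna().any():
        warnings.warn(
            f"PSRF undefined (zero within-chain variance) for "
            f"{list(series.index[series.isna()])}"
        )
    report = ConvergenceReport(psrf=series, threshold=threshold)
    logger.info("PSRF: mean=%.4f sd=%.4f max=%.4f converged=%s",
                report.mean, report.sd, report.max, report.converged)
    return report


# ----------------------------------------------------------------------
# Draws archive: NPZ arrays + JSON manifest, re-loadable for flagging
# without refitting.
# ----------------------------------------------------------------------

def save_draws(draws: PosteriorDraws, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "draws.npz",
        beta=draws.beta_draws, u=draws.u_draws,
        G=draws.G_draws, R=draws.R_draws,
    )
    manifest = {
        "individuals": [str(i) for i in draws.individuals],
        "metabolites": draws.metabolites,
        "covariates": draws.covariates,
        "n_chains": draws.n_chains,
        "n_retained": draws.n_retained,
        "prior_fingerprint": draws.prior_fingerprint,
        "config": None if draws.config is None else {
            "n_chains": draws.config.n_chains, "n_iter": draws.config.n_iter,
            "burn_in": draws.config.burn_in, "thin": draws.config.thin,
            "seed": draws.config.seed,
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return directory


def load_draws(directory) -> PosteriorDraws:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    arrays = np.load(directory / "draws.npz")
    config = None
    if manifest.get("config"):
        config = MCMCConfig(**manifest["config"])
    return PosteriorDraws(
        beta_draws=arrays["beta"], u_draws=arrays["u"],
        G_draws=arrays["G"], R_draws=arrays["R"],
        individuals=manifest["individuals"],
        metabolites=manifest["metabolites"],
        covariates=manifest["covariates"],
        config=config,
        prior_fingerprint=manifest.get("prior_fingerprint", ""),
    )
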