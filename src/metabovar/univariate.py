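"""Univariate Bayesian random-intercept model per metabolite.

This is the "independent model": for metabolite ``m``,

    y_itm = x_it' beta_m + u_im + eps_itm,
    u_im ~ Normal(0, sigma2_u),  eps_itm ~ Normal(0, sigma2_e),

fitted by a conjugate Gibbs sampler.  It serves two roles: the comparison
model in the simulation study, and the empirical-Bayes source of the
multivariate prior's hyperparameters (posterior means/variances of beta_m
and posterior means of the two variance components).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .data_model import DesignMatrices

__all__ = [
    "MCMCConfig",
    "UnivariatePrior",
    "UnivariatePosterior",
    "PriorSummaries",
    "fit_univariate",
    "fit_independent_model",
    "summarize_for_prior",
    "beta_conditional_moments",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chains, iterations, burn-in, thinning, master seed.

    Defaults follow the study protocol of four chains of 5000 iterations
    with a 2000-iteration burn-in and thinning rate 3.
    """

    n_chains: int = 4
    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("n_chains, n_iter and thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_retained < 50:
            raise ValueError(
                f"retained draws per chain ({self.n_retained}) must be >= 50"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def chain_rngs(self) -> list[np.random.Generator]:
        """One independent, reproducible RNG stream per chain."""
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(self.n_chains)]


@dataclass(frozen=True)
class UnivariatePrior:
    """Weakly informative, scale-aware priors for the univariate model.

    With ``s2`` the sample variance of the metabolite, the defaults resolve
    to beta_j ~ Normal(0, beta_scale * s2) per coefficient and
    sigma2 ~ InverseGamma(shape, rate_scale * s2) for both variance
    components.  Explicit values (``beta_var``, ``u_rate``, ``e_rate``,
    per-component shapes) override the scale-aware defaults — used e.g. to
    match the 1-metabolite multivariate prior exactly.
    """

    beta_mean: float = 0.0
    beta_scale: float = 1e8
    var_shape: float = 0.001
    var_rate_scale: float = 0.001
    beta_var: float | np.ndarray | None = None
    u_shape: float | None = None
    u_rate: float | None = None
    e_shape: float | None = None
    e_rate: float | None = None

    def resolve(self, y: np.ndarray, n_fixed: int):
        s2 = float(np.var(y, ddof=1))
        if s2 <= 0:
            s2 = 1.0
        bvar = self.beta_var if self.beta_var is not None else self.beta_scale * s2
        bvar = np.broadcast_to(np.asarray(bvar, dtype=float), (n_fixed,)).copy()
        au = self.u_shape if self.u_shape is not None else self.var_shape
        ae = self.e_shape if self.e_shape is not None else self.var_shape
        bu = self.u_rate if self.u_rate is not None else self.var_rate_scale * s2
        be = self.e_rate if self.e_rate is not None else self.var_rate_scale * s2
        return bvar, float(au), float(bu), float(ae), float(be)


@dataclass
class UnivariatePosterior:
    """Per-chain draws and pooled summaries for one metabolite.

    Arrays are indexed (chain, draw, ...); pooled views concatenate chains.
    """

    metabolite: str
    beta_draws: np.ndarray       # (C, S, L+1)
    u_draws: np.ndarray          # (C, S, N)
    sigma2_u_draws: np.ndarray   # (C, S)
    sigma2_e_draws: np.ndarray   # (C, S)
    individuals: list
    covariates: list[str]
    resid_effect_var: float = float("nan")  # mean posterior variance of per-row residuals

    def __post_init__(self):
        if (self.sigma2_u_draws <= 0).any() or (self.sigma2_e_draws <= 0).any():
            raise ValueError("variance draws must be strictly positive")

    @property
    def beta_pooled(self) -> np.ndarray:
        return self.beta_draws.reshape(-1, self.beta_draws.shape[-1])

    @property
    def u_pooled(self) -> np.ndarray:
        return self.u_draws.reshape(-1, self.u_draws.shape[-1])

    @property
    def sigma2_u_pooled(self) -> np.ndarray:
        return self.sigma2_u_draws.ravel()

    @property
    def sigma2_e_pooled(self) -> np.ndarray:
        return self.sigma2_e_draws.ravel()

    def summaries(self) -> dict:
        return {
            "beta_mean": self.beta_pooled.mean(axis=0),
            "beta_var": self.beta_pooled.var(axis=0, ddof=1),
            "sigma2_u_mean": float(self.sigma2_u_pooled.mean()),
            "sigma2_e_mean": float(self.sigma2_e_pooled.mean()),
            # alternative reading: dispersion of the effect/residual draws
            "u_effect_var": float(self.u_pooled.var(axis=0, ddof=1).mean()),
            "resid_effect_var": self.resid_effect_var,
        }


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def beta_conditional_moments(
    X: np.ndarray, resid: np.ndarray, s2e: float,
    bvar: np.ndarray, b0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the beta full conditional given u (via ``resid = y - u``).

    This is the weighted-least-squares posterior under the normal prior
    Normal(b0, diag(bvar)); the sampler draws from exactly this law.
    """
    prec = X.T @ X / s2e + np.diag(1.0 / bvar)
    cov = linalg.inv(prec)
    mean = cov @ (X.T @ resid / s2e + b0 / bvar)
    return mean, cov


def fit_univariate(
    design: DesignMatrices,
    metabolite: str,
    config: MCMCConfig,
    prior: UnivariatePrior | None = None,
) -> UnivariatePosterior:
    """Gibbs-sample the random-intercept model for one metabolite.

    Full conditionals: multivariate normal for beta, independent normals
    for the u_i, inverse-gamma for sigma2_u and sigma2_e.  Rows where this
    metabolite is missing are excluded.  Initialisation is deterministic
    (OLS beta, zero u, half the sample variance for each component).
    """
    prior = prior or UnivariatePrior()
    m = design.metabolites.index(metabolite)
    obs = np.isfinite(design.Y[:, m])
    y = design.Y[obs, m]
    X = design.X[obs]
    idx = design.indiv_idx[obs]
    keep_ind = np.unique(idx)
    remap = -np.ones(design.n_individuals, dtype=np.int64)
    remap[keep_ind] = np.arange(len(keep_ind))
    idx = remap[idx]
    N = len(keep_ind)
    n, p = X.shape
    counts = np.bincount(idx, minlength=N).astype(float)
    if N < 2 or (counts >= 2).sum() < 2:
        raise ValueError(
            f"metabolite {metabolite!r}: need >= 2 individuals with >= 2 observations"
        )

    bvar, a_u, b_u, a_e, b_e = prior.resolve(y, p)
    b0 = np.full(p, prior.beta_mean)
    XtX = X.T @ X
    beta_init, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_init = max(float(np.var(y, ddof=1)) / 2.0, 1e-8)

    C, S = config.n_chains, config.n_retained
    beta_out = np.empty((C, S, p))
    u_out = np.empty((C, S, N))
    s2u_out = np.empty((C, S))
    s2e_out = np.empty((C, S))
    resid_sum = np.zeros(n)
    resid_sumsq = np.zeros(n)

    for c, rng in enumerate(config.chain_rngs()):
        beta = beta_init.copy()
        u = np.zeros(N)
        s2u = s2e = s2_init
        k = 0
        for it in range(config.n_iter):
            # beta | u, s2e  (law given by beta_conditional_moments)
            prec = XtX / s2e + np.diag(1.0 / bvar)
            lin = X.T @ (y - u[idx]) / s2e + b0 / bvar
            try:
                L = linalg.cholesky(prec, lower=True)
            except linalg.LinAlgError as err:  # pragma: no cover
                raise RuntimeError(
                    f"non-positive-definite beta conditional at iteration {it}"
                ) from err
            mean = linalg.cho_solve((L, True), lin)
            beta = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(p), lower=False
            )
            # u_i | beta, s2u, s2e
            r = y - X @ beta
            prec_u = 1.0 / s2u + counts / s2e
            mean_u = (np.bincount(idx, weights=r, minlength=N) / s2e) / prec_u
            u = mean_u + rng.standard_normal(N) / np.sqrt(prec_u)
            # variance components
            s2u = _inv_gamma(rng, a_u + N / 2.0, b_u + 0.5 * float(u @ u))
            e = r - u[idx]
            s2e = _inv_gamma(rng, a_e + n / 2.0, b_e + 0.5 * float(e @ e))
            if not (np.isfinite(s2u) and np.isfinite(s2e)):
                raise RuntimeError(
                    f"divergent variance draw at iteration {it}; "
                    "consider rescaling the metabolite"
                )
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                    and k < S:
                beta_out[c, k] = beta
                u_out[c, k] = u
                s2u_out[c, k] = s2u
                s2e_out[c, k] = s2e
                resid_sum += e
                resid_sumsq += e * e
                k += 1

    total = C * S
    resid_var = float(np.mean(resid_sumsq / total - (resid_sum / total) ** 2))
    return UnivariatePosterior(
        metabolite=metabolite,
        beta_draws=beta_out,
        u_draws=u_out,
        sigma2_u_draws=s2u_out,
        sigma2_e_draws=s2e_out,
        individuals=[design.individuals[i] for i in keep_ind],
        covariates=design.covariates,
        resid_effect_var=resid_var,
    )


def fit_independent_model(
    design: DesignMatrices,
    config: MCMCConfig,
    prior: UnivariatePrior | None = None,
) -> list[UnivariatePosterior]:
    """Fit the univariate model to every metabolite independently.

    Metabolite ``m`` uses master seed ``config.seed + m`` so the M=1 case
    coincides with a single :func:`fit_univariate` call and streams are
    independent across metabolites.
    """
    fits = []
    for m, name in enumerate(design.metabolites):
        try:
            fits.append(fit_univariate(
                design, name, replace(config, seed=config.seed + m), prior
            ))
        except Exception as err:
            raise RuntimeError(f"univariate fit failed for {name!r}: {err}") from err
    return fits


@dataclass
class PriorSummaries:
    """Deterministic per-metabolite summaries feeding the multivariate prior."""

    metabolites: list[str]
    covariates: list[str]
    beta_mean: np.ndarray      # (L+1, M)
    beta_var: np.ndarray       # (L+1, M)
    sigma2_u_mean: np.ndarray  # (M,)
    sigma2_e_mean: np.ndarray  # (M,)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_fixed(self) -> int:
        return self.beta_mean.shape[0]


def summarize_for_prior(
    fits: list[UnivariatePosterior],
    variance_reading: str = "component_mean",
) -> PriorSummaries:
    """Stack pooled posterior summaries across metabolites.

    ``variance_reading`` selects what fills the scale-matrix diagonals:
    ``"component_mean"`` (default) takes the posterior means of sigma2_u and
    sigma2_e; ``"effect_variance"`` takes the dispersion of the sampled
    random effects / residual variance draws instead.
    """
    if variance_reading not in ("component_mean", "effect_variance"):
        raise ValueError(f"unknown variance_reading {variance_reading!r}")
    p = fits[0].beta_draws.shape[-1]
    if any(f.beta_draws.shape[-1] != p for f in fits):
        raise ValueError("fits have mismatched covariate structure")
    sums = [f.summaries() for f in fits]
    beta_mean = np.column_stack([s["beta_mean"] for s in sums])
    beta_var = np.column_stack([s["beta_var"] for s in sums])
    if variance_reading == "component_mean":
        s2u = np.array([s["sigma2_u_mean"] for s in sums])
        s2e = np.array([s["sigma2_e_mean"] for s in sums])
    else:
        s2u = np.array([s["u_effect_var"] for s in sums])
        s2e = np.array([s["resid_effect_var"] for s in sums])
    return PriorSummaries(
        metabolites=[f.metabolite for f in fits],
        covariates=fits[0].covariates,
        beta_mean=beta_mean,
        beta_var=beta_var,
        sigma2_u_mean=s2u,
        sigma2_e_mean=s2e,
    )
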