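"""Posterior-predictive distributions, HPD intervals and flagging.

For every individual ``i`` and timepoint ``t`` a posterior-predictive
distribution of the M metabolite levels is built from the retained draws:
each draw ``s`` contributes ``beta^(s)' x_it + u_i^(s) + eta`` with
``eta ~ Normal_M(0, R^(s))``.  A highest-posterior-density (HPD) prediction
interval is computed per metabolite at each requested level; an observed
value outside its interval flags the individual for intra-individual
variation in that metabolite at that timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data_model import DesignMatrices, MetaboDataset
from .multivariate import PosteriorDraws

logger = logging.getLogger("metabovar")

__all__ = [
    "PredictiveSamples",
    "predictive_draws",
    "hpd_interval",
    "flag_individuals",
    "summarize_flags",
    "FlagSummary",
    "pair_flag_counts",
    "replicate_datasets",
]

DEFAULT_LEVELS = (0.95, 0.975, 0.99)


def _chol(R: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; a zero matrix (noise-free limit) yields zeros."""
    if not R.any():
        return np.zeros_like(R)
    return linalg.cholesky(R, lower=True)


@dataclass
class PredictiveSamples:
    """Pooled posterior-predictive draws per (individual, timepoint) cell.

    ``draws`` is (S_total, n_cells, M); ``cells`` lists the
    (individual, timepoint) pairs in row order.
    """

    draws: np.ndarray
    cells: list[tuple]
    metabolites: list[str]

    def cell_index(self) -> dict:
        return {c: k for k, c in enumerate(self.cells)}


def predictive_draws(
    draws: PosteriorDraws,
    design: DesignMatrices,
    targets: list[tuple] | None = None,
    seed: int = 0,
) -> PredictiveSamples:
    """Posterior-predictive draws for each (individual, timepoint) target.

    Targets default to every (individual, timepoint) present in the design;
    each must belong to a fitted individual and have a covariate row
    available.  One residual draw eta per (retained draw, cell), from a
    seeded stream.
    """
    pos = {v: k for k, v in enumerate(draws.individuals)}
    rows = {(ind, int(t)): r for r, (ind, t) in enumerate(
        zip(design.row_index["individual"], design.row_index["timepoint"]))}
    if targets is None:
        targets = list(rows)
    X_rows = np.empty((len(targets), design.n_fixed))
    u_cols = np.empty(len(targets), dtype=np.int64)
    for k, (ind, t) in enumerate(targets):
        if ind not in pos:
            raise ValueError(f"individual {ind!r} was not in the fitted model")
        if (ind, int(t)) not in rows:
            raise ValueError(f"no covariate row available for ({ind!r}, {t})")
        X_rows[k] = design.X[rows[(ind, int(t))]]
        u_cols[k] = pos[ind]

    beta = draws.beta_pooled
    u = draws.u_pooled
    R = draws.R_pooled
    S = beta.shape[0]
    M = beta.shape[2]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.empty((S, len(targets), M))
    for s in range(S):
        mean = X_rows @ beta[s] + u[s][u_cols]
        L = _chol(R[s])
        out[s] = mean + rng.standard_normal((len(targets), M)) @ L.T
    return PredictiveSamples(draws=out, cells=[(i, int(t)) for i, t in targets],
                             metabolites=list(draws.metabolites))


def hpd_interval(samples: np.ndarray, level: float,
                 method: str = "hpd") -> tuple[float, float]:
    """Shortest interval containing a ``level`` fraction of the samples.

    Chen-Shao estimator: among all windows of ceil(level * S) consecutive
    order statistics, the one of minimal width; ties break toward the lower
    start index.  ``method="central"`` returns the equal-tail interval
    instead.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    S = samples.size
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if S < 100:
        raise ValueError(f"need >= 100 draws for an HPD interval, got {S}")
    k = math.ceil(level * S)
    if k > S:
        raise ValueError("required window exceeds the number of draws")
    if method == "central":
        lo, hi = np.quantile(samples, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)
    if method != "hpd":
        raise ValueError(f"unknown interval method {method!r}")
    s = np.sort(samples)
    widths = s[k - 1:] - s[: S - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) index on ties
    return float(s[i]), float(s[i + k - 1])


def flag_individuals(
    dataset: MetaboDataset,
    predictive: PredictiveSamples,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    method: str = "hpd",
) -> pd.DataFrame:
    """Build the flag table: one row per (individual, timepoint, metabolite, level).

    Columns: individual, timepoint, metabolite, level, lower, upper,
    observed, flagged.  ``flagged`` is a nullable boolean: NA where the
    observed value is missing (intervals are still reported).  Observed
    interval-nesting violations across levels (possible with empirical HPD
    windows) are logged, not hidden.
    """
    sc = dataset.schema
    cell_of = predictive.cell_index()
    observed: dict[tuple, np.ndarray] = {}
    for row in dataset.data.itertuples(index=False):
        d = row._asdict()
        key = (d[sc.id_col], int(d[sc.time_col]))
        observed[key] = np.array([d[m] for m in sc.metabolite_cols], dtype=float)
        if key not in cell_of and np.isfinite(observed[key]).any():
            raise ValueError(f"observed cell {key} has no predictive samples")

    levels = tuple(sorted(levels))
    records = []
    n_nest_violations = 0
    for key, k in cell_of.items():
        obs = observed.get(key)
        for m, met in enumerate(predictive.metabolites):
            samp = predictive.draws[:, k, m]
            prev = None
            for lev in levels:
                lo, hi = hpd_interval(samp, lev, method=method)
                if prev is not None and (lo > prev[0] or hi < prev[1]):
                    n_nest_violations += 1
                prev = (lo, hi)
                o = obs[m] if obs is not None else np.nan
                flagged = pd.NA if not np.isfinite(o) else bool(o < lo or o > hi)
                records.append((key[0], key[1], met, lev, lo, hi,
                                o if np.isfinite(o) else np.nan, flagged))
    if n_nest_violations:
        logger.warning("%d HPD interval nesting violations across levels",
                       n_nest_violations)
    table = pd.DataFrame(records, columns=[
        "individual", "timepoint", "metabolite", "level",
        "lower", "upper", "observed", "flagged",
    ])
    table["flagged"] = table["flagged"].astype("boolean")
    return table


@dataclass
class FlagSummary:
    """Per-level proportions of flagged individuals plus per-individual detail."""

    proportions: pd.DataFrame  # columns: level, n_flagged, n_total, proportion
    detail: pd.DataFrame       # per (individual, level): max metabolites flagged
    min_metabolites: int


def summarize_flags(flags: pd.DataFrame, min_metabolites: int) -> FlagSummary:
    """Proportion of individuals with >= ``min_metabolites`` metabolites flagged
    at some single timepoint, per HPD level.

    An individual counts once per level if *any* timepoint reaches the
    threshold; flags spread over several timepoints do not accumulate.
    """
    if flags.empty:
        raise ValueError("flag table is empty")
    n_mets = flags["metabolite"].nunique()
    if min_metabolites > n_mets:
        raise ValueError(
            f"min_metabolites={min_metabolites} exceeds M={n_mets}")
    individuals = flags["individual"].unique()
    counts = (
        flags[flags["flagged"] == True]  # noqa: E712 (nullable boolean)
        .groupby(["level", "individual", "timepoint"], sort=True)
        .size().rename("n_flagged").reset_index()
    )
    detail = (
        counts.groupby(["level", "individual"])["n_flagged"].max()
        .rename("max_flagged_in_a_timepoint").reset_index()
    )
    rows = []
    for lev in sorted(flags["level"].unique()):
        sub = detail[detail["level"] == lev]
        n_hit = int((sub["max_flagged_in_a_timepoint"] >= min_metabolites).sum())
        rows.append((lev, n_hit, len(individuals), n_hit / len(individuals)))
    proportions = pd.DataFrame(
        rows, columns=["level", "n_flagged", "n_total", "proportion"])
    return FlagSummary(proportions=proportions, detail=detail,
                       min_metabolites=min_metabolites)


def pair_flag_counts(
    flags: pd.DataFrame, min_metabolites: int, level: float,
) -> pd.DataFrame:
    """Symmetric M x M counts of individuals flagged on metabolite pairs.

    Restricted to individuals reaching ``min_metabolites`` flags at some
    single timepoint at the given level; entry (m, m') counts individuals
    with both metabolites flagged at the same timepoint (union over
    timepoints per individual); the diagonal counts individuals with m
    flagged at any timepoint, within the restricted set.
    """
    if level not in set(flags["level"].unique()):
        raise ValueError(f"level {level} not present in the flag table")
    mets = list(pd.unique(flags["metabolite"]))
    M = len(mets)
    sub = flags[(flags["level"] == level) & (flags["flagged"] == True)]  # noqa: E712
    per_it = sub.groupby(["individual", "timepoint"])["metabolite"].agg(list)
    qualifying = {ind for (ind, _), ms in per_it.items()
                  if len(ms) >= min_metabolites}
    counts = np.zeros((M, M), dtype=int)
    pos = {m: i for i, m in enumerate(mets)}
    for ind in qualifying:
        pairs: set[tuple[int, int]] = set()
        singles: set[int] = set()
        for (i2, _), ms in per_it.items():
            if i2 != ind:
                continue
            js = sorted(pos[m] for m in ms)
            singles.update(js)
            pairs.update((a, b) for ai, a in enumerate(js) for b in js[ai + 1:])
        for a, b in pairs:
            counts[a, b] += 1
            counts[b, a] += 1
        for a in singles:
            counts[a, a] += 1
    return pd.DataFrame(counts, index=mets, columns=mets)


def replicate_datasets(
    draws: PosteriorDraws,
    design: DesignMatrices,
    n_rep: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Posterior-predictive replicate response matrices.

    Replicate ``r`` uses one systematically spaced retained draw
    (beta, u, R)^(s_r) and simulates every design row as
    ``beta' x + u_i + Normal_M(0, R)``; row ordering matches the design, so
    ``design.row_index`` applies to every replicate.
    """
    beta = draws.beta_pooled
    u = draws.u_pooled
    R = draws.R_pooled
    S = beta.shape[0]
    if n_rep > S:
        raise ValueError(f"n_rep={n_rep} exceeds retained draw count {S}")
    idx = (np.arange(n_rep) * S) // n_rep
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reps = []
    for s in idx:
        mean = design.X @ beta[s] + u[s][design.indiv_idx]
        L = _chol(R[s])
        reps.append(mean + rng.standard_normal(mean.shape) @ L.T)
    return reps
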