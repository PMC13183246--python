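"""Repeated-measures metabolomics dataset: ingestion, validation, design matrices.

The data are a long table with one row per (individual, timepoint): an
individual identifier, an integer timepoint, ``L`` covariates (e.g. sex, age,
BMI) and ``M`` metabolite concentrations.  This module validates such tables,
builds the response/design matrices of the mixed model, and computes the
correlation summaries the prior construction and the simulation-study
evaluation rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metabovar")

__all__ = [
    "Schema",
    "MetaboDataset",
    "DesignMatrices",
    "read_metabolite_table",
    "build_design",
    "correlation_by_timepoint",
    "correlation_by_timepoint_from_matrix",
    "observed_sign_matrix",
]


@dataclass(frozen=True)
class Schema:
    """Column-role mapping for a metabolite CSV.

    Attributes
    ----------
    id_col : name of the individual-identifier column.
    time_col : name of the integer timepoint column (1-based).
    covariate_cols : ordered covariate column names (defines the column
        order of the fixed-effect design matrix after the intercept).
    metabolite_cols : ordered metabolite column names.
    """

    id_col: str
    time_col: str
    covariate_cols: tuple[str, ...]
    metabolite_cols: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.metabolite_cols)) != len(self.metabolite_cols):
            raise ValueError("metabolite column names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            id_col=spec["id"],
            time_col=spec["time"],
            covariate_cols=tuple(spec.get("covariates", [])),
            metabolite_cols=tuple(spec["metabolites"]),
        )


@dataclass
class MetaboDataset:
    """Validated repeated-measures table.

    ``data`` holds one row per (individual, timepoint), sorted by individual
    (order of first appearance) then timepoint.  Missing metabolite values
    are permitted; (individual, timepoint) pairs are unique; each individual
    contributes between 1 and T rows.
    """

    data: pd.DataFrame
    schema: Schema

    def __post_init__(self):
        self._validate()

    def _validate(self):
        df, sc = self.data, self.schema
        missing = [c for c in (sc.id_col, sc.time_col, *sc.covariate_cols,
                               *sc.metabolite_cols) if c not in df.columns]
        if missing:
            raise ValueError(f"schema names columns absent from table: {missing}")
        dup = df.duplicated(subset=[sc.id_col, sc.time_col], keep=False)
        if dup.any():
            pairs = df.loc[dup, [sc.id_col, sc.time_col]].drop_duplicates()
            raise ValueError(
                "duplicate (individual, timepoint) pairs: "
                + ", ".join(f"({r[0]}, {r[1]})" for r in pairs.itertuples(index=False))
            )
        t = df[sc.time_col]
        if not np.issubdtype(t.dtype, np.integer):
            raise ValueError("timepoint column must be integer-valued")
        if (t < 1).any():
            raise ValueError("timepoints must be 1-based positive integers")

    # -- dimension bookkeeping -------------------------------------------
    @property
    def individuals(self) -> list:
        return list(self.data[self.schema.id_col].drop_duplicates())

    @property
    def n_individuals(self) -> int:
        return self.data[self.schema.id_col].nunique()

    @property
    def n_timepoints(self) -> int:
        return int(self.data[self.schema.time_col].max())

    @property
    def metabolites(self) -> list[str]:
        return list(self.schema.metabolite_cols)

    @property
    def n_metabolites(self) -> int:
        return len(self.schema.metabolite_cols)

    @property
    def covariates(self) -> list[str]:
        return list(self.schema.covariate_cols)

    def metabolite_frame(self) -> pd.DataFrame:
        return self.data[list(self.schema.metabolite_cols)]


@dataclass
class DesignMatrices:
    """Response and design matrices of the mixed model.

    Y is (n_rows, M); X is (n_rows, L+1) with a leading all-ones intercept
    column; the individual-indicator design is stored as an integer index per
    row (``indiv_idx`` into ``individuals``) rather than materialising the
    binary expansion.  ``row_index`` maps every row back to its
    (individual, timepoint).
    """

    Y: np.ndarray
    X: np.ndarray
    indiv_idx: np.ndarray
    individuals: list
    row_index: pd.DataFrame
    metabolites: list[str]
    covariates: list[str]

    def __post_init__(self):
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X must share row count")
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_metabolites(self) -> int:
        return self.Y.shape[1]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    def timepoints_of(self) -> np.ndarray:
        return self.row_index["timepoint"].to_numpy()


def read_metabolite_table(path, schema: Schema) -> MetaboDataset:
    """Read and validate a metabolite CSV against a column-role schema.

    Raises on duplicate (individual, timepoint) pairs, on schema columns
    absent from the file, and on non-numeric metabolite cells (named by
    row and column).  Incomplete series (an individual missing some
    timepoints) are legal.
    """
    df = pd.read_csv(path)
    for col in schema.metabolite_cols:
        if col not in df.columns:
            raise ValueError(f"metabolite column {col!r} not in {path}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric metabolite value {df[col].iloc[row]!r} "
                f"in column {col!r}, data row {row}"
            )
        df[col] = coerced
    if schema.time_col not in df.columns:
        raise ValueError(f"timepoint column {schema.time_col!r} not in {path}")
    df[schema.time_col] = pd.to_numeric(df[schema.time_col], downcast="integer")
    df[schema.time_col] = df[schema.time_col].astype(np.int64)
    for col in schema.covariate_cols:
        df[col] = pd.to_numeric(df[col])

    # stable order: individuals by first appearance, then timepoint
    order = {v: k for k, v in enumerate(df[schema.id_col].drop_duplicates())}
    df = df.sort_values(
        by=[schema.id_col, schema.time_col],
        key=lambda s: s.map(order) if s.name == schema.id_col else s,
        kind="mergesort",
    ).reset_index(drop=True)

    ds = MetaboDataset(data=df, schema=schema)
    n_missing = int(ds.metabolite_frame().isna().to_numpy().sum())
    logger.info(
        "read %s: N=%d individuals, T=%d timepoints, M=%d metabolites, "
        "L=%d covariates, %d missing metabolite cells",
        path, ds.n_individuals, ds.n_timepoints, ds.n_metabolites,
        len(schema.covariate_cols), n_missing,
    )
    return ds


def build_design(dataset: MetaboDataset, complete_case: bool = True) -> DesignMatrices:
    """Construct Y, X and the individual index from a dataset.

    With ``complete_case`` (default) any row with a missing metabolite or
    covariate value is dropped from the likelihood; surviving rows are
    untouched.  Covariates enter X untransformed, in schema order after the
    intercept.
    """
    sc = dataset.schema
    df = dataset.data
    keep = np.ones(len(df), dtype=bool)
    if complete_case:
        keep &= df[list(sc.metabolite_cols)].notna().all(axis=1).to_numpy()
    if sc.covariate_cols:
        cov_ok = df[list(sc.covariate_cols)].notna().all(axis=1).to_numpy()
        if complete_case and not cov_ok.all():
            logger.warning("dropping %d rows with missing covariates",
                           int((~cov_ok & keep).sum()))
        keep &= cov_ok
    sub = df.loc[keep].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no usable rows after complete-case filtering")

    for col in sc.covariate_cols:
        if sub[col].nunique() <= 1:
            warnings.warn(f"covariate {col!r} has zero variance; kept as-is")

    Y = sub[list(sc.metabolite_cols)].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))]
        + [sub[c].to_numpy(dtype=float) for c in sc.covariate_cols]
    )
    individuals = list(sub[sc.id_col].drop_duplicates())
    pos = {v: k for k, v in enumerate(individuals)}
    indiv_idx = sub[sc.id_col].map(pos).to_numpy(dtype=np.int64)
    row_index = pd.DataFrame({
        "individual": sub[sc.id_col].to_numpy(),
        "timepoint": sub[sc.time_col].to_numpy(),
    })
    return DesignMatrices(
        Y=Y, X=X, indiv_idx=indiv_idx, individuals=individuals,
        row_index=row_index, metabolites=list(sc.metabolite_cols),
        covariates=list(sc.covariate_cols),
    )


def _corr(frame: pd.DataFrame, context: str) -> np.ndarray:
    """Pairwise-complete Pearson correlation with exact unit diagonal.

    A metabolite constant in ``frame`` gets NaN (undefined) correlations,
    with a warning; downstream consumers exclude NaN entries pairwise.
    """
    C = frame.corr(method="pearson").to_numpy()
    const = frame.std(ddof=1).fillna(0.0).to_numpy() == 0.0
    if const.any():
        names = [c for c, f in zip(frame.columns, const) if f]
        warnings.warn(f"constant metabolite(s) {names} in {context}: "
                      "correlations undefined (NaN)")
        C[const, :] = np.nan
        C[:, const] = np.nan
    np.fill_diagonal(C, 1.0)
    return C


def correlation_by_timepoint(dataset: MetaboDataset) -> list[np.ndarray]:
    """Pearson correlation of metabolite levels across individuals at each timepoint.

    Returns T matrices (M x M), pairwise-complete over missing cells, with
    exact unit diagonal.  Requires at least 3 individuals observed at every
    timepoint.
    """
    sc = dataset.schema
    out = []
    for t in range(1, dataset.n_timepoints + 1):
        sub = dataset.data.loc[dataset.data[sc.time_col] == t,
                               list(sc.metabolite_cols)]
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 individuals observed at timepoint {t}")
        out.append(_corr(sub, f"timepoint {t}"))
    return out


def correlation_by_timepoint_from_matrix(
    Y: np.ndarray, timepoints: np.ndarray, metabolites: list[str] | None = None
) -> list[np.ndarray]:
    """Per-timepoint correlation matrices of a raw response matrix.

    Used for posterior-predictive replicate matrices that share a design's
    row ordering but are not wrapped in a MetaboDataset.
    """
    cols = metabolites or [f"m{i}" for i in range(Y.shape[1])]
    out = []
    for t in np.sort(np.unique(timepoints)):
        sub = pd.DataFrame(Y[timepoints == t], columns=cols)
        out.append(_corr(sub, f"timepoint {t}"))
    return out


def observed_sign_matrix(dataset: MetaboDataset) -> np.ndarray:
    """Sign pattern (entries in {-1, +1}) of the pooled correlation of Y.

    The pooled (all rows) Pearson correlation of the observed metabolite
    matrix supplies the sign of each off-diagonal scale-matrix entry of the
    multivariate prior.  Convention: exact zeros and undefined correlations
    map to +1; the diagonal is +1.
    """
    C = _corr(dataset.metabolite_frame(), "pooled sign matrix")
    # tolerance so that exactly-orthogonal columns (zero up to rounding)
    # take the documented +1 convention
    S = np.where(np.nan_to_num(C, nan=0.0) < -1e-12, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S
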