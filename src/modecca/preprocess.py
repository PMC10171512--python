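"""Phenotype and connectome-edge cleaning.

Scikit-learn style transformers implementing the cleaning recipe used by
large population-imaging studies: eligibility filtering by missingness,
winsorisation at the 1st/99th percentiles, k-nearest-neighbour (k=1)
imputation, standardisation to zero mean / unit SD, and confound
regression (residualisation on age, sex, site and similar nuisance
covariates).

Tables are pandas DataFrames (subjects in rows, named variables in
columns) with NaN as the missing value; plain arrays are accepted too.
The canonical stage orders are::

    phenotypes:      filter -> winsorise -> impute -> standardise -> deconfound
    imaging edges:   winsorise -> standardise -> deconfound

provided by :func:`preprocess_phenotypes` / :func:`preprocess_imaging`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MissingnessFilter",
    "Winsoriser",
    "NearestNeighbourImputer",
    "Standardiser",
    "Deconfounder",
    "exclude_high_missing",
    "winsorise",
    "impute_knn",
    "standardise",
    "deconfound",
    "encode_confounds",
    "preprocess_phenotypes",
    "preprocess_imaging",
]


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(x, columns=[f"v{j}" for j in range(x.shape[1])])


class MissingnessFilter(BaseEstimator, TransformerMixin):
    """Drop variables whose missing fraction exceeds ``max_missing_fraction``."""

    def __init__(self, max_missing_fraction: float = 0.5):
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X, y=None):
        if not 0 < self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        df = _as_frame(X)
        frac = df.isna().mean(axis=0)
        keep = frac <= self.max_missing_fraction
        if not keep.any():
            raise ValueError(
                "missingness filter would drop every variable; "
                f"threshold {self.max_missing_fraction} too strict for this table"
            )
        self.kept_columns_ = list(df.columns[keep])
        self.dropped_columns_ = list(df.columns[~keep])
        return self

    def transform(self, X):
        return _as_frame(X)[self.kept_columns_]


class Winsoriser(BaseEstimator, TransformerMixin):
    """Clip each variable to its fitted lower/upper percentile bounds.

    Percentiles are computed over observed values only, with linear
    interpolation between order statistics.  Missing cells pass through
    untouched; an all-missing column is passed through with a warning.
    """

    def __init__(self, lower: float = 1.0, upper: float = 99.0):
        self.lower = lower
        self.upper = upper

    def fit(self, X, y=None):
        if not 0 <= self.lower < self.upper <= 100:
            raise ValueError("need 0 <= lower < upper <= 100")
        df = _as_frame(X)
        vals = df.to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            self.lower_bounds_ = np.nanpercentile(vals, self.lower, axis=0)
            self.upper_bounds_ = np.nanpercentile(vals, self.upper, axis=0)
        empty = np.isnan(self.lower_bounds_)
        if empty.any():
            names = list(df.columns[empty])
            warnings.warn(f"all-missing columns passed through unclipped: {names}")
        self.columns_ = list(df.columns)
        return self

    def transform(self, X):
        df = _as_frame(X)
        vals = df.to_numpy(float)
        lo = np.where(np.isnan(self.lower_bounds_), -np.inf, self.lower_bounds_)
        hi = np.where(np.isnan(self.upper_bounds_), np.inf, self.upper_bounds_)
        out = np.clip(vals, lo, hi)
        out[np.isnan(vals)] = np.nan
        return pd.DataFrame(out, index=df.index, columns=df.columns)


class NearestNeighbourImputer(BaseEstimator, TransformerMixin):
    """Fill missing cells from the nearest donor subject (default k=1).

    Distance between two subjects is the mean squared difference over the
    variables observed in both (Euclidean scaled by the shared-column
    count, so high-overlap pairs are not favoured).  Donors contribute
    only their observed, pre-imputation values; a cell's donor is the
    nearest subject with that variable observed, ties broken by the lowest
    donor index.  A subject sharing no observed column with any donor
    falls back to the column median (logged in ``fallback_log_``).
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        df = _as_frame(X)
        vals = df.to_numpy(float)
        if np.isnan(vals).all(axis=0).any():
            raise ValueError("every column needs at least one observed value")
        self.donor_values_ = vals
        self.donor_index_ = list(df.index)
        self.columns_ = list(df.columns)
        self.column_medians_ = np.nanmedian(vals, axis=0)
        return self

    def _distances(self, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean-squared-difference distances to every donor (rows: queries)."""
        donors = self.donor_values_
        q_obs = ~np.isnan(vals)
        d_obs = ~np.isnan(donors)
        q0 = np.where(q_obs, vals, 0.0)
        d0 = np.where(d_obs, donors, 0.0)
        shared = q_obs.astype(float) @ d_obs.T
        # sum over shared columns of (q - d)^2, assembled from three matmuls
        ssd = (
            (q0**2) @ d_obs.T
            + q_obs.astype(float) @ (d0**2).T
            - 2.0 * q0 @ d0.T
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(shared > 0, ssd / shared, np.inf)
        return dist, shared

    def transform(self, X):
        df = _as_frame(X)
        vals = df.to_numpy(float).copy()
        missing_rows = np.flatnonzero(np.isnan(vals).any(axis=1))
        if missing_rows.size == 0:
            return df.copy()
        dist, _ = self._distances(vals)
        donors = self.donor_values_
        donor_obs = ~np.isnan(donors)
        same_table = vals.shape == donors.shape and df.index.tolist() == list(
            self.donor_index_
        )
        self.fallback_log_ = getattr(self, "fallback_log_", [])
        for s in missing_rows:
            d = dist[s].copy()
            if same_table:
                d[s] = np.inf  # a subject never donates to itself
            order = np.argsort(d, kind="stable")
            for v in np.flatnonzero(np.isnan(vals[s])):
                eligible = order[donor_obs[order, v] & np.isfinite(d[order])]
                if eligible.size == 0:
                    vals[s, v] = self.column_medians_[v]
                    self.fallback_log_.append((df.index[s], self.columns_[v]))
                else:
                    vals[s, v] = donors[eligible[: self.k], v].mean()
        return pd.DataFrame(vals, index=df.index, columns=df.columns)


class Standardiser(BaseEstimator, TransformerMixin):
    """Zero-mean, unit-SD scaling with the sample (n-1) SD convention.

    Zero-variance columns are mapped to all-zero and recorded in
    ``zero_variance_columns_`` rather than raising.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        df = _as_frame(X)
        vals = df.to_numpy(float)
        self.means_ = np.nanmean(vals, axis=0)
        self.stds_ = np.nanstd(vals, axis=0, ddof=self.ddof)
        zero = self.stds_ < 1e-12
        self.zero_variance_columns_ = list(df.columns[zero])
        self.stds_ = np.where(zero, 1.0, self.stds_)
        self._zero_mask = zero
        return self

    def transform(self, X):
        df = _as_frame(X)
        out = (df.to_numpy(float) - self.means_) / self.stds_
        out[:, self._zero_mask] = 0.0
        return pd.DataFrame(out, index=df.index, columns=df.columns)


class Deconfounder(BaseEstimator, TransformerMixin):
    """Replace each variable by its least-squares residual on the confounds.

    An intercept is always included.  Rank-deficient confound designs are
    handled by dropping linearly dependent columns (pivoted QR); the names
    of dropped columns are logged in ``dropped_confounds_``.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def _design(self, confounds: pd.DataFrame) -> np.ndarray:
        c = confounds.to_numpy(float)
        if np.isnan(c).any():
            raise ValueError("confound table must be complete (no missing values)")
        if self.add_intercept:
            c = np.column_stack([np.ones(len(c)), c])
        return c

    def fit(self, X, confounds=None):
        df = _as_frame(X)
        conf = _as_frame(confounds)
        if len(conf) != len(df):
            raise ValueError("confounds must cover the same subjects in order")
        design = self._design(conf)
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        tol = abs(r[0, 0]) * max(design.shape) * np.finfo(float).eps
        rank = int((np.abs(np.diag(r)) > tol).sum())
        keep = np.sort(piv[:rank])
        names = ["intercept"] + list(conf.columns) if self.add_intercept else list(
            conf.columns
        )
        self.dropped_confounds_ = [names[j] for j in piv[rank:]]
        self._keep = keep
        design = design[:, keep]
        self.beta_, *_ = np.linalg.lstsq(design, df.to_numpy(float), rcond=None)
        self._fit_design = design
        return self

    def transform(self, X):
        df = _as_frame(X)
        resid = df.to_numpy(float) - self._fit_design @ self.beta_
        return pd.DataFrame(resid, index=df.index, columns=df.columns)

    def fit_transform(self, X, confounds=None, **kwargs):
        return self.fit(X, confounds=confounds).transform(X)


def encode_confounds(
    confounds: pd.DataFrame, categorical: tuple[str, ...] = ("site",)
) -> pd.DataFrame:
    """One-hot encode categorical confounds, dropping the first level.

    Columns named in ``categorical`` (plus any non-numeric column) are
    dummy-coded; everything else passes through as float.
    """
    cats = [
        c
        for c in confounds.columns
        if c in categorical or not pd.api.types.is_numeric_dtype(confounds[c])
    ]
    out = pd.get_dummies(
        confounds, columns=cats, drop_first=True, dtype=float
    )
    return out.astype(float)


# ---------------------------------------------------------------------------
# thin functional wrappers

def exclude_high_missing(table, max_missing_fraction: float = 0.5):
    f = MissingnessFilter(max_missing_fraction).fit(table)
    return f.transform(table), f.dropped_columns_


def winsorise(table, lower: float = 1.0, upper: float = 99.0):
    return Winsoriser(lower, upper).fit_transform(table)


def impute_knn(table, k: int = 1):
    return NearestNeighbourImputer(k).fit_transform(table)


def standardise(table, ddof: int = 1):
    return Standardiser(ddof).fit_transform(table)


def deconfound(table, confounds):
    return Deconfounder().fit_transform(table, confounds=confounds)


def preprocess_phenotypes(
    table,
    confounds,
    *,
    lower: float = 1.0,
    upper: float = 99.0,
    knn_k: int = 1,
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Full phenotype recipe: filter, winsorise, impute, standardise, deconfound."""
    filt = MissingnessFilter(max_missing_fraction).fit(table)
    out = filt.transform(table)
    out = winsorise(out, lower, upper)
    imputer = NearestNeighbourImputer(knn_k).fit(out)
    out = imputer.transform(out)
    out = standardise(out)
    out = deconfound(out, confounds)
    log = {
        "order": ["filter", "winsorise", "impute", "standardise", "deconfound"],
        "dropped_columns": filt.dropped_columns_,
        "median_fallbacks": getattr(imputer, "fallback_log_", []),
    }
    return out, log


def preprocess_imaging(
    table,
    confounds,
    *,
    lower: float = 1.0,
    upper: float = 99.0,
) -> tuple[pd.DataFrame, dict]:
    """Imaging-edge recipe: winsorise, standardise, deconfound (no missing data)."""
    df = _as_frame(table)
    if df.isna().any().any():
        raise ValueError("imaging block must be complete; impute or filter first")
    out = winsorise(df, lower, upper)
    winsorised = out
    out = standardise(out)
    out = deconfound(out, confounds)
    log = {"order": ["winsorise", "standardise", "deconfound"]}
    return out, {**log, "winsorised": winsorised}
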