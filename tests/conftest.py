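import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """30 subjects x 8 variables with ~20% missing cells."""
    vals = rng.standard_normal((30, 8))
    mask = rng.random((30, 8)) < 0.2
    # keep at least one observed value per column and per row
    mask[0] = False
    mask[:, 0] = False
    vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(vals, columns=[f"v{j}" for j in range(8)])


def brute_force_knn_impute(df: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """Independent nearest-donor imputation by exhaustive enumeration.

    Distance between subjects = mean squared difference over columns
    observed in both; per missing cell, the nearest donor (tie: lowest
    index) with that column observed supplies the value (mean of k nearest
    for k > 1); no eligible donor -> column median.
    """
    vals = df.to_numpy(float)
    out = vals.copy()
    n, p = vals.shape
    for s in range(n):
        for v in range(p):
            if not np.isnan(vals[s, v]):
                continue
            cands = []
            for d in range(n):
                if d == s or np.isnan(vals[d, v]):
                    continue
                shared = ~np.isnan(vals[s]) & ~np.isnan(vals[d])
                if not shared.any():
                    continue
                dist = np.mean((vals[s, shared] - vals[d, shared]) ** 2)
                cands.append((dist, d))
            if cands:
                cands.sort(key=lambda t: (t[0], t[1]))
                donors = [d for _, d in cands[:k]]
                out[s, v] = np.mean([vals[d, v] for d in donors])
            else:
                out[s, v] = np.nanmedian(vals[:, v])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def cca_correlations_eigen_oracle(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Canonical correlations by the generalised-eigenvalue route.

    Eigenvalues of Sxx^-1 Sxy Syy^-1 Syx are the squared canonical
    correlations; independent of the QR/SVD implementation under test.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = x.shape[0]
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    ev = np.sort(np.real(np.linalg.eigvals(m)))[::-1]
    k = min(x.shape[1], y.shape[1])
    return np.sqrt(np.clip(ev[:k], 0.0, 1.0))
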