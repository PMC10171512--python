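"""Partial-correlation connectomes from ROI time series.

An R-node connectome is summarised by the partial correlations between all
node pairs — the correlation between two nodes' time series after the other
R-2 series are regressed out, equal to ``-P_ij / sqrt(P_ii * P_jj)`` for the
precision matrix P.  The strict upper triangle, row-major, gives the
canonical edge vector: R(R-1)/2 features per subject (55 for the default
11-node interoceptive network).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NODES",
    "EdgeVector",
    "edge_pairs",
    "edge_names",
    "extract_roi_series",
    "partial_correlation",
    "vectorise",
    "devectorise",
    "subject_edge_table",
    "population_edge_means",
]

# 11 regions implicated in interoception: cingulate, insular, prefrontal,
# sensorimotor, amygdala and periaqueductal-grey nodes.
DEFAULT_NODES = (
    "dACC", "vACC", "aIC", "pIC", "dmPFC", "vmPFC",
    "Amy", "M1", "S1", "lPAG", "vlPAG",
)


def edge_pairs(nodes) -> list[tuple[str, str]]:
    """Ordered (i, j) node pairs over the strict upper triangle, row-major."""
    nodes = list(nodes)
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


def edge_names(nodes) -> list[str]:
    return [f"{a}__{b}" for a, b in edge_pairs(nodes)]


class EdgeVector:
    """Length-R(R-1)/2 vectorisation of a symmetric connectivity matrix."""

    def __init__(self, values: np.ndarray, nodes):
        self.nodes = list(nodes)
        self.values = np.asarray(values, dtype=float)
        expected = len(self.nodes) * (len(self.nodes) - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} edges for {len(self.nodes)} nodes, "
                f"got shape {self.values.shape}"
            )
        self.edge_index = edge_pairs(self.nodes)

    @property
    def names(self) -> list[str]:
        return [f"{a}__{b}" for a, b in self.edge_index]

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def extract_roi_series(image4d, masks, node_names=None) -> pd.DataFrame:
    """Mean time series within each binary ROI mask of a 4D image.

    ``image4d`` and each mask may be nibabel images or plain arrays on the
    same grid.  Returns a T x R DataFrame with one named column per ROI.
    """
    data = np.asarray(getattr(image4d, "dataobj", image4d), dtype=float)
    if data.ndim != 4:
        raise ValueError("image must be 4D (x, y, z, time)")
    names = list(node_names) if node_names is not None else [
        f"roi{i:02d}" for i in range(len(masks))
    ]
    series = {}
    for name, mask in zip(names, masks):
        m = np.asarray(getattr(mask, "dataobj", mask))
        if m.shape != data.shape[:3]:
            raise ValueError(
                f"mask '{name}' grid {m.shape} does not match image {data.shape[:3]}"
            )
        idx = m > 0
        if not idx.any():
            raise ValueError(f"mask '{name}' is empty")
        series[name] = data[idx, :].mean(axis=0)
    return pd.DataFrame(series)


def partial_correlation(ts, ridge: float = 0.0) -> np.ndarray:
    """Partial-correlation matrix of multivariate time series (T x R).

    Inverts the sample covariance (optionally ridge-stabilised with
    ``cov + ridge * I``) and normalises: entry (i, j) is
    ``-P_ij / sqrt(P_ii * P_jj)``; the diagonal is set to zero.
    """
    x = np.asarray(ts, dtype=float) if not isinstance(ts, pd.DataFrame) else ts.to_numpy()
    t, r = x.shape
    if t <= r:
        raise ValueError(f"need more timepoints ({t}) than nodes ({r})")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    cov = np.cov(x, rowvar=False)
    if ridge:
        cov = cov + ridge * np.eye(r)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance is singular; pass ridge > 0 to stabilise"
        ) from err
    d = 1.0 / np.sqrt(np.diag(prec))
    pc = -(d[:, None] * prec * d[None, :])
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 0.0)
    return pc


def vectorise(matrix: np.ndarray, nodes=None, atol: float = 1e-8) -> EdgeVector:
    """Strict upper triangle (row-major) of a symmetric matrix as an EdgeVector."""
    m = np.asarray(matrix, dtype=float)
    r = m.shape[0]
    if m.shape != (r, r):
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError(f"matrix not symmetric within {atol}")
    nodes = list(nodes) if nodes is not None else [f"n{i:02d}" for i in range(r)]
    iu = np.triu_indices(r, k=1)
    return EdgeVector(m[iu], nodes)


def devectorise(edges: EdgeVector) -> np.ndarray:
    """Symmetric matrix (zero diagonal) from an EdgeVector; inverse of vectorise."""
    r = len(edges.nodes)
    out = np.zeros((r, r))
    iu = np.triu_indices(r, k=1)
    out[iu] = edges.values
    return out + out.T


def subject_edge_table(
    timeseries: np.ndarray, nodes=None, ridge: float = 0.0, subject_ids=None
) -> pd.DataFrame:
    """Edge-vectorised partial correlations for a stack of subjects.

    ``timeseries`` has shape (n_subjects, T, R); the result is a
    subjects x R(R-1)/2 DataFrame with ``nodeA__nodeB`` column names.
    """
    ts = np.asarray(timeseries, dtype=float)
    n, _, r = ts.shape
    nodes = list(nodes) if nodes is not None else [f"n{i:02d}" for i in range(r)]
    rows = [vectorise(partial_correlation(ts[s], ridge=ridge), nodes).values
            for s in range(n)]
    ids = subject_ids if subject_ids is not None else [f"sub{i:05d}" for i in range(n)]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=edge_names(nodes))


def population_edge_means(edge_table: pd.DataFrame) -> pd.Series:
    """Across-subject mean of each edge, used downstream for sign adjustment.

    Should be computed on pre-standardisation values; an (almost) all-zero
    result triggers a warning because the sign information is then
    degenerate.
    """
    if len(edge_table) < 2:
        raise ValueError("need at least 2 subjects for population edge means")
    means = edge_table.mean(axis=0)
    if (means.abs() < 1e-12).all():
        import warnings

        warnings.warn(
            "population edge means are all ~0 (standardised input?); "
            "edge signs are degenerate"
        )
    return means
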