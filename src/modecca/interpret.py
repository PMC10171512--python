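"""Translate significant canonical modes back to original variables.

For each significant mode the two canonical variates are averaged (a
conservative summary robust to either block dominating), the average is
correlated with every processed original variable, and only loadings with
|r| >= 0.2 are reported.  Edge loadings are additionally multiplied by the
sign of the population-mean connectivity of that edge, so a positive
adjusted loading always reads "stronger connection in high-scoring
subjects".  A mode's variance explained is 100 * r^2 percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import CCAResult

__all__ = [
    "ModeReport",
    "average_variates",
    "back_project",
    "threshold_loadings",
    "sign_adjust_edges",
    "variance_explained",
    "build_mode_reports",
]


def average_variates(u, v) -> np.ndarray:
    """Elementwise mean of the two variates, re-standardised to unit variance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("variates must have equal length")
    avg = (u + v) / 2.0
    sd = avg.std(ddof=1)
    if sd < 1e-12:
        raise ValueError(
            "averaged variate has zero variance (u = -v): sign convention failure"
        )
    return (avg - avg.mean()) / sd


def back_project(avg_variate, original: pd.DataFrame) -> pd.Series:
    """Pearson correlation of the averaged variate with every original variable.

    Constant columns get loading 0 (with a warning) rather than NaN.
    """
    z = np.asarray(avg_variate, dtype=float)
    vals = original.to_numpy(dtype=float)
    if vals.shape[0] != z.size:
        raise ValueError("variate and table must cover the same subjects")
    n = z.size
    zc = (z - z.mean()) / z.std(ddof=1)
    xc = vals - vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    const = sd < 1e-12
    if const.any():
        warnings.warn(
            f"constant columns get zero loading: {list(original.columns[const])}"
        )
    sd = np.where(const, 1.0, sd)
    load = (xc / sd).T @ zc / (n - 1)
    load[const] = 0.0
    return pd.Series(np.clip(load, -1.0, 1.0), index=original.columns)


def threshold_loadings(loadings: pd.Series, threshold: float = 0.2) -> dict:
    """Keep loadings with |r| >= threshold (inclusive at the boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = loadings[np.abs(loadings.to_numpy()) >= threshold]
    return dict(keep)


def sign_adjust_edges(
    edge_loadings: pd.Series, edge_means: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Multiply each edge loading by the sign of its population-mean value.

    Edges with an exactly zero mean are passed through unadjusted; their
    names are returned as flags.
    """
    if not edge_loadings.index.equals(edge_means.index):
        edge_means = edge_means.reindex(edge_loadings.index)
        if edge_means.isna().any():
            raise ValueError("edge means do not cover all edge loadings")
    signs = np.sign(edge_means.to_numpy(dtype=float))
    flagged = list(edge_loadings.index[signs == 0])
    signs[signs == 0] = 1.0
    return edge_loadings * signs, flagged


def variance_explained(r: float) -> float:
    """Percent of variance shared by a mode: 100 * r^2 (full precision)."""
    if not 0 <= r <= 1:
        raise ValueError("canonical correlation must be in [0, 1]")
    return 100.0 * r * r


@dataclass
class ModeReport:
    """Interpretation of one significant canonical mode (1-based index)."""

    mode_index: int
    canonical_correlation: float
    p_value: float
    variance_explained_pct: float
    variable_loadings: dict = field(default_factory=dict)
    edge_loadings: dict = field(default_factory=dict)
    threshold: float = 0.2
    flagged_edges: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode_index,
            "canonical_correlation": round(self.canonical_correlation, 4),
            "p_value": self.p_value,
            "variance_explained_pct": round(self.variance_explained_pct, 2),
            "threshold": self.threshold,
            "variable_loadings": {k: round(v, 4) for k, v in
                                  self.variable_loadings.items()},
            "edge_loadings": {k: round(v, 4) for k, v in
                              self.edge_loadings.items()},
            "flagged_edges": self.flagged_edges,
        }


def build_mode_reports(
    cca: CCAResult,
    pvalues,
    X_orig: pd.DataFrame,
    Y_orig: pd.DataFrame,
    edge_means: pd.Series | None = None,
    *,
    threshold: float = 0.2,
    alpha: float = 0.05,
) -> tuple[list[ModeReport], pd.DataFrame, dict]:
    """One report per significant mode, plus an edge list and a summary.

    ``X_orig``/``Y_orig`` are the fully processed (non-PCA-reduced)
    variable tables; ``edge_means`` the pre-standardisation population
    edge means used for sign adjustment (skipped when ``None``).
    Returns ``(reports, edge_list, summary)`` where the edge list holds
    one row per retained edge per mode for graph rendering.
    """
    from .inference import significant_modes

    pvalues = np.asarray(pvalues, dtype=float)
    sig = significant_modes(pvalues, alpha)
    reports: list[ModeReport] = []
    edge_rows: list[dict] = []
    for i in sig:
        avg = average_variates(cca.variates_x[:, i], cca.variates_y[:, i])
        x_load = back_project(avg, X_orig)
        y_load = back_project(avg, Y_orig)
        flagged: list[str] = []
        if edge_means is not None:
            x_load, flagged = sign_adjust_edges(x_load, edge_means)
        report = ModeReport(
            mode_index=i + 1,
            canonical_correlation=float(cca.correlations[i]),
            p_value=float(pvalues[i]),
            variance_explained_pct=variance_explained(float(cca.correlations[i])),
            variable_loadings=threshold_loadings(y_load, threshold),
            edge_loadings=threshold_loadings(x_load, threshold),
            threshold=threshold,
            flagged_edges=flagged,
        )
        reports.append(report)
        for name, value in report.edge_loadings.items():
            a, _, b = name.partition("__")
            edge_rows.append(
                {"mode": i + 1, "nodeA": a, "nodeB": b or a,
                 "adjusted_loading": value}
            )
    edge_list = pd.DataFrame(
        edge_rows, columns=["mode", "nodeA", "nodeB", "adjusted_loading"]
    )
    summary = {
        "n_significant": len(sig),
        "total_variance_explained_pct": float(
            sum(r.variance_explained_pct for r in reports)
        ),
    }
    if not sig:
        summary["notice"] = "no significant modes at the requested alpha"
    return reports, edge_list, summary
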