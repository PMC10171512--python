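"""End-to-end orchestration: data in, audited mode reports out.

One call runs generate/load -> preprocess -> PCA-CCA -> permutation
inference -> mode interpretation and writes a results bundle: processed
tables, PCA and CCA summaries, the permutation null, per-mode reports and
a manifest capturing the configuration, package version and input hashes,
so any run can be reproduced from its bundle alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cca import PCACCA
from .connectome import DEFAULT_NODES, edge_names, population_edge_means
from .inference import build_null, mode_pvalues, significant_modes
from .interpret import build_mode_reports
from .preprocess import encode_confounds, preprocess_imaging, preprocess_phenotypes
from .simulate import GroundTruth, generate_two_block

__all__ = ["PipelineConfig", "run", "validate_inputs", "align_tables", "read_table"]

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """All analysis settings; defaults follow the reference protocol
    (80% PCA variance target, 1st/99th-percentile winsorisation, k=1
    imputation, 50% missingness cap, 100,000 permutations, alpha 0.05,
    |loading| >= 0.2)."""

    variance_target: float = 0.80
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    knn_k: int = 1
    max_missing_fraction: float = 0.5
    loading_threshold: float = 0.2
    n_permutations: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    ridge: float = 0.0
    confound_names: list = field(default_factory=lambda: ["age", "sex", "site"])
    categorical_confounds: list = field(default_factory=lambda: ["site"])
    missing_token: str = "NA"
    # file inputs (ignored when synthetic=True)
    x_table: str | None = None
    y_table: str | None = None
    confound_table: str | None = None
    # synthetic generation
    synthetic: bool = False
    n_subjects: int = 500
    p: int = 55
    q: int = 170
    rho: list = field(default_factory=lambda: [0.5, 0.3])
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    outdir: str = "modecca_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_table(path: str | Path, missing_token: str = "NA") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[missing_token],
                     keep_default_na=False, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject IDs in {path}: {dupes}")
    if len(set(df.columns)) != df.shape[1]:
        raise ValueError(f"duplicate column names in {path}")
    return df


def align_tables(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Realign tables to the sorted intersection of their subject IDs."""
    common = None
    for df in tables.values():
        ids = set(df.index)
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("no subject IDs shared by all tables")
    order = sorted(common)
    return {name: df.loc[order] for name, df in tables.items()}


def validate_inputs(
    x_path: str | Path,
    y_path: str | Path,
    confound_path: str | Path,
    *,
    missing_token: str = "NA",
    max_missing_fraction: float = 0.5,
) -> dict:
    """Structural checks on input tables before a run.

    Verifies unique headers and subject IDs, reports subject alignment,
    flags variables over the missingness cap, and summarises per-variable
    missingness (counts of variables per 10%-wide bin).
    """
    report: dict = {"ok": True, "issues": []}
    tables = {}
    for name, path in (("x", x_path), ("y", y_path), ("confounds", confound_path)):
        tables[name] = read_table(path, missing_token)
        report[f"n_{name}"] = tables[name].shape
    ids = [set(t.index) for t in tables.values()]
    shared = set.intersection(*ids)
    report["n_shared_subjects"] = len(shared)
    if any(len(s) != len(shared) for s in ids):
        report["issues"].append("subject IDs differ across tables; "
                                "aligned by sorted intersection")
    if tables["confounds"].isna().any().any():
        report["ok"] = False
        report["issues"].append("confound table has missing values")
    frac = tables["y"].isna().mean(axis=0)
    over = frac[frac > max_missing_fraction]
    report["flagged_for_exclusion"] = dict(over.round(4))
    hist, _ = np.histogram(frac.to_numpy(), bins=np.linspace(0, 1, 11))
    report["missingness_histogram"] = hist.tolist()
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="subject_id",
              float_format=_FLOAT_FMT)


def run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns the in-memory results bundle.

    Writes the serialised bundle to ``outdir`` (or ``config.outdir``).
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}
    input_hashes = {}

    if config.synthetic:
        truth = GroundTruth(
            true_rho=np.asarray(config.rho, dtype=float),
            seed=config.seed,
            missing_rate=config.missing_rate,
            outlier_rate=config.outlier_rate,
        )
        x_names = None
        r_nodes = len(DEFAULT_NODES)
        if config.p == r_nodes * (r_nodes - 1) // 2:
            x_names = edge_names(DEFAULT_NODES)
        x_raw, y_raw, confounds, truth = generate_two_block(
            config.n_subjects, config.p, config.q, truth, x_names=x_names
        )
        log["stages"].append({"stage": "generate",
                              "n_subjects": config.n_subjects,
                              "rho": list(map(float, truth.true_rho))})
    else:
        if not (config.x_table and config.y_table and config.confound_table):
            raise ValueError("x_table, y_table and confound_table are required "
                             "unless synthetic=True")
        tables = {
            "x": read_table(config.x_table, config.missing_token),
            "y": read_table(config.y_table, config.missing_token),
            "confounds": read_table(config.confound_table, config.missing_token),
        }
        for key, path in (("x", config.x_table), ("y", config.y_table),
                          ("confounds", config.confound_table)):
            input_hashes[key] = _sha256(Path(path))
        aligned = align_tables(tables)
        x_raw, y_raw, confounds = aligned["x"], aligned["y"], aligned["confounds"]
        if x_raw.isna().any().any():
            bad = list(x_raw.columns[x_raw.isna().any()])
            raise ValueError(f"imaging block has missing values in {bad}")
        truth = None
        log["stages"].append({"stage": "load",
                              "n_subjects": int(len(x_raw))})

    conf_design = encode_confounds(
        confounds[config.confound_names],
        categorical=tuple(config.categorical_confounds),
    )

    x_proc, x_log = preprocess_imaging(
        x_raw, conf_design,
        lower=config.lower_percentile, upper=config.upper_percentile,
    )
    edge_means = population_edge_means(x_log["winsorised"])
    log["stages"].append({"stage": "preprocess_x", "order": x_log["order"],
                          "n_variables": int(x_proc.shape[1])})

    y_proc, y_log = preprocess_phenotypes(
        y_raw, conf_design,
        lower=config.lower_percentile, upper=config.upper_percentile,
        knn_k=config.knn_k, max_missing_fraction=config.max_missing_fraction,
    )
    log["stages"].append({
        "stage": "preprocess_y", "order": y_log["order"],
        "dropped_columns": y_log["dropped_columns"],
        "n_variables": int(y_proc.shape[1]),
        "n_cells_imputed": int(y_raw[y_proc.columns].isna().sum().sum()),
    })

    model = PCACCA(config.variance_target).fit(x_proc, y_proc)
    log["stages"].append({
        "stage": "pca_cca",
        "x_components": int(model.pca_x_.n_components_),
        "x_cum_variance_pct": float(
            100 * model.pca_x_.explained_variance_ratio_[
                : model.pca_x_.n_components_].sum()),
        "y_components": int(model.pca_y_.n_components_),
        "y_cum_variance_pct": float(
            100 * model.pca_y_.explained_variance_ratio_[
                : model.pca_y_.n_components_].sum()),
        "correlations": [float(c) for c in model.correlations_],
    })

    null = build_null(model.scores_x_, model.scores_y_,
                      n_permutations=config.n_permutations, seed=config.seed)
    pvals = mode_pvalues(model.cca_, null)
    sig = significant_modes(pvals, config.alpha)
    log["stages"].append({"stage": "permutation",
                          "n_permutations": config.n_permutations,
                          "n_significant": len(sig)})

    reports, edge_list, summary = build_mode_reports(
        model.cca_, pvals, x_proc, y_proc, edge_means,
        threshold=config.loading_threshold, alpha=config.alpha,
    )

    # ---- serialise bundle -------------------------------------------------
    _write_tsv(x_proc, outdir / "processed_x.tsv")
    _write_tsv(y_proc, outdir / "processed_y.tsv")
    _write_tsv(conf_design, outdir / "confound_design.tsv")
    edge_means.to_csv(outdir / "edge_means.tsv", sep="\t",
                      header=["mean"], index_label="edge",
                      float_format=_FLOAT_FMT)
    mode_table = pd.DataFrame({
        "mode": np.arange(1, model.cca_.n_modes + 1),
        "canonical_correlation": model.correlations_,
        "p_value": pvals,
        "significant": [i in sig for i in range(model.cca_.n_modes)],
    })
    mode_table.to_csv(outdir / "modes.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    np.savetxt(outdir / "null_max_correlations.tsv",
               null.max_correlations, fmt=_FLOAT_FMT)
    _write_tsv(pd.DataFrame(model.cca_.variates_x, index=x_proc.index,
                            columns=[f"mode{i+1}" for i in
                                     range(model.cca_.n_modes)]),
               outdir / "variates_x.tsv")
    _write_tsv(pd.DataFrame(model.cca_.variates_y, index=y_proc.index,
                            columns=[f"mode{i+1}" for i in
                                     range(model.cca_.n_modes)]),
               outdir / "variates_y.tsv")
    edge_list.to_csv(outdir / "edge_list.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    (outdir / "mode_reports.json").write_text(json.dumps(
        {"modes": [r.to_json_dict() for r in reports], "summary": summary},
        indent=1, sort_keys=True))

    manifest = {
        "package": "modecca",
        "version": __version__,
        "config": asdict(config),
        "input_hashes": input_hashes,
        "conventions": {
            "percentiles": "linear interpolation between order statistics",
            "sd": "sample (n-1)",
            "p_value": "plus-one permutation estimator",
            "edge_order": "strict upper triangle, row-major",
        },
        "log": log,
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))

    return {
        "x_processed": x_proc,
        "y_processed": y_proc,
        "edge_means": edge_means,
        "model": model,
        "null": null,
        "pvalues": pvals,
        "significant": sig,
        "reports": reports,
        "edge_list": edge_list,
        "summary": summary,
        "manifest": manifest,
        "truth": truth,
    }
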