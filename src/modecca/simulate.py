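"""Synthetic two-block populations with planted canonical modes.

The real cohort behind this kind of analysis (large biobank imaging studies)
is access-restricted, so every downstream stage is exercised against data
whose population structure is known exactly.  Two devices provide that
ground truth:

* :func:`generate_two_block` plants ``K`` latent modes shared between an
  imaging-like block X and a phenotype-like block Y.  Mode ``k`` is built as

      x_k = sqrt(rho_k) * z_k + sqrt(1 - rho_k) * e_xk
      y_k = sqrt(rho_k) * z_k + sqrt(1 - rho_k) * e_yk

  with ``z`` and the ``e`` terms iid standard normal across subjects, so the
  population correlation of the pair is exactly ``rho_k``.  Each block is
  then mapped through a random orthogonal rotation, which leaves canonical
  correlations untouched, and finally contaminated with confound effects,
  missing cells and heavy-tailed outliers.

* :func:`generate_roi_timeseries` draws per-subject multivariate-normal time
  series from a known precision matrix, so the population partial
  correlation between nodes i and j is ``-P_ij / sqrt(P_ii * P_jj)`` in
  closed form.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "PrecisionSpec",
    "generate_two_block",
    "generate_roi_timeseries",
    "haar_orthogonal",
    "write_fixture",
    "make_phantom",
]

# Fixed per-stage offsets fanned out from the one global seed, so stages are
# reproducible independently of each other.
_SEED_OFFSETS = {
    "latent": 11,
    "rotation_x": 23,
    "rotation_y": 29,
    "confounds": 37,
    "confound_effects": 41,
    "missing": 43,
    "outliers": 47,
    "timeseries": 53,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SEED_OFFSETS[stage]])


def haar_orthogonal(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random orthogonal matrix via QR with sign-fixed diagonal."""
    a = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(a)
    # fix signs so the distribution is exactly Haar and the draw reproducible
    q *= np.sign(np.diag(r))
    return q


@dataclass
class GroundTruth:
    """Planted population structure of a two-block simulation.

    ``true_rho`` holds the K canonical correlations, strictly positive and
    non-increasing; ``loadings_x``/``loadings_y`` are the orthonormal signal
    directions in each block's observed coordinates (filled in by the
    generator when left ``None``).  Confound effects are per-variable
    coefficients on the encoded confound design.
    """

    true_rho: np.ndarray
    seed: int = 0
    loadings_x: np.ndarray | None = None
    loadings_y: np.ndarray | None = None
    confound_effects_x: np.ndarray | None = None
    confound_effects_y: np.ndarray | None = None
    missing_rate: float = 0.02
    outlier_rate: float = 0.01

    def __post_init__(self) -> None:
        self.true_rho = np.atleast_1d(np.asarray(self.true_rho, dtype=float))
        if self.true_rho.size and (
            np.any(self.true_rho <= 0) or np.any(self.true_rho > 1)
        ):
            raise ValueError("true_rho entries must lie in (0, 1]")
        if np.any(np.diff(self.true_rho) > 0):
            raise ValueError("true_rho must be non-increasing")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        for name in ("loadings_x", "loadings_y"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                gram = mat.T @ mat
                if not np.allclose(gram, np.eye(mat.shape[1]), atol=1e-10):
                    raise ValueError(f"{name} must have orthonormal columns")
                setattr(self, name, mat)

    @property
    def n_modes(self) -> int:
        return int(self.true_rho.size)

    def to_json_dict(self) -> dict:
        out = {
            "true_rho": self.true_rho.tolist(),
            "seed": int(self.seed),
            "missing_rate": float(self.missing_rate),
            "outlier_rate": float(self.outlier_rate),
        }
        for name in (
            "loadings_x",
            "loadings_y",
            "confound_effects_x",
            "confound_effects_y",
        ):
            mat = getattr(self, name)
            out[name] = None if mat is None else np.asarray(mat).tolist()
        return out


@dataclass
class PrecisionSpec:
    """Known inverse-covariance (precision) structure for ROI time series."""

    n_nodes: int
    precision: np.ndarray
    n_timepoints: int = 490  # one resting-state run in the emulated study

    def __post_init__(self) -> None:
        p = np.asarray(self.precision, dtype=float)
        if p.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("precision must be n_nodes x n_nodes")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(p).min() <= 0:
            raise ValueError("precision must be positive definite")
        self.precision = p

    def normalised(self) -> "PrecisionSpec":
        """Rescale to unit diagonal (correlation-like precision)."""
        d = 1.0 / np.sqrt(np.diag(self.precision))
        return PrecisionSpec(
            self.n_nodes, d[:, None] * self.precision * d[None, :], self.n_timepoints
        )

    def partial_correlations(self) -> np.ndarray:
        """Population partial-correlation matrix implied by the precision."""
        p = self.precision
        d = 1.0 / np.sqrt(np.diag(p))
        pc = -(d[:, None] * p * d[None, :])
        np.fill_diagonal(pc, 0.0)
        return pc


def _confound_design(confounds: pd.DataFrame) -> np.ndarray:
    """Numeric design used to inject confound effects: age, sex, site dummies."""
    parts = [
        confounds["age"].to_numpy(float),
        confounds["sex"].to_numpy(float),
    ]
    site = confounds["site"].to_numpy(int)
    for level in (1, 2):  # first level is the reference
        parts.append((site == level).astype(float))
    return np.column_stack(parts)


def generate_two_block(
    n_subjects: int,
    p: int,
    q: int,
    truth: GroundTruth,
    *,
    with_confounds: bool = True,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw an (X, Y, confounds) population with planted canonical modes.

    Returns the two subject-by-variable blocks, a confound table (``age``
    continuous, ``sex`` binary, ``site`` three-level categorical) and the
    completed :class:`GroundTruth` with realised loadings.  Missing cells are
    punched into Y completely at random at ``truth.missing_rate``; a fraction
    ``truth.outlier_rate`` of cells in both blocks is replaced by +/-8-SD
    excursions.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be at least 10")
    k = truth.n_modes
    if k > min(p, q):
        raise ValueError(f"K={k} exceeds min(p, q)={min(p, q)}")

    seed = int(truth.seed)
    rng = _stage_rng(seed, "latent")
    z = rng.standard_normal((n_subjects, k))
    ex = rng.standard_normal((n_subjects, p))
    ey = rng.standard_normal((n_subjects, q))

    rho = truth.true_rho
    base_x = ex.copy()
    base_y = ey.copy()
    if k:
        base_x[:, :k] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * ex[:, :k]
        base_y[:, :k] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * ey[:, :k]

    qx = haar_orthogonal(p, _stage_rng(seed, "rotation_x"))
    qy = haar_orthogonal(q, _stage_rng(seed, "rotation_y"))
    x = base_x @ qx.T
    y = base_y @ qy.T
    loadings_x = qx[:, :k]
    loadings_y = qy[:, :k]

    crng = _stage_rng(seed, "confounds")
    confounds = pd.DataFrame(
        {
            "age": crng.standard_normal(n_subjects),
            "sex": crng.integers(0, 2, n_subjects).astype(float),
            "site": crng.integers(0, 3, n_subjects),
        }
    )
    eff_x = truth.confound_effects_x
    eff_y = truth.confound_effects_y
    if with_confounds:
        design = _confound_design(confounds)
        erng = _stage_rng(seed, "confound_effects")
        if eff_x is None:
            eff_x = erng.normal(0.0, 0.3, size=(p, design.shape[1]))
        if eff_y is None:
            eff_y = erng.normal(0.0, 0.3, size=(q, design.shape[1]))
        x = x + design @ np.asarray(eff_x).T
        y = y + design @ np.asarray(eff_y).T
    else:
        eff_x = np.zeros((p, 4)) if eff_x is None else eff_x
        eff_y = np.zeros((q, 4)) if eff_y is None else eff_y

    if truth.outlier_rate > 0:
        orng = _stage_rng(seed, "outliers")
        for block in (x, y):
            mask = orng.random(block.shape) < truth.outlier_rate
            sd = block.std(axis=0, ddof=1)
            signs = np.where(orng.random(block.shape) < 0.5, -1.0, 1.0)
            excursion = block.mean(axis=0) + signs * 8.0 * sd
            block[mask] = np.broadcast_to(excursion, block.shape)[mask]

    if truth.missing_rate > 0:
        mrng = _stage_rng(seed, "missing")
        miss = mrng.random(y.shape) < truth.missing_rate
        y = np.where(miss, np.nan, y)

    subjects = [f"sub{i:05d}" for i in range(n_subjects)]
    x_names = x_names or [f"x{j:03d}" for j in range(p)]
    y_names = y_names or [f"y{j:03d}" for j in range(q)]
    x_df = pd.DataFrame(x, index=subjects, columns=x_names)
    y_df = pd.DataFrame(y, index=subjects, columns=y_names)
    confounds.index = pd.Index(subjects)

    completed = GroundTruth(
        true_rho=rho,
        seed=seed,
        loadings_x=loadings_x,
        loadings_y=loadings_y,
        confound_effects_x=np.asarray(eff_x, dtype=float),
        confound_effects_y=np.asarray(eff_y, dtype=float),
        missing_rate=truth.missing_rate,
        outlier_rate=truth.outlier_rate,
    )
    return x_df, y_df, confounds, completed


def generate_roi_timeseries(
    n_subjects: int, spec: PrecisionSpec, seed: int
) -> np.ndarray:
    """Per-subject T x R time series drawn from ``inv(spec.precision)``.

    Returns an array of shape ``(n_subjects, T, R)``.  Requires ``T > R + 2``
    so each subject's sample precision is estimable.
    """
    t, r = spec.n_timepoints, spec.n_nodes
    if t <= r + 2:
        raise ValueError(f"n_timepoints={t} too small for {r} nodes (need T > R + 2)")
    cov = np.linalg.inv(spec.precision)
    chol = np.linalg.cholesky(cov)
    rng = _stage_rng(int(seed), "timeseries")
    white = rng.standard_normal((n_subjects, t, r))
    return white @ chol.T


def make_phantom(
    series: np.ndarray,
    voxels_per_roi: int = 4,
    grid: tuple[int, int, int] | None = None,
):
    """Build a small 4D image plus binary ROI masks from a T x R series.

    Voxels inside mask ``r`` carry column ``r`` of ``series`` plus zero-sum
    per-voxel offsets, so the mask average reproduces the column exactly.
    Returns ``(image4d, masks)`` as ``nibabel.Nifti1Image`` objects.
    """
    import nibabel as nib

    series = np.asarray(series, dtype=float)
    t, r = series.shape
    n_vox = r * voxels_per_roi
    if grid is None:
        nx = int(np.ceil(n_vox ** (1 / 3)))
        grid = (nx, nx, max(1, int(np.ceil(n_vox / nx**2))))
    if np.prod(grid) < n_vox:
        raise ValueError("grid too small for requested ROI voxels")

    data = np.zeros((*grid, t))
    masks = []
    flat = np.unravel_index(np.arange(n_vox), grid)
    offsets = np.linspace(-1.0, 1.0, voxels_per_roi)
    offsets -= offsets.mean()  # zero-sum within each mask
    for roi in range(r):
        mask = np.zeros(grid, dtype=np.uint8)
        for v in range(voxels_per_roi):
            idx = roi * voxels_per_roi + v
            pos = (flat[0][idx], flat[1][idx], flat[2][idx])
            mask[pos] = 1
            data[pos] = series[:, roi] + offsets[v]
        masks.append(nib.Nifti1Image(mask, np.eye(4)))
    return nib.Nifti1Image(data, np.eye(4)), masks


def write_fixture(
    outdir: str | Path,
    tables: dict[str, pd.DataFrame],
    truth: GroundTruth | None = None,
    phantom_series: np.ndarray | None = None,
    voxels_per_roi: int = 4,
) -> dict[str, str]:
    """Serialise a simulation to delimited text (+ optional NIfTI phantom).

    Tables go to TSV with a header row, subject IDs in the first column and
    ``NA`` as the missing token; the ground truth goes to a JSON sidecar.
    Returns a map of logical name to file path with content hashes in
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", na_rep="NA", index_label="subject_id",
                  float_format="%.12g")
        written[name] = str(path)
    if truth is not None:
        path = outdir / "ground_truth.json"
        path.write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
        written["ground_truth"] = str(path)
    if phantom_series is not None:
        img, masks = make_phantom(phantom_series, voxels_per_roi=voxels_per_roi)
        path = outdir / "phantom.nii"
        img.to_filename(path)
        written["phantom"] = str(path)
        for i, mask in enumerate(masks):
            mpath = outdir / f"mask{i:02d}.nii"
            mask.to_filename(mpath)
            written[f"mask{i:02d}"] = str(mpath)
        np.savetxt(outdir / "phantom_series.tsv", phantom_series,
                   delimiter="\t", fmt="%.12g")
        written["phantom_series"] = str(outdir / "phantom_series.tsv")

    hashes = {
        name: hashlib.sha256(Path(path).read_bytes()).hexdigest()
        for name, path in written.items()
    }
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(hashes, indent=1, sort_keys=True))
    written["manifest"] = str(manifest)
    return written
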