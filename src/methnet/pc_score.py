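"""PCA-based discriminatory gene scoring from per-gene signal densities.

Individuals (rows) x genes (columns); the per-gene score is the absolute
PC1 loading (times a display scale).  With individuals << genes the
eigen-decomposition is done through the SVD of the centered matrix, which is
exact and cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca_signal", "retain_components", "gene_pc_scores"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # genes x components, orthonormal columns
    variance_fraction: np.ndarray
    scores: pd.DataFrame  # individuals x components


def pca_signal(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """Eigen-decomposition of the sample covariance (or correlation, with
    ``scale``) of the individuals x genes matrix."""
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    x = matrix.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = matrix.shape[0]
    eigenvalues = s**2 / (n - 1)
    ncomp = min(n - 1 if center else n, matrix.shape[1])
    eigenvalues = eigenvalues[:ncomp]
    loadings = pd.DataFrame(
        vt[:ncomp].T, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(ncomp)],
    )
    total = eigenvalues.sum()
    frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    scores = pd.DataFrame(
        u[:, :ncomp] * s[:ncomp], index=matrix.index, columns=loadings.columns,
    )
    return PCAResult(eigenvalues=eigenvalues, loadings=loadings,
                     variance_fraction=frac, scores=scores)


def retain_components(eigenvalues: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Indices (0-based) of components with eigenvalue > 1 plus each
    component's variance fraction (Guttman-Kaiser criterion)."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(eigenvalues) > 1e-9):
        raise ValueError("eigenvalues must be sorted descending")
    total = eigenvalues.sum()
    frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    kept = [int(i) for i in np.flatnonzero(eigenvalues > 1.0)]
    if not kept:
        warnings.warn("no component has eigenvalue > 1", stacklevel=2)
    return kept, frac


def gene_pc_scores(loadings_pc1: pd.Series, densities: pd.Series,
                   display_scale: float = 100.0) -> pd.DataFrame:
    """Ranked per-gene table: pc_score = |PC1 loading| * display_scale plus the
    gene's group-mean signal density variation, sorted by score descending."""
    scores = loadings_pc1.abs() * display_scale
    out = pd.DataFrame({
        "pc_score": scores,
        "signal_density_variation": densities.reindex(loadings_pc1.index),
    })
    out.index.name = "gene"
    return out.sort_values("pc_score", ascending=False, kind="mergesort")
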