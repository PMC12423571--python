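"""Environmental predictors: standardization, correlation PCA, raster means."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import Grid
from .rasters import Raster

__all__ = ["PcaResult", "standardize", "pca", "summarize_raster"]


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each column to mean 0, sd 1 (divisor n-1).

    Returns the standardized matrix and a two-row frame holding the means
    and standard deviations used, so the transform is reproducible.
    """
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    bad = sds[sds <= 0]
    if len(bad):
        raise ValueError(f"constant column(s): {list(bad.index)}")
    out = (matrix - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds}).T
    return out, params


@dataclass
class PcaResult:
    """Loadings, scores and variance fractions of a correlation-matrix PCA."""

    loadings: pd.DataFrame  # variables x components
    scores: np.ndarray  # cells x components
    variance_fractions: np.ndarray  # all p fractions, summing to 1

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(matrix: pd.DataFrame, k: int = 2) -> PcaResult:
    """PCA via eigendecomposition of the correlation matrix.

    The input is standardized internally, so the covariance of the
    standardized columns *is* the correlation matrix.  Components are
    ordered by decreasing eigenvalue; each loading vector is oriented so
    its largest-magnitude element is positive.
    """
    if k < 1 or k > matrix.shape[1]:
        raise ValueError("k must be between 1 and the number of variables")
    z, _ = standardize(matrix)
    R = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    fractions = evals / evals.sum()
    loadings = pd.DataFrame(
        evecs[:, :k],
        index=list(matrix.columns),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    scores = z.to_numpy() @ evecs[:, :k]
    return PcaResult(loadings, scores, fractions)


def summarize_raster(raster: Raster, grid: Grid) -> np.ndarray:
    """Unweighted per-cell mean of raster pixels whose centers fall in the cell.

    Cells with no valid (non-NaN) pixel get NaN and are reported by the
    caller.  Raises when the raster and grid extents are disjoint.
    """
    gx, gy = raster.pixel_centers()
    cells = grid.cell_of(gx.ravel(), gy.ravel())
    vals = raster.values.ravel()
    if not (cells >= 0).any():
        raise ValueError("raster extent is disjoint from the grid")
    out = np.full(grid.n_cells, np.nan)
    ok = (cells >= 0) & ~np.isnan(vals)
    sums = np.bincount(cells[ok], weights=vals[ok], minlength=grid.n_cells)
    counts = np.bincount(cells[ok], minlength=grid.n_cells)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out
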