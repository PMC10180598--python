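"""Per-tree spatial covariates: distance matrix, distance PCA, competition.

Three covariates summarise a tree's spatial context on the planting grid:

* the pairwise Euclidean **distance matrix** between all grid cells, in
  planting-distance units (one unit = one spacing interval, 3.05 m in
  the motivating trials);
* **distance principal components** (PC1-PC3): each cell's feature
  vector is its row of distances to every cell of the grid; the first
  three components of a column-centred (unscaled) PCA summarise the
  cell's overall spatial position and typically capture 98-100% of the
  distance variance on trial-scale grids;
* the **competition index**: the number of living stems (measured trees
  or live fillers) within a one-unit radius of the focal cell.  On a
  unit lattice only the four rook neighbours can qualify, so the index
  is an integer 0-4.

The distance matrix and PC scores are computed over *all* grid cells
(including empty positions) and later joined to measured trees only;
competition counts only living neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .geometry import TrialMap

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "distance_pca",
    "competition_index",
    "spatial_covariates",
]


@dataclass
class DistanceMatrix:
    """Euclidean distances between all grid cells of one trial.

    ``cells`` holds the 1-based (row, col) pair for each matrix index,
    row-major; ``entries`` is the symmetric distance matrix in grid
    units.
    """

    trial_id: str
    cells: np.ndarray  # (m, 2)
    entries: np.ndarray  # (m, m)


def pairwise_distances(tmap: TrialMap) -> DistanceMatrix:
    """Distance matrix over every cell of the complete trial grid."""
    if tmap.n_cells == 0:
        raise ValueError("empty trial map")
    cells = tmap.cells()
    entries = squareform(pdist(cells.astype(float)))
    return DistanceMatrix(trial_id=tmap.trial_id, cells=cells, entries=entries)


def distance_pca(dmat: DistanceMatrix, k: int = 3) -> tuple[pd.DataFrame, float]:
    """Principal-component scores of the distance matrix.

    Each cell's feature vector is its row of distances to all cells.
    Features are column-centred but not scaled.  The sign of each
    component is fixed so that its loading vector has a nonnegative sum
    (first nonzero loading positive on a tie), making scores
    reproducible bit-for-bit.

    Returns
    -------
    (scores, explained_fraction)
        ``scores`` has columns ``trial, row, col, pc1..pck`` with one row
        per grid cell; ``explained_fraction`` is the fraction of total
        distance-matrix variance captured by the ``k`` components.
    """
    m = dmat.entries.shape[0]
    if not (1 <= k <= m):
        raise ValueError(f"k={k} outside [1, {m}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(dmat.entries)
    loadings = pca.components_
    for i in range(k):
        s = loadings[i].sum()
        flip = s < 0
        if s == 0 and np.any(loadings[i]):
            flip = loadings[i][np.flatnonzero(loadings[i])[0]] < 0
        if flip:
            scores[:, i] = -scores[:, i]
            loadings[i] = -loadings[i]
    out = pd.DataFrame(
        {"trial": dmat.trial_id, "row": dmat.cells[:, 0], "col": dmat.cells[:, 1]}
    )
    for i in range(k):
        out[f"pc{i + 1}"] = scores[:, i]
    explained = float(pca.explained_variance_ratio_.sum())
    return out, explained


def competition_index(tmap: TrialMap, radius: float = 1.0) -> np.ndarray:
    """Count of living stems within ``radius`` grid units of each cell.

    Dead/missing positions exert no competition; the focal cell itself is
    excluded.  At the default unit radius on a unit lattice the count is
    bounded by the four rook neighbours.

    Returns an ``(n_rows, n_cols)`` integer array covering every cell.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    living = tmap.is_living().astype(int)
    counts = np.zeros_like(living)
    r = int(np.floor(radius))
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj == 0:
                continue
            if np.hypot(di, dj) > radius + 1e-12:
                continue
            src = living[
                max(0, -di) : living.shape[0] - max(0, di),
                max(0, -dj) : living.shape[1] - max(0, dj),
            ]
            counts[
                max(0, di) : living.shape[0] - max(0, -di),
                max(0, dj) : living.shape[1] - max(0, -dj),
            ] += src
    return counts


def spatial_covariates(tmap: TrialMap, k: int = 3, radius: float = 1.0) -> tuple[pd.DataFrame, float]:
    """Joined covariate table for one trial: PC scores plus competition.

    Convenience wrapper used by the model-assembly layer; one row per
    grid cell with columns ``trial, row, col, pc1..pck, competition``.
    """
    dmat = pairwise_distances(tmap)
    scores, explained = distance_pca(dmat, k=k)
    comp = competition_index(tmap, radius=radius)
    scores["competition"] = comp[scores["row"] - 1, scores["col"] - 1]
    return scores, explained
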