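"""Trial planting grids and *post hoc* block delineation.

Forest progeny trials analysed here were planted as randomized complete
block designs (RCBD) of single-tree plots on a regular square spacing
(one grid unit = one spacing interval).  Every analysis downstream needs
the *complete* planting grid -- including positions of dead, missing and
filler trees -- because spatial covariates and autoregressive residual
structures are defined on the full lattice.

Two after-the-fact ("post hoc") blocking schemes are supported:

* **complete row/column blocking** -- the grid rows are cut into a small
  number of contiguous tiers ("row blocks") and the columns likewise
  ("column blocks"), mirroring the physical tiers of the original layout;
* **incomplete sub-blocking** -- the grid is tiled by small rectangles
  (default 5 x 5 cells), giving finer row bands and column bands that are
  used as extra random factors to absorb micro-site heterogeneity.

Row indices increase south to north; the column direction follows the
trial's recorded layout and is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEASURED",
    "MISSING",
    "FILLER",
    "TrialMap",
    "BlockAssignment",
    "build_complete_grid",
    "assign_complete_blocks",
    "assign_incomplete_blocks",
]

#: occupancy codes for grid cells
MEASURED = "measured"
MISSING = "missing"
FILLER = "filler"

_STATUS_CODES = {MEASURED: 1, MISSING: 0, FILLER: 2}


@dataclass
class TrialMap:
    """Complete planting grid of one trial.

    Attributes
    ----------
    trial_id : str
        Trial label.
    n_rows, n_cols : int
        Grid dimensions.  Cells are addressed by 1-based ``(row, col)``.
    status : ndarray of str, shape (n_rows, n_cols)
        Occupancy of each cell: ``"measured"``, ``"missing"`` (dead or
        never planted) or ``"filler"`` (live border tree without
        phenotype).
    tree_id : ndarray of object, shape (n_rows, n_cols)
        Tree identifier per cell (``None`` where no tree).
    original_block : ndarray of object, shape (n_rows, n_cols)
        Replicate/block label of the original RCBD layout (``None`` where
        unknown).
    column_direction : str
        ``"W_TO_E"`` or ``"E_TO_W"``; metadata describing how column
        indices map onto the ground.
    """

    trial_id: str
    n_rows: int
    n_cols: int
    status: np.ndarray
    tree_id: np.ndarray
    original_block: np.ndarray
    column_direction: str = "W_TO_E"

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cells(self) -> np.ndarray:
        """All (row, col) pairs, 1-based, row-major."""
        rr, cc = np.meshgrid(
            np.arange(1, self.n_rows + 1), np.arange(1, self.n_cols + 1), indexing="ij"
        )
        return np.column_stack([rr.ravel(), cc.ravel()])

    def is_living(self) -> np.ndarray:
        """Boolean mask of cells holding a living stem (measured or filler)."""
        return (self.status == MEASURED) | (self.status == FILLER)

    def n_measured(self) -> int:
        return int((self.status == MEASURED).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table: one row per cell."""
        cells = self.cells()
        r0 = cells[:, 0] - 1
        c0 = cells[:, 1] - 1
        return pd.DataFrame(
            {
                "trial": self.trial_id,
                "row": cells[:, 0],
                "col": cells[:, 1],
                "status": self.status[r0, c0],
                "tree_id": self.tree_id[r0, c0],
                "original_block": self.original_block[r0, c0],
            }
        )


@dataclass
class BlockAssignment:
    """Post hoc block labels for every cell of one trial grid.

    ``row_block`` and ``col_block`` hold a label per cell (2-D object
    arrays).  Under the incomplete scheme ``subblock`` additionally holds
    the rectangle label formed by intersecting the row and column bands.
    """

    trial_id: str
    scheme: str  # "complete_row_column" | "incomplete_subblock"
    row_block: np.ndarray
    col_block: np.ndarray
    block_dims: tuple
    subblock: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        n_rows, n_cols = self.row_block.shape
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        out = pd.DataFrame(
            {
                "trial": self.trial_id,
                "row": rr.ravel() + 1,
                "col": cc.ravel() + 1,
                "row_block": self.row_block[rr.ravel(), cc.ravel()],
                "col_block": self.col_block[rr.ravel(), cc.ravel()],
            }
        )
        if self.subblock is not None:
            out["subblock"] = self.subblock[rr.ravel(), cc.ravel()]
        return out


def build_complete_grid(
    records: pd.DataFrame,
    n_rows: int,
    n_cols: int,
    *,
    trial_id: str | None = None,
    column_direction: str = "W_TO_E",
) -> TrialMap:
    """Build the complete planting grid for one trial.

    Parameters
    ----------
    records : DataFrame
        Phenotype records of a single trial with 1-based ``row`` and
        ``col`` columns.  Optional columns: ``tree_id``, ``status``
        (``measured``/``missing``/``filler``; default measured), and
        ``rep`` or ``block`` for the original RCBD block label.
    n_rows, n_cols : int
        Declared layout dimensions.

    Returns
    -------
    TrialMap
        Every cell of the ``n_rows x n_cols`` lattice is present; cells
        without a record are marked ``missing``.

    Raises
    ------
    ValueError
        On empty grid dimensions, coordinates outside the declared
        layout, or two records claiming the same cell.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    if trial_id is None:
        trial_id = str(records["trial"].iloc[0]) if "trial" in records and len(records) else "trial"

    status = np.full((n_rows, n_cols), MISSING, dtype=object)
    tree_id = np.full((n_rows, n_cols), None, dtype=object)
    original_block = np.full((n_rows, n_cols), None, dtype=object)

    if len(records):
        rows = np.asarray(records["row"], dtype=int)
        cols = np.asarray(records["col"], dtype=int)
        bad = (rows < 1) | (rows > n_rows) | (cols < 1) | (cols > n_cols)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"trial {trial_id}: coordinate ({rows[i]},{cols[i]}) outside "
                f"declared {n_rows}x{n_cols} layout"
            )
        flat = (rows - 1) * n_cols + (cols - 1)
        uniq, counts = np.unique(flat, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(
                f"trial {trial_id}: duplicate records at cell "
                f"(row={dup // n_cols + 1}, col={dup % n_cols + 1})"
            )
        rec_status = (
            records["status"].astype(str).to_numpy()
            if "status" in records
            else np.full(len(records), MEASURED, dtype=object)
        )
        unknown = set(rec_status) - set(_STATUS_CODES)
        if unknown:
            raise ValueError(f"unknown status value(s): {sorted(unknown)}")
        status[rows - 1, cols - 1] = rec_status
        if "tree_id" in records:
            tree_id[rows - 1, cols - 1] = records["tree_id"].to_numpy()
        blk_col = "rep" if "rep" in records else ("block" if "block" in records else None)
        if blk_col is not None:
            original_block[rows - 1, cols - 1] = records[blk_col].to_numpy()

    return TrialMap(
        trial_id=trial_id,
        n_rows=n_rows,
        n_cols=n_cols,
        status=status,
        tree_id=tree_id,
        original_block=original_block,
        column_direction=column_direction,
    )


def _bands(n: int, n_bands: int) -> np.ndarray:
    """Band index (0-based) for positions 0..n-1 cut into ``n_bands``
    contiguous bands whose sizes differ by at most one."""
    sizes = np.full(n_bands, n // n_bands, dtype=int)
    sizes[: n % n_bands] += 1
    return np.repeat(np.arange(n_bands), sizes)


def assign_complete_blocks(
    tmap: TrialMap, n_row_tiers: int, n_col_tiers: int
) -> BlockAssignment:
    """Cut the grid into complete row and column blocks (tiers).

    Rows are split into ``n_row_tiers`` contiguous bands and columns into
    ``n_col_tiers`` bands; band widths differ by at most one cell.  Each
    cell receives one row-block and one column-block label, prefixed with
    the trial id so labels are unique across trials.
    """
    if not (1 <= n_row_tiers <= tmap.n_rows):
        raise ValueError(f"n_row_tiers={n_row_tiers} outside [1, {tmap.n_rows}]")
    if not (1 <= n_col_tiers <= tmap.n_cols):
        raise ValueError(f"n_col_tiers={n_col_tiers} outside [1, {tmap.n_cols}]")
    rb = _bands(tmap.n_rows, n_row_tiers)
    cb = _bands(tmap.n_cols, n_col_tiers)
    row_block = np.empty((tmap.n_rows, tmap.n_cols), dtype=object)
    col_block = np.empty((tmap.n_rows, tmap.n_cols), dtype=object)
    for i in range(tmap.n_rows):
        for j in range(tmap.n_cols):
            row_block[i, j] = f"{tmap.trial_id}_RB{rb[i] + 1}"
            col_block[i, j] = f"{tmap.trial_id}_CB{cb[j] + 1}"
    return BlockAssignment(
        trial_id=tmap.trial_id,
        scheme="complete_row_column",
        row_block=row_block,
        col_block=col_block,
        block_dims=(n_row_tiers, n_col_tiers),
    )


def _fold_bands(n: int, size: int) -> np.ndarray:
    """Band index for positions 0..n-1 in bands of ``size`` cells; a
    remainder shorter than ``size`` is folded into the last band so that
    no band is smaller than ``size`` (avoids singleton blocks)."""
    idx = np.arange(n) // size
    n_bands = max(n // size, 1)
    return np.minimum(idx, n_bands - 1)


def assign_incomplete_blocks(
    tmap: TrialMap, block_rows: int = 5, block_cols: int = 5
) -> BlockAssignment:
    """Tile the grid with ``block_rows x block_cols`` rectangular
    sub-blocks, scanning row-major from cell (1, 1).

    Returns row-band and column-band labels (the two random factors used
    by the incomplete-blocking models) plus the intersection rectangle
    label.  Interior blocks all share the same dimensions; remainder
    cells along an axis are folded into the last band.
    """
    if block_rows <= 0 or block_cols <= 0:
        raise ValueError("block dimensions must be positive")
    if block_rows > tmap.n_rows or block_cols > tmap.n_cols:
        raise ValueError(
            f"block {block_rows}x{block_cols} exceeds grid "
            f"{tmap.n_rows}x{tmap.n_cols}"
        )
    rb = _fold_bands(tmap.n_rows, block_rows)
    cb = _fold_bands(tmap.n_cols, block_cols)
    row_block = np.empty((tmap.n_rows, tmap.n_cols), dtype=object)
    col_block = np.empty((tmap.n_rows, tmap.n_cols), dtype=object)
    subblock = np.empty((tmap.n_rows, tmap.n_cols), dtype=object)
    for i in range(tmap.n_rows):
        for j in range(tmap.n_cols):
            row_block[i, j] = f"{tmap.trial_id}_SR{rb[i] + 1}"
            col_block[i, j] = f"{tmap.trial_id}_SC{cb[j] + 1}"
            subblock[i, j] = f"{tmap.trial_id}_SB{rb[i] + 1}_{cb[j] + 1}"
    return BlockAssignment(
        trial_id=tmap.trial_id,
        scheme="incomplete_subblock",
        row_block=row_block,
        col_block=col_block,
        block_dims=(block_rows, block_cols),
        subblock=subblock,
    )
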