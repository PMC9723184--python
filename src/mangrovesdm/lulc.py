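"""Classification accuracy, post-classification change matrix, and per-grid
mangrove cover / degradation / accretion statistics.

The change accounting is post-classification: two independently classified
categorical maps are cross-tabulated cell by cell. Per-grid degradation and
accretion rates are the inputs the restoration-prioritization indicators
consume. When the LULC maps are at a finer sub-grid resolution than the
1-km analysis lattice (e.g. 30-m pixels), area fractions within each grid
cell are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridDefinition, GridMismatchError, LulcMap


@dataclass(frozen=True)
class ConfusionMatrix:
    """Reference-by-predicted class counts (rows = reference)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label list does not match matrix size")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ChangeMatrix:
    """Cell-count cross-tabulation of two LULC dates."""

    classes_t1: tuple[str, ...]
    classes_t2: tuple[str, ...]
    counts: np.ndarray
    cell_area: float = 1.0  # km^2 per counted cell

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes_t1), columns=list(self.classes_t2))

    def area(self, c1: str, c2: str) -> float:
        i = self.classes_t1.index(c1)
        j = self.classes_t2.index(c2)
        return float(self.counts[i, j]) * self.cell_area


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of reference samples classified correctly (trace/total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def kappa_coefficient(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e computed
    from the row and column margins. Returns 0 when p_e == 1 (degenerate
    single-class table).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / (n * n)
    if p_e >= 1.0 - 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def change_matrix(t1: LulcMap, t2: LulcMap) -> ChangeMatrix:
    """Exact cross-tabulation: counts[i, j] = cells labelled i at t1, j at t2."""
    if t1.codes.shape != t2.codes.shape or not t1.grid.same_geometry(t2.grid):
        raise GridMismatchError("the two LULC maps do not share a grid")
    k1, k2 = len(t1.classes), len(t2.classes)
    counts = np.zeros((k1, k2), dtype=int)
    np.add.at(counts, (t1.codes.ravel(), t2.codes.ravel()), 1)
    f = t1.subgrid_factor
    cell_area = t1.grid.cell_area / (f * f)
    return ChangeMatrix(tuple(t1.classes), tuple(t2.classes), counts, cell_area=cell_area)


def gridwise_mangrove_stats(
    grid: GridDefinition,
    t1: LulcMap,
    t2: LulcMap,
    mangrove_class: str = "mangrove",
) -> pd.DataFrame:
    """Per-grid mangrove cover, degradation rate and accretion rate.

    For each analysis grid cell:

    - ``mangrove_cover_pct_t2``: % of the cell's area under mangrove at t2;
    - ``degradation_rate_pct``: % of the cell's t1 mangrove area lost by t2
      (0 by convention when the cell had no t1 mangrove, flagged);
    - ``accretion_rate_pct``: % of the cell's t2 mangrove area newly gained
      since t1 (0 by convention when there is no t2 mangrove).

    At the 1-km analysis resolution each grid holds a single LULC cell;
    finer maps are aggregated by area fraction within each grid cell.
    """
    if t1.codes.shape != t2.codes.shape or not t1.grid.same_geometry(grid) or not t2.grid.same_geometry(grid):
        raise GridMismatchError("LULC maps do not cover the analysis grid")
    f = t1.subgrid_factor
    m1 = (t1.codes == t1.class_code(mangrove_class))
    m2 = (t2.codes == t2.class_code(mangrove_class))

    def per_grid(a: np.ndarray) -> np.ndarray:
        blocks = a.reshape(grid.n_rows, f, grid.n_cols, f)
        return blocks.sum(axis=(1, 3)).ravel().astype(float)

    n_sub = float(f * f)
    t1_m = per_grid(m1)
    t2_m = per_grid(m2)
    retained = per_grid(m1 & m2)
    new = per_grid(~m1 & m2)

    cover = 100.0 * t2_m / n_sub
    with np.errstate(divide="ignore", invalid="ignore"):
        degradation = np.where(t1_m > 0, 100.0 * (t1_m - retained) / t1_m, 0.0)
        accretion = np.where(t2_m > 0, 100.0 * new / t2_m, 0.0)
    return pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "mangrove_cover_pct_t2": cover,
            "degradation_rate_pct": degradation,
            "accretion_rate_pct": accretion,
            "no_t1_mangrove": t1_m == 0,
        }
    )
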