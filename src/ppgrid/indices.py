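"""Global diagnostic indices over selected cells and their paired comparisons.

Two per-eye summaries of a (segmentation, orientation) grid, computed over
the cells its heatmap selected (AUROC >= 0.70):

* mean index — the average thickness of the selected cells (micrometres);
* weighted index — the average of thickness x cell-AUROC over the selected
  cells (the AUROC weights come from the same heatmap).

The weighted index divides by the number of selected cells; dividing by
the sum of the weights instead would rescale every eye by the same
positive constant and therefore leave its AUROC — and every comparison
built on it — unchanged.  When all selected weights are equal, the two
indices are exactly proportional, so their AUROCs coincide and the paired
comparison is degenerate.

Comparisons are paired DeLong tests on the same eyes: mean vs weighted
index within a grid, and tilted vs horizontal grid for one index kind
(each orientation using its own selection).  A (segmentation,
orientation) whose selection is empty, or whose index AUROC falls below
0.70, is excluded from ranking and cutoff analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Cohort, Group, GridOrientation, Segmentation, ThicknessGridSet
from .heatmap import AurocHeatmap, CellSelection, select_cells
from .roc import AurocResult, DeLongComparison, auroc, delong_paired

__all__ = [
    "IndexKind",
    "EmptySelectionError",
    "GlobalIndexResult",
    "mean_index",
    "weighted_index",
    "compute_index",
    "index_auroc",
    "compare_mean_vs_weighted",
    "compare_orientations",
    "layer_ranking",
    "RankedLayer",
    "EXCLUSION_AUROC",
]

#: A layer whose global-index AUROC falls below this is excluded.
EXCLUSION_AUROC = 0.70


class IndexKind(enum.Enum):
    MEAN = "MEAN"
    WEIGHTED = "WEIGHTED"


class EmptySelectionError(ValueError):
    """Raised when an index is requested over an empty cell selection."""


def mean_index(gridset: ThicknessGridSet, selection: CellSelection) -> float:
    """Average thickness (um) of the selected cells for one eye."""
    if len(selection) == 0:
        raise EmptySelectionError(
            f"{selection.segmentation.value}/{selection.orientation.value}: "
            "no cells selected"
        )
    grid = gridset.grid(selection.segmentation, selection.orientation)
    return float(
        np.mean([grid[r - 1, c - 1] for r, c in selection.selected])
    )


def weighted_index(
    gridset: ThicknessGridSet, selection: CellSelection, heatmap: AurocHeatmap
) -> float:
    """Average of thickness x cell AUROC over the selected cells for one eye."""
    if len(selection) == 0:
        raise EmptySelectionError(
            f"{selection.segmentation.value}/{selection.orientation.value}: "
            "no cells selected"
        )
    grid = gridset.grid(selection.segmentation, selection.orientation)
    vals = [
        grid[r - 1, c - 1] * heatmap.cell(r, c).auc for r, c in selection.selected
    ]
    return float(np.mean(vals))


@dataclass
class GlobalIndexResult:
    """Per-eye index values and index-level AUROC for one grid.

    ``excluded`` is set when the selection is empty or the index AUROC is
    below :data:`EXCLUSION_AUROC`; excluded results carry no per-eye values
    when the selection is empty.
    """

    segmentation: Segmentation
    orientation: GridOrientation
    index_kind: IndexKind
    selection: CellSelection
    per_eye_value: dict[str, float]
    auroc: AurocResult | None
    excluded: bool = False
    exclusion_reason: str | None = None

    def group_values(self, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
        """(control, glaucoma) per-eye index vectors in cohort order."""
        control, glaucoma = [], []
        for rec in cohort.records:
            v = self.per_eye_value[rec.eye_id]
            (glaucoma if rec.group == Group.GLAUCOMA else control).append(v)
        return np.asarray(control), np.asarray(glaucoma)


def index_auroc(cohort: Cohort, per_eye_value: dict[str, float]) -> AurocResult:
    """AUROC of per-eye index values, control vs glaucoma."""
    control = [per_eye_value[r.eye_id] for r in cohort.records if r.group == Group.CONTROL]
    glaucoma = [per_eye_value[r.eye_id] for r in cohort.records if r.group == Group.GLAUCOMA]
    return auroc(control, glaucoma)


def compute_index(
    cohort: Cohort,
    heatmap: AurocHeatmap,
    kind: IndexKind,
    exclusion_auroc: float = EXCLUSION_AUROC,
) -> GlobalIndexResult:
    """Build the selection, per-eye index values and index AUROC for a grid."""
    selection = select_cells(heatmap)
    if len(selection) == 0:
        return GlobalIndexResult(
            segmentation=heatmap.segmentation,
            orientation=heatmap.orientation,
            index_kind=kind,
            selection=selection,
            per_eye_value={},
            auroc=None,
            excluded=True,
            exclusion_reason=(
                f"no cells with AUROC >= {selection.threshold:.2f}"
            ),
        )
    per_eye: dict[str, float] = {}
    for rec, gs in cohort:
        if kind == IndexKind.MEAN:
            per_eye[rec.eye_id] = mean_index(gs, selection)
        else:
            per_eye[rec.eye_id] = weighted_index(gs, selection, heatmap)
    res = index_auroc(cohort, per_eye)
    excluded = res.auc < exclusion_auroc
    return GlobalIndexResult(
        segmentation=heatmap.segmentation,
        orientation=heatmap.orientation,
        index_kind=kind,
        selection=selection,
        per_eye_value=per_eye,
        auroc=res,
        excluded=excluded,
        exclusion_reason=(
            f"index AUROC {res.auc:.3f} < {exclusion_auroc:.2f}" if excluded else None
        ),
    )


def _paired(cohort: Cohort, a: GlobalIndexResult, b: GlobalIndexResult) -> DeLongComparison:
    ca, ga = a.group_values(cohort)
    cb, gb = b.group_values(cohort)
    return delong_paired(ca, ga, cb, gb)


def compare_mean_vs_weighted(
    cohort: Cohort, mean_result: GlobalIndexResult, weighted_result: GlobalIndexResult
) -> DeLongComparison:
    """Paired DeLong test: mean vs weighted index on the same eyes."""
    if (
        mean_result.segmentation != weighted_result.segmentation
        or mean_result.orientation != weighted_result.orientation
    ):
        raise ValueError("mean/weighted comparison requires the same grid")
    return _paired(cohort, mean_result, weighted_result)


def compare_orientations(
    cohort: Cohort, tilted: GlobalIndexResult, horizontal: GlobalIndexResult
) -> DeLongComparison:
    """Paired DeLong test: tilted vs horizontal grid for one index kind.

    Each orientation uses its own cell selection; the comparison is between
    the two analysis products, not cell-matched quantities.
    """
    if tilted.segmentation != horizontal.segmentation:
        raise ValueError("orientation comparison requires the same segmentation")
    if tilted.index_kind != horizontal.index_kind:
        raise ValueError("orientation comparison requires the same index kind")
    return _paired(cohort, tilted, horizontal)


@dataclass(frozen=True)
class RankedLayer:
    segmentation: Segmentation
    auc: float | None
    excluded: bool
    reason: str | None


def layer_ranking(results: list[GlobalIndexResult]) -> list[RankedLayer]:
    """Segmentations ordered by descending index AUROC.

    Excluded layers (empty selection or AUROC < 0.70) sort last but remain
    listed, flagged with their reason.  Ties (and excluded layers among
    themselves) keep the canonical segmentation enumeration order.
    """
    order = {seg: i for i, seg in enumerate(Segmentation)}
    entries = []
    for res in results:
        auc = res.auroc.auc if res.auroc is not None else None
        entries.append(
            RankedLayer(
                segmentation=res.segmentation,
                auc=auc,
                excluded=res.excluded,
                reason=res.exclusion_reason,
            )
        )
    return sorted(
        entries,
        key=lambda e: (
            e.excluded,
            -(e.auc if (e.auc is not None and not e.excluded) else -np.inf),
            order[e.segmentation],
        ),
    )


def index_table(
    cohort: Cohort, results: list[GlobalIndexResult]
) -> pd.DataFrame:
    """Flat results table: one row per (segmentation, orientation, kind)."""
    rows = []
    for res in results:
        row = {
            "segmentation": res.segmentation.value,
            "orientation": res.orientation.value,
            "index_kind": res.index_kind.value,
            "n_selected_cells": len(res.selection),
            "excluded": res.excluded,
            "exclusion_reason": res.exclusion_reason or "",
        }
        if res.auroc is not None:
            row.update(
                auc=res.auroc.auc, ci_low=res.auroc.ci_low, ci_high=res.auroc.ci_high
            )
        else:
            row.update(auc=np.nan, ci_low=np.nan, ci_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
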