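"""Per-superpixel AUROC heatmaps and discriminative-cell selection.

For each (segmentation, orientation) the diagnostic ability of every one
of the 64 cells is summarised as the AUROC of its thickness (control vs
glaucoma), rendered with the study's colour rule — blue for AUROC <= 0.5,
white for 0.60-0.69, red for AUROC >= 0.70 — and cells with AUROC >= 0.70
are selected for the global indices.  The colour legend leaves the bands
(0.5, 0.6) and (0.69, 0.70) unnamed; they are shown as INTERMEDIATE here
and never influence selection, which uses only the >= 0.70 rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Cohort, Group, GridOrientation, Segmentation, cell_label
from .roc import AurocResult, auroc

__all__ = [
    "ColorClass",
    "AurocHeatmap",
    "CellSelection",
    "classify_color",
    "build_heatmap",
    "select_cells",
    "heatmap_frame",
    "plot_heatmap",
]

SELECTION_THRESHOLD = 0.70


class ColorClass(enum.Enum):
    BLUE = "BLUE"
    WHITE = "WHITE"
    RED = "RED"
    INTERMEDIATE = "INTERMEDIATE"


def classify_color(auc: float, threshold: float = SELECTION_THRESHOLD) -> ColorClass:
    """Colour class of one cell: blue <= 0.5, white in [0.60, 0.69],
    red >= threshold (0.70), INTERMEDIATE in the unnamed gaps."""
    if auc >= threshold:
        return ColorClass.RED
    if auc <= 0.5:
        return ColorClass.BLUE
    if 0.60 <= auc <= 0.69:
        return ColorClass.WHITE
    return ColorClass.INTERMEDIATE


@dataclass
class CellSelection:
    """Cells selected as discriminative (AUROC >= threshold); 1-based (row, col)."""

    segmentation: Segmentation
    orientation: GridOrientation
    selected: frozenset[tuple[int, int]]
    threshold: float = SELECTION_THRESHOLD

    def __len__(self) -> int:
        return len(self.selected)

    def labels(self) -> list[str]:
        return [cell_label(r, c) for r, c in sorted(self.selected)]


@dataclass
class AurocHeatmap:
    """8x8 map of per-cell AUROC results for one (segmentation, orientation)."""

    segmentation: Segmentation
    orientation: GridOrientation
    cells: list[list[AurocResult]]  # [row-1][col-1]
    threshold: float = SELECTION_THRESHOLD

    def cell(self, row: int, col: int) -> AurocResult:
        """1-based access by cell name indices."""
        return self.cells[row - 1][col - 1]

    @property
    def auc_matrix(self) -> np.ndarray:
        return np.array([[r.auc for r in row] for row in self.cells])

    @property
    def color_class(self) -> np.ndarray:
        return np.array(
            [[classify_color(r.auc, self.threshold) for r in row] for row in self.cells],
            dtype=object,
        )

    def argmax_cell(self) -> tuple[int, int]:
        """1-based (row, col) of the highest AUROC (first by row-major order)."""
        flat = int(np.argmax(self.auc_matrix))
        return flat // 8 + 1, flat % 8 + 1


def build_heatmap(
    cohort: Cohort,
    segmentation: Segmentation,
    orientation: GridOrientation,
    threshold: float = SELECTION_THRESHOLD,
) -> AurocHeatmap:
    """Per-cell AUROC of thickness across the cohort for one grid."""
    arr = cohort.thickness_array(segmentation, orientation)  # validates presence
    mask = cohort.group_mask(Group.GLAUCOMA)
    n_g, n_c = int(mask.sum()), int((~mask).sum())
    if n_g < 2 or n_c < 2:
        raise ValueError(
            f"need >= 2 eyes per group, got {n_c} control / {n_g} glaucoma"
        )
    control = arr[~mask]
    glaucoma = arr[mask]
    cells = [
        [auroc(control[:, r, c], glaucoma[:, r, c]) for c in range(8)]
        for r in range(8)
    ]
    return AurocHeatmap(
        segmentation=segmentation,
        orientation=orientation,
        cells=cells,
        threshold=threshold,
    )


def select_cells(heatmap: AurocHeatmap) -> CellSelection:
    """Cells with AUROC >= threshold (inclusive boundary); may be empty."""
    selected = frozenset(
        (r, c)
        for r in range(1, 9)
        for c in range(1, 9)
        if heatmap.cell(r, c).auc >= heatmap.threshold
    )
    return CellSelection(
        segmentation=heatmap.segmentation,
        orientation=heatmap.orientation,
        selected=selected,
        threshold=heatmap.threshold,
    )


def heatmap_frame(heatmap: AurocHeatmap) -> pd.DataFrame:
    """Long-format table of the heatmap (one row per cell)."""
    rows = []
    for r in range(1, 9):
        for c in range(1, 9):
            res = heatmap.cell(r, c)
            rows.append(
                {
                    "segmentation": heatmap.segmentation.value,
                    "orientation": heatmap.orientation.value,
                    "row": r,
                    "col": c,
                    "cell": cell_label(r, c),
                    "auc": res.auc,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "color": classify_color(res.auc, heatmap.threshold).value,
                }
            )
    return pd.DataFrame(rows)


_COLOR_RGB = {
    ColorClass.BLUE: (0.35, 0.55, 0.95),
    ColorClass.WHITE: (1.0, 1.0, 1.0),
    ColorClass.RED: (0.92, 0.30, 0.25),
    ColorClass.INTERMEDIATE: (0.88, 0.88, 0.88),
}


def plot_heatmap(heatmap: AurocHeatmap, path) -> None:
    """Render the heatmap as an image (row 1 inferior at the bottom,
    column 1 temporal on the left), annotated with AUROC values."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = heatmap.color_class
    img = np.array(
        [[_COLOR_RGB[colors[r, c]] for c in range(8)] for r in range(8)]
    )
    fig, ax = plt.subplots(figsize=(5.2, 5.2))
    ax.imshow(img, origin="lower", extent=(0.5, 8.5, 0.5, 8.5))
    auc = heatmap.auc_matrix
    for r in range(8):
        for c in range(8):
            ax.text(
                c + 1, r + 1, f"{auc[r, c]:.2f}",
                ha="center", va="center", fontsize=7,
            )
    ax.set_xticks(range(1, 9))
    ax.set_yticks(range(1, 9))
    ax.set_xlabel("column (temporal → nasal)")
    ax.set_ylabel("row (inferior → superior)")
    ax.set_title(
        f"{heatmap.segmentation.value} — {heatmap.orientation.value}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
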