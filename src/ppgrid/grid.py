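"""Data model for posterior-pole 8x8 macular thickness grids.

The Spectralis posterior-pole protocol exports, per eye and per retinal
segmentation, an 8x8 grid of 64 "superpixel" mean thicknesses (micrometres).
Cells are named ``r.c`` with row 1 inferior, row 8 superior, column 1
temporal and column 8 nasal *in right-eye convention*; the device exports
each eye in its own anatomical frame, so left-eye grids are mirrored
(column-reversed) at ingest and every downstream statistic sees all eyes as
right eyes.

Internally a grid is a ``numpy`` array of shape ``(8, 8)`` indexed
``[row-1, col-1]`` (0-based array, 1-based cell names).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Segmentation",
    "GridOrientation",
    "Laterality",
    "Group",
    "EyeRecord",
    "ThicknessGridSet",
    "Cohort",
    "CohortValidationError",
    "GridDimensionError",
    "cell_label",
    "parse_cell_label",
    "mirror_to_right_eye",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]


class Segmentation(enum.Enum):
    """Retinal segmentations exported by the posterior-pole software.

    The enumeration order is the canonical (deterministic) tie-break order
    used when ranking layers by diagnostic ability.  GCC is the ganglion
    cell complex (RNFL + GCL + IPL); GCLIPL is GCL + IPL; IRL/ORL are the
    inner/outer retinal layers; OPLONL combines the outer plexiform and
    outer nuclear layers.
    """

    RETINA = "RETINA"
    RNFL = "RNFL"
    GCL = "GCL"
    GCLIPL = "GCLIPL"
    GCC = "GCC"
    OPLONL = "OPLONL"
    IRL = "IRL"
    ORL = "ORL"


#: Segmentations whose thickness comes from inner retinal layers and is
#: expected to thin in glaucoma.  The outer layers (OPLONL, ORL) are spared.
INNER_SEGMENTATIONS = (
    Segmentation.RETINA,
    Segmentation.RNFL,
    Segmentation.GCL,
    Segmentation.GCLIPL,
    Segmentation.GCC,
    Segmentation.IRL,
)


class GridOrientation(enum.Enum):
    """Grid orientation: device-tilted (~7 deg, disc-fovea axis) or horizontal."""

    TILTED_7 = "TILTED_7"
    HORIZONTAL = "HORIZONTAL"


class Laterality(enum.Enum):
    RIGHT = "right"
    LEFT = "left"


class Group(enum.Enum):
    CONTROL = "control"
    GLAUCOMA = "glaucoma"


class GridDimensionError(ValueError):
    """Raised when a thickness grid is not exactly 8x8."""


class CohortValidationError(ValueError):
    """Raised on malformed cohort files; carries the offending keys."""

    def __init__(self, message: str, keys: list | None = None):
        super().__init__(message)
        self.keys = keys or []


def cell_label(row: int, col: int) -> str:
    """1-based cell name ``"r.c"`` (row 1 inferior, col 1 temporal)."""
    if not (1 <= row <= 8 and 1 <= col <= 8):
        raise ValueError(f"cell indices out of range: ({row}, {col})")
    return f"{row}.{col}"


def parse_cell_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`cell_label`."""
    try:
        r_s, c_s = label.split(".")
        row, col = int(r_s), int(c_s)
    except ValueError as exc:
        raise ValueError(f"malformed cell label {label!r}") from exc
    if not (1 <= row <= 8 and 1 <= col <= 8):
        raise ValueError(f"cell label out of range: {label!r}")
    return row, col


def mirror_to_right_eye(grid: np.ndarray, laterality: Laterality) -> np.ndarray:
    """Map a device-convention grid to right-eye anatomical convention.

    Right-eye grids are returned unchanged; left-eye grids have their
    columns reversed (column k <-> column 9-k) so that column 1 is temporal
    and column 8 nasal for every eye.  Rows (inferior -> superior) are
    unaffected.  The operation is an involution on left-eye grids.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (8, 8):
        raise GridDimensionError(f"expected an 8x8 grid, got shape {grid.shape}")
    if laterality == Laterality.RIGHT:
        return grid.copy()
    return grid[:, ::-1].copy()


@dataclass
class EyeRecord:
    """Clinical and demographic attributes of one eye.

    ``group`` and ``laterality`` are mandatory; clinical covariates may be
    missing (NaN).  ``bcva`` is decimal visual acuity, ``iop`` intraocular
    pressure in mmHg, ``cupping`` the vertical cup/disc ratio, and
    ``md``/``psd`` the visual-field mean deviation and pattern standard
    deviation in dB.
    """

    subject_id: str
    eye_id: str
    laterality: Laterality
    group: Group
    age: float = math.nan
    sex: str | None = None
    iop: float = math.nan
    bcva: float = math.nan
    cupping: float = math.nan
    md: float = math.nan
    psd: float = math.nan

    def __post_init__(self):
        if not isinstance(self.laterality, Laterality):
            self.laterality = Laterality(str(self.laterality).lower())
        if not isinstance(self.group, Group):
            self.group = Group(str(self.group).lower())
        if not math.isnan(self.age) and self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (math.isnan(self.cupping) or 0.0 <= self.cupping <= 1.0):
            raise ValueError(f"cupping must lie in [0, 1], got {self.cupping}")


@dataclass
class ThicknessGridSet:
    """Per-eye 8x8 thickness matrices keyed by (segmentation, orientation).

    All grids are stored in right-eye convention (row 1 inferior, column 1
    temporal); values are micrometres and must be positive and finite.
    """

    eye_id: str
    values: dict[tuple[Segmentation, GridOrientation], np.ndarray] = field(
        default_factory=dict
    )

    def set_grid(
        self, seg: Segmentation, orient: GridOrientation, grid: np.ndarray
    ) -> None:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (8, 8):
            raise GridDimensionError(f"expected an 8x8 grid, got shape {grid.shape}")
        if not np.all(np.isfinite(grid)) or np.any(grid <= 0):
            raise ValueError(
                f"thickness values for eye {self.eye_id}, {seg.value}/{orient.value} "
                "must be positive and finite"
            )
        self.values[(seg, orient)] = grid

    def grid(self, seg: Segmentation, orient: GridOrientation) -> np.ndarray:
        return self.values[(seg, orient)]

    def keys(self):
        return self.values.keys()


class Cohort:
    """An ordered collection of eyes: parallel lists of records and grid sets.

    Iterating yields ``(EyeRecord, ThicknessGridSet)`` pairs.  Convenience
    accessors return stacked numpy arrays for vectorised statistics.
    """

    def __init__(self, records: list[EyeRecord], grids: list[ThicknessGridSet]):
        if len(records) != len(grids):
            raise ValueError("records and grids must have equal length")
        for rec, gs in zip(records, grids):
            if rec.eye_id != gs.eye_id:
                raise ValueError(
                    f"record/grid eye_id mismatch: {rec.eye_id} vs {gs.eye_id}"
                )
        self.records = list(records)
        self.grids = list(grids)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[EyeRecord, ThicknessGridSet]]:
        return iter(zip(self.records, self.grids))

    @property
    def eye_ids(self) -> list[str]:
        return [r.eye_id for r in self.records]

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([r.group == group for r in self.records], dtype=bool)

    def n_in_group(self, group: Group) -> int:
        return int(self.group_mask(group).sum())

    def thickness_array(
        self, seg: Segmentation, orient: GridOrientation
    ) -> np.ndarray:
        """Stacked thickness grids, shape ``(n_eyes, 8, 8)``."""
        try:
            return np.stack([gs.grid(seg, orient) for gs in self.grids])
        except KeyError as exc:
            raise CohortValidationError(
                f"missing grids for {seg.value}/{orient.value}", [exc.args[0]]
            ) from exc

    def cell_values(
        self, seg: Segmentation, orient: GridOrientation, row: int, col: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(control, glaucoma) thickness vectors for one 1-based cell."""
        arr = self.thickness_array(seg, orient)[:, row - 1, col - 1]
        mask = self.group_mask(Group.GLAUCOMA)
        return arr[~mask], arr[mask]

    def segmentations(self) -> list[Segmentation]:
        segs = {k[0] for gs in self.grids for k in gs.keys()}
        return [s for s in Segmentation if s in segs]

    def orientations(self) -> list[GridOrientation]:
        orients = {k[1] for gs in self.grids for k in gs.keys()}
        return [o for o in GridOrientation if o in orients]


#: Exact column set of the long-format cohort file.
COHORT_COLUMNS = [
    "subject_id",
    "eye_id",
    "laterality",
    "group",
    "age",
    "sex",
    "iop",
    "bcva",
    "cupping",
    "md",
    "psd",
    "segmentation",
    "orientation",
    "row",
    "col",
    "thickness_um",
]

_CLINICAL_FLOATS = ["age", "iop", "bcva", "cupping", "md", "psd"]


def read_cohort(path: str | Path) -> Cohort:
    """Read a long-format cohort file and return grids in right-eye convention.

    One row per eye x segmentation x orientation x cell.  Validation:
    exact column set, recognised enum tokens (case-insensitive), positive
    thickness, no duplicate (eye, segmentation, orientation, cell) keys,
    all 64 cells present for every (segmentation, orientation) an eye
    carries, and a common (segmentation, orientation) set across eyes.
    Left-eye grids are mirrored so column 1 is temporal for every eye.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "eye_id": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(
            f"missing columns: {missing_cols}", missing_cols
        )
    if len(df) == 0:
        return Cohort([], [])

    try:
        df["segmentation"] = df["segmentation"].str.upper().map(
            lambda s: Segmentation(s)
        )
        df["orientation"] = df["orientation"].str.upper().map(
            lambda s: GridOrientation(s)
        )
    except ValueError as exc:
        raise CohortValidationError(f"unrecognised token: {exc}") from exc

    bad = df[~np.isfinite(df["thickness_um"]) | (df["thickness_um"] <= 0)]
    if len(bad):
        keys = [
            (r.eye_id, r.segmentation.value, r.orientation.value, int(r.row), int(r.col))
            for r in bad.itertuples()
        ]
        raise CohortValidationError(
            f"non-positive or non-finite thickness at {len(keys)} keys "
            f"(first: {keys[0]})",
            keys,
        )

    dup_mask = df.duplicated(
        subset=["eye_id", "segmentation", "orientation", "row", "col"], keep=False
    )
    if dup_mask.any():
        dups = df[dup_mask]
        keys = sorted(
            {
                (r.eye_id, r.segmentation.value, r.orientation.value, int(r.row), int(r.col))
                for r in dups.itertuples()
            }
        )
        raise CohortValidationError(
            f"duplicate cell rows for {len(keys)} keys (first: {keys[0]})", keys
        )

    records: list[EyeRecord] = []
    gridsets: list[ThicknessGridSet] = []
    key_sets: set[frozenset] = set()
    for eye_id, sub in df.groupby("eye_id", sort=False):
        first = sub.iloc[0]
        rec = EyeRecord(
            subject_id=str(first["subject_id"]),
            eye_id=str(eye_id),
            laterality=Laterality(str(first["laterality"]).lower()),
            group=Group(str(first["group"]).lower()),
            age=float(first["age"]) if pd.notna(first["age"]) else math.nan,
            sex=str(first["sex"]).lower() if pd.notna(first["sex"]) else None,
            iop=float(first["iop"]) if pd.notna(first["iop"]) else math.nan,
            bcva=float(first["bcva"]) if pd.notna(first["bcva"]) else math.nan,
            cupping=float(first["cupping"]) if pd.notna(first["cupping"]) else math.nan,
            md=float(first["md"]) if pd.notna(first["md"]) else math.nan,
            psd=float(first["psd"]) if pd.notna(first["psd"]) else math.nan,
        )
        gs = ThicknessGridSet(eye_id=str(eye_id))
        for (seg, orient), block in sub.groupby(
            ["segmentation", "orientation"], sort=False
        ):
            rows = block["row"].to_numpy(dtype=int)
            cols = block["col"].to_numpy(dtype=int)
            if np.any((rows < 1) | (rows > 8) | (cols < 1) | (cols > 8)):
                raise CohortValidationError(
                    f"cell indices out of range for eye {eye_id}, "
                    f"{seg.value}/{orient.value}"
                )
            present = set(zip(rows.tolist(), cols.tolist()))
            if len(present) != 64:
                missing = sorted(
                    cell_label(r, c)
                    for r in range(1, 9)
                    for c in range(1, 9)
                    if (r, c) not in present
                )
                raise CohortValidationError(
                    f"eye {eye_id}, {seg.value}/{orient.value}: missing cells "
                    f"{missing}",
                    [(eye_id, seg.value, orient.value, m) for m in missing],
                )
            grid = np.empty((8, 8))
            grid[rows - 1, cols - 1] = block["thickness_um"].to_numpy(dtype=float)
            gs.set_grid(seg, orient, mirror_to_right_eye(grid, rec.laterality))
        key_sets.add(frozenset(gs.keys()))
        records.append(rec)
        gridsets.append(gs)

    if len(key_sets) > 1:
        raise CohortValidationError(
            "eyes carry inconsistent (segmentation, orientation) sets"
        )
    return Cohort(records, gridsets)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the long format, in device (unmirrored) convention.

    Inverse of :func:`read_cohort`: left-eye grids are column-reversed back
    to the device frame on output, so a read/write round trip reproduces
    every thickness value exactly.
    """
    rows: list[dict] = []
    for rec, gs in cohort:
        base = {
            "subject_id": rec.subject_id,
            "eye_id": rec.eye_id,
            "laterality": rec.laterality.value,
            "group": rec.group.value,
            "age": rec.age,
            "sex": rec.sex if rec.sex is not None else "",
            "iop": rec.iop,
            "bcva": rec.bcva,
            "cupping": rec.cupping,
            "md": rec.md,
            "psd": rec.psd,
        }
        for (seg, orient), grid in gs.values.items():
            device = mirror_to_right_eye(grid, rec.laterality)  # involution
            for r in range(1, 9):
                for c in range(1, 9):
                    row = dict(base)
                    row.update(
                        segmentation=seg.value,
                        orientation=orient.value,
                        row=r,
                        col=c,
                        thickness_um=device[r - 1, c - 1],
                    )
                    rows.append(row)
    out = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    # 17 significant digits: lossless binary64 round trip through text
    out.to_csv(path, index=False, float_format="%.17g")
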