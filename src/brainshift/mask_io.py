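"""Binary segmentation masks on world-anchored voxel grids, plus cohort tables.

Every metric in this package operates on world coordinates (mm).  The
contract established here: voxel indices are 0-based, a voxel's world
position is the position of its *center*, and the affine of a NIfTI file
maps index ``(i, j, k)`` to that center.  Masks being compared must share
a grid (shape and affine within tolerance); resampling is always explicit.
"""

from __future__ import annotations

import csv
import decimal
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "CaseRecord",
    "GridMismatchError",
    "MaskFormatError",
    "CohortValidationError",
    "read_mask",
    "write_mask",
    "resample_to_grid",
    "read_cohort",
    "write_cohort",
    "reference_cohort_path",
    "load_reference_cohort",
    "round_half_away",
    "COHORT_COLUMNS",
    "US_QUALITY_LABELS",
]

GRID_ATOL = 1e-4

US_QUALITY_LABELS = ("excellent", "good", "sufficient", "poor")

COHORT_COLUMNS = [
    "case_id",
    "vol_pre_mri_cm3",
    "vol_pre_us_cm3",
    "vol_res_ius_cm3",
    "vol_post_us_cm3",
    "vol_post_mri_cm3",
    "cog_offset_mm",
    "hausdorff_mm",
    "dice",
    "us_quality",
    "exclude_pre",
    "exclude_pre_reason",
    "exclude_post",
    "exclude_post_reason",
]


class MaskFormatError(ValueError):
    """Raised when a mask file is not a readable 3D NIfTI volume."""


class GridMismatchError(ValueError):
    """Raised when two masks that must share a grid do not."""


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the documented schema."""


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (report/display convention).

    numpy and Python's built-in ``round`` use banker's rounding; published
    tables conventionally round 17.55 -> 17.6, so we do too.  The value is
    first snapped to a fine decimal grid so that binary representation
    error (e.g. the exact mean of 17.5 and 17.6 being 17.549999...997)
    cannot flip a decimal tie.
    """
    snapped = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-(ndigits + 6)), rounding=decimal.ROUND_HALF_UP
    )
    exponent = decimal.Decimal(1).scaleb(-ndigits)
    if snapped >= 0:
        rounded = snapped.quantize(exponent, rounding=decimal.ROUND_HALF_UP)
    else:
        rounded = -(-snapped).quantize(exponent, rounding=decimal.ROUND_HALF_UP)
    return float(rounded)


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D image: shape, spacing (mm), origin and orientation.

    ``origin`` is the world position (mm) of the center of voxel (0, 0, 0);
    ``orientation`` is a 3x3 direction matrix with orthonormal columns.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        R = np.asarray(self.orientation, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "orientation", tuple(map(tuple, R)))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @classmethod
    def from_affine(cls, shape: Sequence[int], affine: np.ndarray) -> "VoxelGrid":
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
            raise MaskFormatError("affine must be a finite 4x4 matrix")
        M = affine[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        if np.any(spacing <= 0):
            raise MaskFormatError("affine has a zero-length column (degenerate spacing)")
        orientation = M / spacing
        return cls(
            shape=tuple(int(s) for s in shape),
            spacing=tuple(spacing),
            origin=tuple(affine[:3, 3]),
            orientation=tuple(map(tuple, orientation)),
        )

    def index_to_world(self, indices) -> np.ndarray:
        """Map voxel indices (..., 3) to world-mm coordinates of voxel centers."""
        idx = np.asarray(indices, dtype=float)
        return idx @ (self.direction_matrix @ np.diag(self.spacing)).T + np.asarray(
            self.origin
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def approx_equal(self, other: "VoxelGrid", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass
class BinaryMask:
    """A segmented object: a set of foreground voxels on a :class:`VoxelGrid`.

    Stored as a boolean array for efficiency; ``voxel_indices`` exposes the
    voxel-set view used by the metric definitions.
    """

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = data.astype(bool)

    @classmethod
    def from_indices(cls, grid: VoxelGrid, indices: Iterable[tuple]) -> "BinaryMask":
        data = np.zeros(grid.shape, dtype=bool)
        idx = np.asarray(list(indices), dtype=int)
        if idx.size:
            if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
                raise ValueError("voxel index outside grid shape")
            data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return cls(grid=grid, data=data)

    @property
    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer array of foreground voxel indices."""
        return np.argwhere(self.data)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxel_indices.tolist()}

    def world_coordinates(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of foreground voxel centers."""
        return self.grid.index_to_world(self.voxel_indices)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def same_content(self, other: "BinaryMask", atol: float = GRID_ATOL) -> bool:
        return self.grid.approx_equal(other.grid, atol) and bool(
            np.array_equal(self.data, other.data)
        )


def read_mask(path) -> BinaryMask:
    """Read a NIfTI-1 volume as a binary mask (foreground = values > 0.5)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise MaskFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskFormatError(
            f"{path}: expected a 3D volume, got {data.ndim} dimensions"
        )
    if img.affine is None or not np.all(np.isfinite(img.affine)):
        raise MaskFormatError(f"{path}: unreadable or non-finite affine")
    grid = VoxelGrid.from_affine(data.shape, img.affine)
    return BinaryMask(grid=grid, data=data > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as NIfTI-1 (uint8 0/1, grid affine honored)."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def resample_to_grid(mask: BinaryMask, grid: VoxelGrid) -> BinaryMask:
    """Nearest-neighbor resample of a mask onto another grid.

    Never called implicitly: metric functions require shared grids and the
    caller decides when resampling is legitimate.
    """
    if mask.grid.approx_equal(grid):
        return BinaryMask(grid=grid, data=mask.data.copy())
    # target index -> world -> source index
    T = np.linalg.inv(mask.grid.affine) @ grid.affine
    coords = np.indices(grid.shape, dtype=float).reshape(3, -1)
    src = T[:3, :3] @ coords + T[:3, 3:4]
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8), src, order=0, mode="constant", cval=0
    )
    return BinaryMask(grid=grid, data=out.reshape(grid.shape) > 0)


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass
class CaseRecord:
    """One row of the per-case cohort table.

    Volumes in cm^3, distances in mm; ``None`` means missing/not assessed.
    ``vol_res_ius_cm3`` is the residual volume seen on intraoperative US that
    triggered an extension of the resection.
    """

    case_id: str
    vol_pre_mri_cm3: float | None = None
    vol_pre_us_cm3: float | None = None
    vol_res_ius_cm3: float | None = None
    vol_post_us_cm3: float | None = None
    vol_post_mri_cm3: float | None = None
    cog_offset_mm: float | None = None
    hausdorff_mm: float | None = None
    dice: float | None = None
    us_quality: str | None = None
    exclude_pre: bool = False
    exclude_pre_reason: str = ""
    exclude_post: bool = False
    exclude_post_reason: str = ""

    def __post_init__(self) -> None:
        for name in (
            "vol_pre_mri_cm3",
            "vol_pre_us_cm3",
            "vol_res_ius_cm3",
            "vol_post_us_cm3",
            "vol_post_mri_cm3",
            "cog_offset_mm",
            "hausdorff_mm",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortValidationError(
                    f"case {self.case_id}: {name} must be >= 0, got {v}"
                )
        if self.dice is not None and not (0.0 <= self.dice <= 1.0):
            raise CohortValidationError(
                f"case {self.case_id}: dice must lie in [0, 1], got {self.dice}"
            )
        if self.us_quality is not None and self.us_quality not in US_QUALITY_LABELS:
            raise CohortValidationError(
                f"case {self.case_id}: unknown US quality label {self.us_quality!r}"
            )


def _parse_float(cell: str, column: str, case_id: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise CohortValidationError(
            f"case {case_id}: column {column} is not numeric: {cell!r}"
        ) from exc


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"true", "1", "yes"}


def read_cohort(path) -> list[CaseRecord]:
    """Read a cohort CSV (comma-separated, UTF-8, dot decimals, header row)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != COHORT_COLUMNS:
            raise CohortValidationError(
                f"{path}: header must be exactly {','.join(COHORT_COLUMNS)}"
            )
        records = []
        for row in reader:
            case_id = row["case_id"].strip()
            if not case_id:
                raise CohortValidationError(f"{path}: row with empty case_id")
            quality = row["us_quality"].strip().lower() or None
            records.append(
                CaseRecord(
                    case_id=case_id,
                    vol_pre_mri_cm3=_parse_float(row["vol_pre_mri_cm3"], "vol_pre_mri_cm3", case_id),
                    vol_pre_us_cm3=_parse_float(row["vol_pre_us_cm3"], "vol_pre_us_cm3", case_id),
                    vol_res_ius_cm3=_parse_float(row["vol_res_ius_cm3"], "vol_res_ius_cm3", case_id),
                    vol_post_us_cm3=_parse_float(row["vol_post_us_cm3"], "vol_post_us_cm3", case_id),
                    vol_post_mri_cm3=_parse_float(row["vol_post_mri_cm3"], "vol_post_mri_cm3", case_id),
                    cog_offset_mm=_parse_float(row["cog_offset_mm"], "cog_offset_mm", case_id),
                    hausdorff_mm=_parse_float(row["hausdorff_mm"], "hausdorff_mm", case_id),
                    dice=_parse_float(row["dice"], "dice", case_id),
                    us_quality=quality,
                    exclude_pre=_parse_bool(row["exclude_pre"]),
                    exclude_pre_reason=row["exclude_pre_reason"].strip(),
                    exclude_post=_parse_bool(row["exclude_post"]),
                    exclude_post_reason=row["exclude_post_reason"].strip(),
                )
            )
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_cohort(records: Sequence[CaseRecord], path) -> None:
    """Write records to CSV in the documented schema (round-trips exactly)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([_format_cell(getattr(r, c)) for c in COHORT_COLUMNS])


def reference_cohort_path() -> Path:
    """Path of the packaged 31-case glioblastoma iUS cohort table."""
    return Path(
        resources.files("brainshift").joinpath("data/glioblastoma_ius_cohort.csv")
    )


def load_reference_cohort() -> list[CaseRecord]:
    return read_cohort(reference_cohort_path())
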