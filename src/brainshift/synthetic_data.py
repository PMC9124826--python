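"""Synthetic phantom mask pairs and cohorts with known ground truth.

No public image archive carries co-registered MRI / intraoperative-3D-US
tumor segmentations, so validation rests on phantoms whose differences are
constructed from the three ingredients that separate an intraoperative US
segmentation from its MRI counterpart: a rigid translation (brain shift of
a few mm), a smooth elastic deformation (tissue distortion, probe
pressure), and boundary segmentation noise (observer variability at the
tumor margin).

The base object is a digitized irregular ellipsoid: a ball whose radius is
modulated by a smooth low-order function of direction.  The "US" mask is
the base mask warped through translation plus a Gaussian-smoothed random
displacement field, with nearest-neighbor resampling so masks stay binary,
followed by random flips of surface voxels.  Everything is deterministic
given the integer seed in the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .mask_io import BinaryMask, CaseRecord, VoxelGrid
from . import metrics

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "GenerationError",
    "default_grid",
    "make_phantom",
    "make_cohort",
    "sample_case",
]

DEFAULT_SPACING_MM = 0.5
DEFAULT_SHAPE = 96

# cohort-level defaults emulate the marginal structure of the clinical
# cohort this package was built around: log-normally dispersed tumor
# volumes (median ~16 cm^3, spanning ~0.5-95 cm^3), shifts of a few mm
# (mean ~3.9 mm, range ~0.25-13 mm), roughly a third of cases left with
# residual tumor, and an ultrasound-triggered extension of resection in
# about a fifth of the complete resections.
DEFAULT_VOLUME_MEDIAN_CM3 = 16.3
DEFAULT_VOLUME_SIGMA_LOG = 0.89
DEFAULT_SHIFT_MEAN_MM = 3.9
DEFAULT_SHIFT_SIGMA_LOG = 0.58
DEFAULT_STR_FRACTION = 10 / 28
DEFAULT_EXTENSION_FRACTION = 4 / 18
_QUALITY_PROBS = {"excellent": 17 / 31, "good": 8 / 31, "sufficient": 5 / 31, "poor": 1 / 31}


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be generated on the requested grid."""


def default_grid(
    shape: int = DEFAULT_SHAPE, spacing_mm: float = DEFAULT_SPACING_MM
) -> VoxelGrid:
    """Isotropic cube grid centered on the world origin."""
    origin = -(shape - 1) / 2.0 * spacing_mm
    return VoxelGrid(
        shape=(shape, shape, shape),
        spacing=(spacing_mm, spacing_mm, spacing_mm),
        origin=(origin, origin, origin),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic mask pair."""

    seed: int
    grid: VoxelGrid = field(default_factory=default_grid)
    base_radius_mm: float = 10.0
    shape_irregularity: float = 0.15  # relative amplitude of radial modulation
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    elastic_sigma_mm: float = 6.0  # correlation length of the displacement field
    elastic_amp_mm: float = 1.0  # maximum displacement magnitude
    boundary_noise_prob: float = 0.05  # per-surface-voxel flip probability

    def __post_init__(self) -> None:
        if self.base_radius_mm < 3.0 * max(self.grid.spacing):
            raise ValueError(
                "base_radius_mm must be at least 3x the largest spacing "
                "(object not resolvable)"
            )
        if not (0.0 <= self.shape_irregularity < 1.0):
            raise ValueError("shape_irregularity must lie in [0, 1)")
        if self.elastic_amp_mm < 0 or self.elastic_sigma_mm <= 0:
            raise ValueError("elastic parameters must be nonnegative (sigma > 0)")
        if not (0.0 <= self.boundary_noise_prob <= 1.0):
            raise ValueError("boundary_noise_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomPair:
    mask_mri: BinaryMask
    mask_us: BinaryMask
    spec: PhantomSpec
    true_shift_mm: float


def _radial_modulation(rng: np.random.Generator, units: np.ndarray) -> np.ndarray:
    """Smooth low-order function of direction with max |value| = 1.

    A random combination of linear and centered quadratic forms in the
    direction cosines — band-limited on the sphere, so the object boundary
    stays smooth at any resolution.
    """
    g = np.zeros(units.shape[0])
    for _ in range(3):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        g += rng.normal() * (units @ v)
    for _ in range(6):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        g += rng.normal() * ((units @ v) ** 2 - 1.0 / 3.0)
    peak = np.abs(g).max()
    return g / peak if peak > 0 else g


def _check_not_clipped(data: np.ndarray, what: str) -> None:
    if (
        data[0].any() or data[-1].any()
        or data[:, 0].any() or data[:, -1].any()
        or data[:, :, 0].any() or data[:, :, -1].any()
    ):
        raise GenerationError(f"{what} touches the grid boundary; enlarge the grid")


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one co-registered MRI-like / US-like mask pair."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    shape = grid.shape

    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    world = grid.index_to_world(idx)
    center_idx = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    center = grid.index_to_world(center_idx)
    offsets = world - center
    r = np.linalg.norm(offsets, axis=1)
    units = np.divide(offsets, r[:, None], out=np.zeros_like(offsets), where=r[:, None] > 0)

    radius = spec.base_radius_mm
    if spec.shape_irregularity > 0:
        radius = spec.base_radius_mm * (
            1.0 + spec.shape_irregularity * _radial_modulation(rng, units)
        )
    base = (r <= radius).reshape(shape)
    if not base.any():
        raise GenerationError("base object contains no voxels")
    _check_not_clipped(base, "base object")

    # inverse warp: output voxel x samples the base mask at x - t - d(x)
    lin_inv = np.linalg.inv(grid.direction_matrix @ np.diag(grid.spacing))
    shift_vox = lin_inv @ np.asarray(spec.translation_mm, dtype=float)
    coords = np.indices(shape, dtype=float)
    src = coords - shift_vox[:, None, None, None]
    if spec.elastic_amp_mm > 0:
        disp = rng.normal(size=(3,) + shape)
        sigma_vox = [spec.elastic_sigma_mm / s for s in grid.spacing]
        for axis in range(3):
            disp[axis] = ndimage.gaussian_filter(disp[axis], sigma=sigma_vox)
        norm = np.sqrt((disp**2).sum(axis=0))
        peak = norm.max()
        if peak > 0:
            disp *= spec.elastic_amp_mm / peak
        src = src - np.einsum("ij,j...->i...", lin_inv, disp)
    warped = (
        ndimage.map_coordinates(
            base.astype(np.uint8), src.reshape(3, -1), order=0, mode="constant", cval=0
        ).reshape(shape)
        > 0
    )
    _check_not_clipped(warped, "warped object")

    if spec.boundary_noise_prob > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        surface_fg = warped & ~ndimage.binary_erosion(warped, structure)
        surface_bg = ~warped & ndimage.binary_dilation(warped, structure)
        drop = surface_fg & (rng.random(shape) < spec.boundary_noise_prob)
        add = surface_bg & (rng.random(shape) < spec.boundary_noise_prob)
        warped = (warped & ~drop) | add
        _check_not_clipped(warped, "noisy object")
    if not warped.any():
        raise GenerationError("warped object contains no voxels")

    return PhantomPair(
        mask_mri=BinaryMask(grid=grid, data=base),
        mask_us=BinaryMask(grid=grid, data=warped),
        spec=spec,
        true_shift_mm=float(np.linalg.norm(spec.translation_mm)),
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _auto_grid(
    radius_mm: float,
    shift_mm: float,
    elastic_amp_mm: float,
    irregularity: float,
    spacing_mm: float = DEFAULT_SPACING_MM,
    max_shape: int = 128,
) -> VoxelGrid:
    """Smallest centered cube grid that holds the object with margin.

    Coarsens the spacing (in 0.05 mm steps) when the object would need more
    than ``max_shape`` voxels per axis, keeping generation time bounded for
    large tumors.
    """
    half = radius_mm * (1.0 + irregularity) + shift_mm + elastic_amp_mm + 3.0 * spacing_mm
    n = math.ceil(2.0 * half / spacing_mm)
    if n > max_shape:
        spacing_mm = math.ceil(2.0 * half / max_shape / 0.05) * 0.05
        half = radius_mm * (1.0 + irregularity) + shift_mm + elastic_amp_mm + 3.0 * spacing_mm
        n = math.ceil(2.0 * half / spacing_mm)
    n += n % 2
    return default_grid(shape=n, spacing_mm=spacing_mm)


def _radius_for_volume(volume_cm3: float) -> float:
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def sample_case(
    case_id: str,
    rng: np.random.Generator,
    *,
    volume_median_cm3: float = DEFAULT_VOLUME_MEDIAN_CM3,
    volume_sigma_log: float = DEFAULT_VOLUME_SIGMA_LOG,
    shift_mean_mm: float = DEFAULT_SHIFT_MEAN_MM,
    shift_sigma_log: float = DEFAULT_SHIFT_SIGMA_LOG,
    str_fraction: float = DEFAULT_STR_FRACTION,
    extension_fraction: float = DEFAULT_EXTENSION_FRACTION,
    shape_irregularity: float = 0.15,
    elastic_sigma_mm: float = 6.0,
    elastic_amp_mm: float = 1.0,
    boundary_noise_prob: float = 0.03,
) -> tuple[CaseRecord, PhantomPair, dict]:
    """Draw one synthetic case: phantom pair, metrics, residual volumes.

    Returns the record (metric columns computed from the actual masks, never
    sampled), the phantom pair, and a ground-truth dict.
    """
    target_volume = float(
        np.clip(volume_median_cm3 * math.exp(volume_sigma_log * rng.normal()), 0.5, 95.0)
    )
    radius = _radius_for_volume(target_volume)
    shift_median = shift_mean_mm * math.exp(-0.5 * shift_sigma_log**2)
    shift = float(
        np.clip(shift_median * math.exp(shift_sigma_log * rng.normal()), 0.25, 13.0)
    )
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = tuple(shift * direction)

    grid = _auto_grid(radius, shift, elastic_amp_mm, shape_irregularity)
    spec = PhantomSpec(
        seed=int(rng.integers(2**31)),
        grid=grid,
        base_radius_mm=radius,
        shape_irregularity=shape_irregularity,
        translation_mm=translation,
        elastic_sigma_mm=elastic_sigma_mm,
        elastic_amp_mm=elastic_amp_mm,
        boundary_noise_prob=boundary_noise_prob,
    )
    pair = make_phantom(spec)
    pm = metrics.compare(pair.mask_us, pair.mask_mri)

    is_str = bool(rng.random() < str_fraction)
    if is_str:
        residual_us = float(np.clip(2.1 * math.exp(1.0 * rng.normal()), 0.1, 18.0))
        residual_mri = float(residual_us * math.exp(0.15 * rng.normal()))
        vol_res_ius = None
    else:
        residual_us = 0.0
        residual_mri = 0.0
        vol_res_ius = (
            float(np.clip(1.0 * math.exp(0.8 * rng.normal()), 0.1, 3.5))
            if rng.random() < extension_fraction
            else None
        )
    quality = str(
        rng.choice(list(_QUALITY_PROBS), p=list(_QUALITY_PROBS.values()))
    )

    record = CaseRecord(
        case_id=case_id,
        vol_pre_mri_cm3=pm.vol_b_cm3,
        vol_pre_us_cm3=pm.vol_a_cm3,
        vol_res_ius_cm3=vol_res_ius,
        vol_post_us_cm3=residual_us,
        vol_post_mri_cm3=residual_mri,
        cog_offset_mm=pm.cog_offset_mm,
        hausdorff_mm=pm.hausdorff_mm,
        dice=pm.dice,
        us_quality=quality,
    )
    truth = {
        "case_id": case_id,
        "seed": spec.seed,
        "true_shift_mm": pair.true_shift_mm,
        "translation_mm": list(translation),
        "target_volume_cm3": target_volume,
        "base_radius_mm": radius,
        "elastic_amp_mm": elastic_amp_mm,
        "boundary_noise_prob": boundary_noise_prob,
        "grid_shape": list(grid.shape),
        "grid_spacing_mm": list(grid.spacing),
    }
    return record, pair, truth


def make_cohort(
    n_cases: int,
    seed: int,
    **case_params,
) -> list[CaseRecord]:
    """Generate a synthetic cohort of ``n_cases`` internally consistent records.

    Per case a phantom pair is generated and the metric columns are computed
    from the masks, so every record obeys the same geometry the real
    pipeline measures.  Keyword arguments are forwarded to
    :func:`sample_case`.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_cases):
        record, _, _ = sample_case(f"S{i + 1:03d}", rng, **case_params)
        records.append(record)
    return records
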