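"""Delivered-dose accumulation to planning-frame cord voxels.

Per-fraction dose grids live on the daily guidance (MVCT) frames; the
registration transform for each fraction carries every cord voxel
centre from the planning frame into that fraction's frame, where the
dose is sampled by trilinear interpolation and summed over fractions:

    D_A(v) = sum_f  D_f( S_f( T_f(x_v) ) )

with T_f the fraction's registration map and S_f any post-imaging couch
shift (a translation applied after the registration map).  Only voxels
covered by every fraction's dose grid enter the DVH; out-of-grid
samples are excluded, never zero-filled.

The headline statistic is the near-maximum dose D2% — the minimum dose
received by the hottest 2% of the organ's voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .image_io import ImageVolume, StructureSet
from .registration import TransformChain, _sample_trilinear

__all__ = [
    "DoseGrid",
    "CordVoxels",
    "DeliveredDoseMap",
    "DoseSummary",
    "DoseComparison",
    "cord_voxels",
    "accumulate_dose",
    "dvh_summary",
    "planned_vs_delivered",
    "cohort_dose_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class DoseGrid:
    """One fraction's absorbed-dose grid (Gy) on its MVCT frame."""

    volume: ImageVolume
    fraction_index: int = 0
    couch_shift: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volume.voxels)
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("dose values must be finite and non-negative")


@dataclass
class CordVoxels:
    """Planning-frame voxels inside the cord contours."""

    indices: np.ndarray  # (n, 3) int voxel indices (i, j, k)
    centres_mm: np.ndarray  # (n, 3) mm
    frame: str = "unnamed"

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class DeliveredDoseMap:
    """Accumulated dose D_A per cord voxel with per-fraction coverage."""

    voxels: CordVoxels
    dose_gy: np.ndarray  # (n,) summed over covered fractions
    coverage: np.ndarray  # (n,) int: fractions whose grids contained the voxel
    n_fractions: int

    @property
    def included(self) -> np.ndarray:
        """Voxels covered by all fractions (the common region rule)."""
        return self.coverage == self.n_fractions


@dataclass
class DoseSummary:
    """DVH summary for one organ: D2%, mean/max dose, full DVH."""

    d2_percent: float
    mean_gy: float
    max_gy: float
    n_voxels: int
    dvh_dose_gy: np.ndarray = field(repr=False, default=None)
    dvh_volume_fraction: np.ndarray = field(repr=False, default=None)


def cord_voxels(structure: StructureSet, frame: ImageVolume) -> CordVoxels:
    """Voxel centres of ``frame`` lying inside the organ's slice polygons.

    A voxel belongs to a slice's region when its (x, y) centre is inside
    or on the boundary of the slice polygon (closed-region rule), and
    the slice planes match within half a slice spacing.
    """
    dz = frame.spacing[2]
    planes = frame.z_planes
    nz, ny, nx = frame.shape
    xs = frame.origin[0] + frame.spacing[0] * np.arange(nx)
    ys = frame.origin[1] + frame.spacing[1] * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)

    idx_list, centre_list = [], []
    for z, contours in structure.slices().items():
        k = int(np.argmin(np.abs(planes - z)))
        if abs(planes[k] - z) > dz / 2 + 1e-9:
            continue
        region = unary_union([Polygon(c.points) for c in contours])
        inside = shapely.intersects_xy(region, gx.ravel(), gy.ravel()).reshape(gx.shape)
        jj, ii = np.nonzero(inside)
        if len(ii) == 0:
            warnings.warn(f"contour at z={z:.2f} mm smaller than one voxel", stacklevel=2)
            continue
        idx_list.append(np.column_stack([ii, jj, np.full(len(ii), k)]))
        centre_list.append(np.column_stack([xs[ii], ys[jj], np.full(len(ii), planes[k])]))
    if not idx_list:
        raise ValueError("no cord voxels: contours enclose no voxel centres on this grid")
    return CordVoxels(
        np.concatenate(idx_list), np.concatenate(centre_list), frame=frame.frame
    )


def accumulate_dose(
    voxels: CordVoxels,
    transforms: list[TransformChain],
    grids: list[DoseGrid],
) -> DeliveredDoseMap:
    """Sum per-fraction doses at the mapped position of every cord voxel.

    Each fraction's transform maps the voxel centre into that fraction's
    frame; any couch shift on the grid is composed after the mapping.
    Dose is sampled trilinearly; samples outside the grid mark the voxel
    uncovered for that fraction.
    """
    if len(transforms) != len(grids):
        raise ValueError(
            f"mismatched fraction counts: {len(transforms)} transforms, {len(grids)} grids"
        )
    n = len(voxels)
    dose = np.zeros(n)
    coverage = np.zeros(n, dtype=int)
    for chain, grid in zip(transforms, grids):
        mapped = chain.apply(voxels.centres_mm)
        if grid.couch_shift is not None:
            mapped = mapped + np.asarray(grid.couch_shift, dtype=float)
        vals, inside = _sample_trilinear(
            grid.volume.voxels, grid.volume.spacing, grid.volume.origin, mapped
        )
        dose[inside] += vals[inside]
        coverage += inside
    return DeliveredDoseMap(voxels, dose, coverage, n_fractions=len(grids))


def dvh_summary(
    doses: DeliveredDoseMap | np.ndarray,
    dvh_bin_gy: float = 0.1,
    interpolated: bool = False,
) -> DoseSummary:
    """DVH statistics for equal-volume voxels.

    D2% is, by default, the smallest dose among the ceil(0.02 n)
    highest-dose voxels; ``interpolated=True`` instead interpolates the
    cumulative DVH at the 2% volume level.

    Raises
    ------
    ValueError
        If no included voxel remains.
    """
    if isinstance(doses, DeliveredDoseMap):
        vals = doses.dose_gy[doses.included]
    else:
        vals = np.asarray(doses, dtype=float)
    n = len(vals)
    if n == 0:
        raise ValueError("zero included voxels")
    sorted_desc = np.sort(vals)[::-1]
    if interpolated:
        frac = (np.arange(1, n + 1)) / n  # volume fraction receiving >= dose
        d2 = float(np.interp(0.02, frac, sorted_desc))
    else:
        k = int(np.ceil(0.02 * n))
        d2 = float(sorted_desc[:k].min())
    edges = np.arange(0.0, vals.max() + 2 * dvh_bin_gy, dvh_bin_gy)
    volume_fraction = np.array([(vals >= d).mean() for d in edges])
    return DoseSummary(
        d2_percent=d2,
        mean_gy=float(vals.mean()),
        max_gy=float(vals.max()),
        n_voxels=n,
        dvh_dose_gy=edges,
        dvh_volume_fraction=volume_fraction,
    )


@dataclass
class DoseComparison:
    """Delivered-minus-planned difference in D2% for one patient."""

    planned_d2: float
    delivered_d2: float

    @property
    def delta(self) -> float:
        return self.delivered_d2 - self.planned_d2


def planned_vs_delivered(planned: DoseSummary, delivered: DoseSummary) -> DoseComparison:
    return DoseComparison(planned.d2_percent, delivered.d2_percent)


def cohort_dose_comparison(deltas) -> dict:
    """Cohort counts of higher/lower delivered D2% and mean excess/deficit."""
    deltas = np.asarray([d.delta if isinstance(d, DoseComparison) else d for d in deltas])
    higher = deltas[deltas > 0]
    lower = deltas[deltas < 0]
    return {
        "n_higher": int(len(higher)),
        "n_lower": int(len(lower)),
        "mean_excess_gy": float(higher.mean()) if len(higher) else 0.0,
        "mean_deficit_gy": float(-lower.mean()) if len(lower) else 0.0,
    }
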