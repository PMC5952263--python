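"""Synthetic neck-like planning/guidance scan pairs with known ground truth.

The phantom is a continuous analytic model of a neck: an elliptical
soft-tissue body that tapers toward superior slices, a cord-like
cylinder (radius 4 mm) inside a bony vertebral ring whose density
undulates along z (vertebral bodies and discs), smooth random tissue
texture, and a detached treatment-couch slab posterior to the body.

Both scan analogues sample this continuous model, exactly as real
scanners sample a continuous patient:

* the planning-scan (kVCT) analogue, 2.148 x 2.148 x 3.0 mm voxels, is
  block-averaged from a 2x finer rasterisation, mimicking archival
  down-sampling;
* each guidance-scan (MVCT) analogue, 0.754 x 0.754 x 6.0 mm voxels,
  samples the model *deformed* by a known transform, with Gaussian HU
  noise added to emulate the poor signal-to-noise of megavoltage
  imaging.

All spatial structure (taper, bone undulation, texture correlation) is
kept smooth at scales above the 6 mm guidance slice spacing, so the
coarse-slice sampling does not alias it.

The ground-truth transform maps planning-frame points to guidance-frame
points — the direction the registration estimates — so recovered
transforms, propagated contours and accumulated doses can all be
checked against analytic truth.  Contour truth is computed by mapping
the exact analytic contours, never by rasterising masks.  Everything is
reproducible bit-for-bit from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import Contour, ImageVolume, StructureSet
from .masking import BinaryMask
from .dose import DoseGrid
from .propagation import regroup_to_slices
from .registration import (
    AffineTransform,
    BSplineTransform,
    RigidTransform,
    TransformChain,
    Translation,
)

__all__ = [
    "DeformationSpec",
    "PhantomSpec",
    "generate_phantom",
    "generate_fraction",
    "build_truth_chain",
    "invert_chain_at",
    "phantom_hu",
    "random_body_points",
]

_CHUNK = 32768  # point-chunk size for memory-bounded B-spline evaluation


@dataclass
class DeformationSpec:
    """Ground-truth deformation: rigid part plus optional smooth warp.

    ``warp_max_mm`` > 0 switches on a random cubic-B-spline displacement
    field whose per-component coefficients are clipped to that
    amplitude, which bounds the displacement magnitude (B-spline weights
    are a convex combination).
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = None  # optional 3x3 matrix about the volume centre
    warp_max_mm: float = 0.0
    warp_spacing_mm: float = 15.0
    # neck-flexion analogue: anterior-posterior displacement varying
    # sinusoidally along z — a curvature change no rigid or affine map fits
    flex_mm: float = 0.0
    flex_period_mm: float = 90.0


@dataclass
class PhantomSpec:
    """Geometry, intensities and acquisition settings of the phantom."""

    # planning-grid analogue: archival kVCT voxel pitch
    kvct_spacing: tuple[float, float, float] = (2.148, 2.148, 3.0)
    kvct_shape: tuple[int, int, int] = (16, 80, 80)  # (nz, ny, nx)
    # guidance-grid analogue: MVCT voxel pitch; the stack spans the
    # planning volume in z so registration is not starved of overlap
    mvct_spacing: tuple[float, float, float] = (0.754, 0.754, 6.0)
    mvct_shape: tuple[int, int, int] = (10, 224, 224)

    body_semi_axes: tuple[float, float] = (75.0, 58.0)  # mm, (x, y)
    cord_centre: tuple[float, float] = (0.0, 25.0)  # mm, posterior offset
    cord_radius: float = 4.0
    canal_radius: float = 7.0
    ring_inner_radius: float = 8.0
    ring_outer_radius: float = 13.0

    hu_air: float = -1000.0
    hu_tissue: float = 40.0
    hu_canal: float = 0.0
    hu_cord: float = 45.0
    hu_bone: float = 800.0
    hu_couch: float = 300.0
    couch_y_range: tuple[float, float] = (68.0, 80.0)
    couch_x_half_width: float = 70.0

    # axial structure constraining registration along z
    body_taper: float = 0.25
    vertebra_period_mm: float = 24.0
    vertebra_contrast: float = 0.45  # fractional bone-HU modulation depth
    # smooth random tissue texture: a band-limited continuous field
    texture_sd_hu: float = 25.0
    texture_corr_mm: float = 4.0  # in-plane correlation length
    texture_corr_z_mm: float = 9.0
    texture_components: int = 160

    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    noise_sd_hu: float = 20.0
    fraction_dose_gy: float = 65.0 / 30.0
    dose_sigma_mm: float = 12.0
    contour_vertices: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation.warp_max_mm > 0.45 * self.deformation.warp_spacing_mm:
            # displacement gradient stays well below 1, keeping the warp
            # invertible on the body region
            raise ValueError("warp amplitude too large for a safely invertible phantom")

    # z extent of the planning stack; the taper and bone undulation are
    # referenced to it but the model is defined for all z
    @property
    def kvct_z_range(self) -> tuple[float, float]:
        half = self.kvct_spacing[2] * (self.kvct_shape[0] - 1) / 2
        return -half, half


# ---------------------------------------------------------------------------
# Continuous model
# ---------------------------------------------------------------------------

def _texture_field(spec: PhantomSpec):
    """Band-limited Gaussian random field as a sum of random cosines.

    Wavevectors are drawn from the (anisotropic) Gaussian spectral
    density matching the requested correlation lengths, so the field is
    smooth, stationary and evaluable at any continuous point — the
    phantom has no preferred lattice.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9001]))
    k = rng.normal(
        0.0,
        [1.0 / spec.texture_corr_mm, 1.0 / spec.texture_corr_mm, 1.0 / spec.texture_corr_z_mm],
        size=(spec.texture_components, 3),
    )
    phases = rng.uniform(0, 2 * np.pi, size=spec.texture_components)
    amp = spec.texture_sd_hu * np.sqrt(2.0 / spec.texture_components)
    return k, phases, amp


def _body_scale(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    z_lo, z_hi = spec.kvct_z_range
    frac = (np.asarray(z, dtype=float) - z_lo) / max(z_hi - z_lo, 1e-9)
    # wide clamp: the taper continues smoothly past the planning stack so
    # guidance scans see no artificial kink in the anatomy
    return np.clip(1.0 - spec.body_taper * frac, 0.3, 1.4)


def phantom_hu(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """HU of the continuous phantom model at arbitrary mm points."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    ax, by = spec.body_semi_axes
    s = _body_scale(spec, z)
    body = (x / (s * ax)) ** 2 + (y / (s * by)) ** 2 <= 1.0
    r2 = (x - spec.cord_centre[0]) ** 2 + (y - spec.cord_centre[1]) ** 2
    hu = np.full(len(pts), spec.hu_air)
    hu[body] = spec.hu_tissue
    ring = body & (r2 >= spec.ring_inner_radius**2) & (r2 <= spec.ring_outer_radius**2)
    z_lo = spec.kvct_z_range[0]
    mod = 1.0 - spec.vertebra_contrast * 0.5 * (
        1.0 + np.sin(2 * np.pi * (z - z_lo) / spec.vertebra_period_mm)
    )
    hu[ring] = spec.hu_bone * mod[ring]
    hu[body & (r2 <= spec.canal_radius**2)] = spec.hu_canal
    hu[body & (r2 <= spec.cord_radius**2)] = spec.hu_cord
    couch = (
        (y >= spec.couch_y_range[0])
        & (y <= spec.couch_y_range[1])
        & (np.abs(x) <= spec.couch_x_half_width)
        & ~body
    )
    hu[couch] = spec.hu_couch
    if spec.texture_sd_hu > 0 and body.any():
        k, phases, amp = _texture_field(spec)
        bp = pts[body].astype(np.float32)
        k32 = k.T.astype(np.float32)
        ph32 = phases.astype(np.float32)
        tex = np.empty(len(bp), dtype=np.float32)
        for s in range(0, len(bp), 1 << 18):  # chunked: bounded memory, f32 cos
            tex[s : s + (1 << 18)] = np.cos(bp[s : s + (1 << 18)] @ k32 + ph32).sum(axis=1)
        hu[body] += amp * tex.astype(float)
    return hu


def _grid_centres(shape, spacing, origin):
    nz, ny, nx = shape
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)
    return xs, ys, zs


def _centred_origin(shape, spacing):
    nz, ny, nx = shape
    return (
        -spacing[0] * (nx - 1) / 2,
        -spacing[1] * (ny - 1) / 2,
        -spacing[2] * (nz - 1) / 2,
    )


def _grid_points(shape, spacing, origin) -> np.ndarray:
    xs, ys, zs = _grid_centres(shape, spacing, origin)
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


# ---------------------------------------------------------------------------
# Planning scan
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet, BinaryMask]:
    """Build the planning volume, exact cord contours and true body mask.

    The volume is rasterised on a lattice twice as fine in each axis and
    block-averaged down, emulating archival down-sampling.  Cord
    contours are exact circles (64 vertices) on every slice plane.
    """
    ax, by = spec.body_semi_axes
    cx, cy = spec.cord_centre
    s_min = float(_body_scale(spec, spec.kvct_z_range[1]))
    if (cx / (s_min * ax)) ** 2 + (cy / (s_min * by)) ** 2 > (
        1 - spec.cord_radius / (s_min * min(ax, by))
    ) ** 2:
        raise ValueError("cord outside body ellipse")

    shape = spec.kvct_shape
    spacing = spec.kvct_spacing
    origin = _centred_origin(shape, spacing)
    fine_shape = tuple(2 * n for n in shape)
    fine_spacing = tuple(s / 2 for s in spacing)
    # fine lattice placed so each 2x2x2 fine block centres on a coarse voxel
    fine_origin = tuple(o - fs / 2 for o, fs in zip(origin, fine_spacing))
    fine = phantom_hu(spec, _grid_points(fine_shape, fine_spacing, fine_origin)).reshape(
        fine_shape
    )
    nz, ny, nx = shape
    coarse = fine.reshape(nz, 2, ny, 2, nx, 2).mean(axis=(1, 3, 5))
    kvct = ImageVolume(coarse, spacing, origin, frame="phantom-kvct")

    cord = StructureSet("spinal_cord", _phantom_contours(spec, kvct), frame=kvct.frame)

    xs, ys, zs = _grid_centres(shape, spacing, origin)
    gx, gy = np.meshgrid(xs, ys)
    body = np.stack(
        [
            (gx / (s * ax)) ** 2 + (gy / (s * by)) ** 2 <= 1.0
            for s in _body_scale(spec, zs)
        ]
    )
    mask_truth = BinaryMask(body, spacing, origin, frame=kvct.frame)
    return kvct, cord, mask_truth


def _phantom_contours(spec: PhantomSpec, kvct: ImageVolume) -> list[Contour]:
    theta = np.linspace(0, 2 * np.pi, spec.contour_vertices, endpoint=False)
    cx, cy = spec.cord_centre
    circle = np.column_stack(
        [cx + spec.cord_radius * np.cos(theta), cy + spec.cord_radius * np.sin(theta)]
    )
    return [Contour(float(z), circle.copy()) for z in kvct.z_planes]


# ---------------------------------------------------------------------------
# Ground-truth deformation
# ---------------------------------------------------------------------------

def build_truth_chain(
    spec: PhantomSpec,
    kvct: ImageVolume,
    rng: np.random.Generator | None = None,
) -> TransformChain:
    """Assemble the analytic fixed-to-moving ground-truth transform."""
    d = spec.deformation
    lo, hi = kvct.extent_mm()
    centre = 0.5 * (np.asarray(lo) + np.asarray(hi))
    transforms = []
    if d.affine is not None:
        transforms.append(
            AffineTransform(
                np.concatenate([np.asarray(d.affine, dtype=float).ravel(), d.translation]),
                centre=centre,
            )
        )
    elif any(abs(a) > 0 for a in d.rotation_deg):
        angles = np.deg2rad(d.rotation_deg)
        transforms.append(
            RigidTransform(np.concatenate([angles, d.translation]), centre=centre)
        )
    elif any(abs(t) > 0 for t in d.translation):
        transforms.append(Translation(d.translation))
    if d.warp_max_mm > 0 or d.flex_mm > 0:
        bs = BSplineTransform.covering(lo, hi, d.warp_spacing_mm)
        coeffs = np.zeros(bs.grid_shape + (3,))
        if d.warp_max_mm > 0:
            if rng is None:
                rng = np.random.default_rng(spec.seed)
            coeffs += np.clip(
                rng.normal(0.0, d.warp_max_mm / 2.5, size=bs.grid_shape + (3,)),
                -d.warp_max_mm,
                d.warp_max_mm,
            )
        if d.flex_mm > 0:
            z_cp = bs.grid_origin[2] + bs.grid_spacing[2] * np.arange(bs.grid_shape[2])
            bend = d.flex_mm * np.sin(2 * np.pi * (z_cp - lo[2]) / d.flex_period_mm)
            coeffs[..., 1] += bend[None, None, :]
        bs.coefficients = coeffs
        transforms.append(bs)
    return TransformChain(transforms, fixed_frame=kvct.frame, moving_frame="phantom-mvct")


def invert_chain_at(
    chain: TransformChain, pts: np.ndarray, max_iter: int = 30, tol: float = 1e-6
) -> np.ndarray:
    """Numerically invert a near-identity chain at the given points.

    Fixed-point iteration x <- x + (y - T(x)); converges rapidly for the
    small, smooth deformations the phantom uses.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = np.empty_like(pts)
    for s in range(0, len(pts), _CHUNK):
        y = pts[s : s + _CHUNK]
        x = y.copy()
        for _ in range(max_iter):
            residual = y - chain.apply(x)
            x = x + residual
            if np.max(np.abs(residual)) < tol:
                break
        out[s : s + _CHUNK] = x
    return out


# ---------------------------------------------------------------------------
# Guidance fractions
# ---------------------------------------------------------------------------

def generate_fraction(
    kvct: ImageVolume,
    spec: PhantomSpec,
    fraction_index: int,
) -> tuple[ImageVolume, TransformChain, StructureSet, DoseGrid]:
    """One daily guidance scan with its ground-truth transform, contours, dose.

    The guidance voxel at mm position y images the continuous phantom at
    the pre-deformation position T^-1(y), so the scan shows the anatomy
    moved by the ground-truth map.  The random warp (when enabled) and
    the HU noise are drawn from a stream seeded by (spec.seed,
    fraction_index): fractions are distinct yet individually
    reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, fraction_index]))
    truth = build_truth_chain(spec, kvct, rng=rng)

    shape = spec.mvct_shape
    spacing = spec.mvct_spacing
    origin = _centred_origin(shape, spacing)
    targets = _grid_points(shape, spacing, origin)
    sources = invert_chain_at(truth, targets)  # planning-frame position per voxel
    vals = phantom_hu(spec, sources)
    if spec.noise_sd_hu > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd_hu, size=vals.shape)
    mvct = ImageVolume(
        vals.reshape(shape), spacing, origin, frame=f"phantom-mvct-{fraction_index}"
    )
    truth.moving_frame = mvct.frame

    # exact contour truth: analytic vertices through the analytic map
    mapped = [
        truth.apply(np.column_stack([c.points, np.full(len(c.points), c.z)]))
        for c in _phantom_contours(spec, kvct)
    ]
    all_pts = np.vstack(mapped)
    lo, hi = mvct.extent_mm()
    if (all_pts[:, :2].min(axis=0) < np.asarray(lo[:2])).any() or (
        all_pts[:, :2].max(axis=0) > np.asarray(hi[:2])
    ).any():
        raise ValueError("deformation pushes the cord outside the guidance grid")
    truth_contours = StructureSet(
        "spinal_cord", regroup_to_slices(mapped, mvct), frame=mvct.frame
    )

    # fraction dose: Gaussian falloff about the deformed cord axis, i.e.
    # constant in the anatomy-following frame recovered by the inverse map
    r2 = (sources[:, 0] - spec.cord_centre[0]) ** 2 + (sources[:, 1] - spec.cord_centre[1]) ** 2
    dose_vals = spec.fraction_dose_gy * np.exp(-r2 / (2 * spec.dose_sigma_mm**2))
    dose = DoseGrid(
        ImageVolume(dose_vals.reshape(shape), spacing, origin, frame=mvct.frame),
        fraction_index=fraction_index,
    )
    return mvct, truth, truth_contours, dose


def random_body_points(
    spec: PhantomSpec, kvct: ImageVolume, n: int, seed: int = 0
) -> np.ndarray:
    """Uniform random mm points strictly inside the body ellipse (landmarks)."""
    rng = np.random.default_rng(seed)
    ax, by = spec.body_semi_axes
    lo, hi = kvct.extent_mm()
    s_min = float(_body_scale(spec, hi[2]))
    pts = []
    while len(pts) < n:
        cand = rng.uniform(
            [-0.9 * s_min * ax, -0.9 * s_min * by, lo[2]],
            [0.9 * s_min * ax, 0.9 * s_min * by, hi[2]],
            size=(4 * n, 3),
        )
        keep = (cand[:, 0] / (s_min * ax)) ** 2 + (cand[:, 1] / (s_min * by)) ** 2 <= 0.81
        pts.extend(cand[keep].tolist())
    return np.asarray(pts[:n])
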