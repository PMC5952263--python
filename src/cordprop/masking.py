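"""Patient body mask used to exclude the treatment couch from registration.

The mask is the largest 26-connected component of above-threshold voxels
in the planning scan: patient tissue is far above air (~-1000 HU), and
the couch — also above threshold — forms a separate, smaller component,
so it drops out of the registration sampling region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImageVolume

__all__ = ["BinaryMask", "build_body_mask", "DEFAULT_THRESHOLD_HU"]

logger = logging.getLogger(__name__)

#: Default HU threshold separating patient/couch from air.  Air sits near
#: -1000 HU and soft tissue above about -200 HU, so -400 HU splits them
#: robustly even with heavy image noise.
DEFAULT_THRESHOLD_HU = -400.0

# 26-neighbour connectivity: tolerant of thin, noisy necks.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Boolean voxel mask on the same grid as its parent volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    frame: str = "unnamed"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def indices_mm(self) -> np.ndarray:
        """Patient-mm centres of all true voxels, shape (n, 3), (x,y,z)."""
        kk, jj, ii = np.nonzero(self.voxels)
        idx = np.column_stack([ii, jj, kk]).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def build_body_mask(
    volume: ImageVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    closing: bool = False,
) -> BinaryMask:
    """Build the body mask as the largest above-threshold component.

    Parameters
    ----------
    volume : ImageVolume
        CT volume in HU.
    threshold_hu : float
        Voxels with HU >= threshold are candidates; the largest
        26-connected 3D component among them is kept.
    closing : bool
        Optionally apply one binary-closing pass to fill small holes.
        Off by default.

    Raises
    ------
    ValueError
        If no voxel is above threshold ("empty mask").
    """
    above = volume.voxels >= threshold_hu
    if not above.any():
        raise ValueError(f"empty mask: no voxels >= {threshold_hu} HU")

    labels, n_comp = ndimage.label(above, structure=_STRUCT_26)
    if n_comp == 1:
        keep = 1
    else:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n_comp + 1))
        best = sizes.max()
        winners = np.nonzero(sizes == best)[0] + 1
        if len(winners) > 1:
            # Deterministic tie-break: component containing the lowest
            # (k, j, i) voxel index in raster order.
            firsts = {
                lab: np.argmax(labels.ravel() == lab) for lab in winners
            }
            keep = min(firsts, key=lambda lab: firsts[lab])
            logger.warning(
                "body-mask tie between %d equal-size components; kept the one "
                "with the lowest voxel index", len(winners)
            )
        else:
            keep = int(winners[0])
    mask = labels == keep
    if closing:
        mask = ndimage.binary_closing(mask, structure=_STRUCT_26)
    return BinaryMask(mask, volume.spacing, volume.origin, frame=volume.frame)
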