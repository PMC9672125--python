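"""Binary mathematical morphology with a spherical structuring element.

Erosion of a binary image I by element B keeps the voxels z whose
translated element B_z fits entirely inside the foreground; dilation
marks the voxels whose (symmetric) element touches the foreground.  The
erosion-then-dilation composition (morphological opening, "E&D") deletes
foreground components too small to contain a translate of B — the
diminutive false-positive speckles a segmentation model leaves behind —
while larger structures survive essentially intact.

The element is the discrete Euclidean ball: all integer offsets with
||z||_2 <= radius.  At the default radius 2 it contains 33 voxels.
Voxels outside the grid count as background, so objects touching the
border erode there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io_preprocess import BinaryMask


def ball_offsets(radius: int) -> np.ndarray:
    """Integer offsets z with squared Euclidean norm <= radius**2."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = gx**2 + gy**2 + gz**2 <= r * r
    return np.stack([gx[keep], gy[keep], gz[keep]], axis=1)


@dataclass
class StructuringElement:
    """Discrete Euclidean ball of the given radius (voxels)."""

    radius: int = 2
    footprint: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ParameterError(f"radius must be >= 0, got {self.radius}")
        r = int(self.radius)
        ax = np.arange(-r, r + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        self.footprint = (gx**2 + gy**2 + gz**2 <= r * r)

    @property
    def size(self) -> int:
        """Number of voxels in the element (33 at radius 2)."""
        return int(self.footprint.sum())


def erode(mask: BinaryMask, element: StructuringElement | None = None) -> BinaryMask:
    """Binary erosion; out-of-grid voxels are background."""
    element = element or StructuringElement()
    out = ndimage.binary_erosion(
        mask.data, structure=element.footprint, border_value=0
    )
    return BinaryMask(data=out, spacing=mask.spacing)


def dilate(mask: BinaryMask, element: StructuringElement | None = None) -> BinaryMask:
    """Binary dilation (union of balls around foreground), clipped to the grid."""
    element = element or StructuringElement()
    out = ndimage.binary_dilation(
        mask.data, structure=element.footprint, border_value=0
    )
    return BinaryMask(data=out, spacing=mask.spacing)


def open_ed(mask: BinaryMask, element: StructuringElement | None = None) -> BinaryMask:
    """Erosion followed by dilation (3D morphological opening)."""
    element = element or StructuringElement()
    return dilate(erode(mask, element), element)
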