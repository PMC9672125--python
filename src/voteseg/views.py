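"""Multi-view decomposition of volumes and lossless reassembly.

A 3D volume feeds the segmentation networks in five representations:
axial / coronal / sagittal 2D slice stacks, 2.5D three-channel axial
slabs (slices i-1, i, i+1 as channels), and non-overlapping 3D patches
(64 x 64 x 128 by default).  Every decomposition here is invertible so
that per-representation predictions can be voted in a common volume frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, ParameterError
from .io_preprocess import BinaryMask, Volume

VIEWS = ("axial", "coronal", "sagittal")
#: array axis along which each view's slices are taken (x, y, z convention)
VIEW_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

DEFAULT_PATCH_SHAPE = (64, 64, 128)


def _wrap_like(source: Volume | BinaryMask, data: np.ndarray) -> Volume | BinaryMask:
    if isinstance(source, BinaryMask):
        return BinaryMask(data=data.astype(bool), spacing=source.spacing)
    return Volume(data=data, spacing=source.spacing)


@dataclass
class ViewStack:
    """Ordered 2D frames along one anatomical view, with provenance."""

    view: str
    frames: list[np.ndarray]
    index_map: list[int]  # frame position -> plane coordinate in the source
    source_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    is_mask: bool = False

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SlabStack:
    """2.5D axial slabs: frame i holds axial slices (i-1, i, i+1) as channels."""

    frames: list[np.ndarray]  # each (3, nx, ny)
    index_map: list[int]
    source_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PatchGrid:
    """Disjoint, exhaustive 3D tiling of a zero-padded volume."""

    patch_shape: tuple[int, int, int]
    patches: list[np.ndarray]
    offsets: list[tuple[int, int, int]]  # corner coordinates in padded space
    pad: tuple[int, int, int]  # trailing zero-pad per axis
    source_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    is_mask: bool = False

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(s + p for s, p in zip(self.source_shape, self.pad))  # type: ignore[return-value]


def extract_slices(x: Volume | BinaryMask, view: str) -> ViewStack:
    """Cut a volume into the ordered 2D planes of one view."""
    if view not in VIEW_AXIS:
        raise ParameterError(f"unknown view {view!r}; expected one of {VIEWS}")
    axis = VIEW_AXIS[view]
    n = x.shape[axis]
    frames = [np.take(x.data, k, axis=axis).copy() for k in range(n)]
    return ViewStack(
        view=view,
        frames=frames,
        index_map=list(range(n)),
        source_shape=x.shape,
        spacing=x.spacing,
        is_mask=isinstance(x, BinaryMask),
    )


def stack_to_volume(stack: ViewStack) -> Volume | BinaryMask:
    """Inverse of :func:`extract_slices`; frames are placed by ``index_map``."""
    axis = VIEW_AXIS.get(stack.view)
    if axis is None:
        raise ParameterError(f"unknown view {stack.view!r}")
    shape = stack.source_shape
    n = shape[axis]
    plane_shape = tuple(s for i, s in enumerate(shape) if i != axis)
    if len(stack.frames) != n or sorted(stack.index_map) != list(range(n)):
        raise ConsistencyError(
            f"need exactly one frame per plane: {n} planes, "
            f"{len(stack.frames)} frames"
        )
    out = np.empty(shape, dtype=stack.frames[0].dtype)
    for frame, k in zip(stack.frames, stack.index_map):
        if frame.shape != plane_shape:
            raise ConsistencyError(
                f"frame for plane {k} has shape {frame.shape}, expected {plane_shape}"
            )
        idx = [slice(None)] * 3
        idx[axis] = k
        out[tuple(idx)] = frame
    template = BinaryMask(np.zeros((1, 1, 1), bool), stack.spacing) if stack.is_mask \
        else Volume(np.zeros((1, 1, 1)), stack.spacing)
    return _wrap_like(template, out)


def make_slabs(vol: Volume) -> SlabStack:
    """Build 2.5D three-channel axial slabs.

    Edge frames replicate their nearest existing neighbour: frame 0's
    channel 0 is slice 0 itself, and likewise at the top of the stack.
    """
    nz = vol.shape[2]
    frames = []
    for i in range(nz):
        lo, hi = max(i - 1, 0), min(i + 1, nz - 1)
        frames.append(
            np.stack(
                [vol.data[:, :, lo], vol.data[:, :, i], vol.data[:, :, hi]], axis=0
            )
        )
    return SlabStack(
        frames=frames,
        index_map=list(range(nz)),
        source_shape=vol.shape,
        spacing=vol.spacing,
    )


def tile_patches(
    x: Volume | BinaryMask,
    patch_shape: tuple[int, int, int] = DEFAULT_PATCH_SHAPE,
) -> PatchGrid:
    """Zero-pad trailing edges to patch multiples, then cut disjoint blocks.

    Blocks are enumerated in raster order with z fastest; the order is
    irrelevant to reassembly (offsets carry position) but fixed for
    reproducibility.
    """
    if any(p <= 0 for p in patch_shape):
        raise ParameterError(f"patch dimensions must be positive, got {patch_shape}")
    shape = x.shape
    pad = tuple((-s) % p for s, p in zip(shape, patch_shape))
    padded = np.pad(x.data, [(0, p) for p in pad], mode="constant")
    patches, offsets = [], []
    px, py, pz = patch_shape
    for ox in range(0, padded.shape[0], px):
        for oy in range(0, padded.shape[1], py):
            for oz in range(0, padded.shape[2], pz):
                patches.append(padded[ox:ox + px, oy:oy + py, oz:oz + pz].copy())
                offsets.append((ox, oy, oz))
    return PatchGrid(
        patch_shape=tuple(patch_shape),  # type: ignore[arg-type]
        patches=patches,
        offsets=offsets,
        pad=pad,  # type: ignore[arg-type]
        source_shape=shape,
        spacing=x.spacing,
        is_mask=isinstance(x, BinaryMask),
    )


def assemble_patches(grid: PatchGrid) -> Volume | BinaryMask:
    """Inverse of :func:`tile_patches`: place blocks by offset, crop the pad."""
    padded_shape = grid.padded_shape
    expected = set()
    px, py, pz = grid.patch_shape
    for ox in range(0, padded_shape[0], px):
        for oy in range(0, padded_shape[1], py):
            for oz in range(0, padded_shape[2], pz):
                expected.add((ox, oy, oz))
    got = [tuple(o) for o in grid.offsets]
    if len(got) != len(set(got)) or set(got) != expected:
        raise ConsistencyError(
            "patch offsets must tile the padded volume exactly once "
            f"(expected {len(expected)} distinct offsets, got {len(got)})"
        )
    if len(grid.patches) != len(got):
        raise ConsistencyError("one patch required per offset")
    out = np.empty(padded_shape, dtype=np.asarray(grid.patches[0]).dtype)
    for patch, (ox, oy, oz) in zip(grid.patches, got):
        patch = np.asarray(patch)
        if patch.shape != grid.patch_shape:
            raise ConsistencyError(
                f"patch at {(ox, oy, oz)} has shape {patch.shape}, "
                f"expected {grid.patch_shape}"
            )
        out[ox:ox + px, oy:oy + py, oz:oz + pz] = patch
    sx, sy, sz = grid.source_shape
    cropped = out[:sx, :sy, :sz]
    template = BinaryMask(np.zeros((1, 1, 1), bool), grid.spacing) if grid.is_mask \
        else Volume(np.zeros((1, 1, 1)), grid.spacing)
    return _wrap_like(template, cropped.copy())
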