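"""Volume / mask I/O and CBCT-style preprocessing.

Axis convention (fixed for the whole toolkit): array axis 0 is the patient
x (sagittal) direction, axis 1 is y (coronal), axis 2 is z (axial).  An
axial slice is therefore the fixed-z plane ``data[:, :, k]``.  Intensities
are Hounsfield units (HU).

Preprocessing mirrors a common CBCT workflow: 3D Gaussian denoising
(sigma 1 voxel by default), horizontal-flip augmentation, a metallic
dental burden (MDB) screen that flags scans dominated by metal, and a
semiautomatic threshold-contour helper used to build ground-truth tooth
masks slice by slice.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.draw import polygon2mask

from .errors import DimensionalityError, FormatError, ParameterError

DEFAULT_SPACING = (0.19, 0.19, 0.19)  # mm, isotropic CBCT voxel

#: MDB screening defaults: TH1 is a metal-density threshold, TH2 an
#: enamel-density threshold, TH3 the ratio above which a scan counts as
#: carrying a heavy metallic dental burden.
TH1_DEFAULT = 3070.0
TH2_DEFAULT = 2500.0
TH3_DEFAULT = 0.4


def _check_3d(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3D grid, got {data.ndim} dimension(s)"
        )
    if min(data.shape) < 1:
        raise DimensionalityError("every axis must have extent >= 1")


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ParameterError(f"spacing must be three positive values, got {spacing}")
    return sp  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3D scalar grid in HU with voxel spacing, axes (x, y, z)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_3d(data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.isin(uniq, (0, 1)).all():
                raise ParameterError("mask values must be restricted to {0, 1}")
        self.data = data.astype(bool)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MdbReport:
    """Result of the metallic-dental-burden screen.

    ``mdbr`` is the ratio of voxel counts above the metal threshold (th1)
    and above the enamel threshold (th2); ``heavy`` flags ``mdbr > th3``.
    """

    th1: float
    th2: float
    th3: float
    count_above_th1: int
    count_above_th2: int
    mdbr: float
    heavy: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


# ---------------------------------------------------------------------------
# I/O (SimpleITK backend: NIfTI, NRRD, DICOM series)
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "nrrd", "dicom_dir")


def _sitk_to_xyz(img: sitk.Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise DimensionalityError(f"payload is {arr.ndim}D, expected a 3D volume")
    return np.ascontiguousarray(arr.transpose(2, 1, 0)), tuple(img.GetSpacing())


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a 3D volume from NIfTI, NRRD, or a DICOM series directory.

    Intensities are taken as HU after the header's rescale slope/intercept
    (applied by the reader); no further calibration is performed.
    ``format`` may be omitted, in which case it is inferred from the path.
    """
    path = os.fspath(path)
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")
    try:
        if format == "dicom_dir":
            reader = sitk.ImageSeriesReader()
            names = reader.GetGDCMSeriesFileNames(path)
            if not names:
                raise FormatError(f"no DICOM series found in {path!r}")
            reader.SetFileNames(names)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except FormatError:
        raise
    except RuntimeError as exc:  # SimpleITK wraps ITK I/O failures
        raise FormatError(f"could not read {path!r}: {exc}") from exc
    data, spacing = _sitk_to_xyz(img)
    return Volume(data=data, spacing=spacing)


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom_dir"
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ParameterError(f"cannot infer format of {path!r}; pass format=")


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a Volume as NIfTI or NRRD (by extension)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    try:
        sitk.WriteImage(img, os.fspath(path))
    except RuntimeError as exc:
        raise FormatError(f"could not write {path!r}: {exc}") from exc


def read_mask(path: str | os.PathLike, format: str | None = None) -> BinaryMask:
    vol = read_volume(path, format)
    return BinaryMask(data=vol.data != 0, spacing=vol.spacing)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    write_volume(
        Volume(data=mask.data.astype(np.uint8), spacing=mask.spacing), path
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def gaussian_smooth(vol: Volume, sigma: float = 1.0) -> Volume:
    """3D Gaussian denoising with reflective boundaries.

    ``sigma`` is in voxels (the grid is isotropic, so voxels and mm are
    proportional); ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return Volume(data=vol.data.copy(), spacing=vol.spacing)
    smoothed = ndimage.gaussian_filter(
        vol.data.astype(float), sigma=sigma, mode="reflect"
    )
    return Volume(data=smoothed, spacing=vol.spacing)


def compute_mdbr(
    vol: Volume,
    th1: float = TH1_DEFAULT,
    th2: float = TH2_DEFAULT,
    th3: float = TH3_DEFAULT,
) -> MdbReport:
    """Screen a volume for heavy metallic dental burden.

    The screening ratio is ``count(vol > th1) / count(vol > th2)``: the
    fraction of enamel-or-denser voxels that are metal-dense.  A scan with
    no voxel above th2 has ratio 0 (nothing dense enough to judge, so it
    is conservatively not excluded).
    """
    if th1 < th2:
        raise ParameterError(f"th1 ({th1}) must be >= th2 ({th2})")
    n1 = int(np.count_nonzero(vol.data > th1))
    n2 = int(np.count_nonzero(vol.data > th2))
    mdbr = n1 / n2 if n2 > 0 else 0.0
    return MdbReport(
        th1=float(th1), th2=float(th2), th3=float(th3),
        count_above_th1=n1, count_above_th2=n2,
        mdbr=mdbr, heavy=bool(mdbr > th3),
    )


def hflip(x: Volume | BinaryMask) -> Volume | BinaryMask:
    """Mirror every axial slice left-right (reverse the x axis)."""
    flipped = x.data[::-1, :, :].copy()
    return dataclasses.replace(x, data=flipped)


def augment_flip(items: Iterable[Volume | BinaryMask]) -> list[Volume | BinaryMask]:
    """Augmentation factor 2: originals followed by their horizontal flips."""
    items = list(items)
    return items + [hflip(it) for it in items]


def semiauto_contour(
    vol: Volume,
    roi: Sequence[Sequence[float]] | Mapping[int, Sequence[Sequence[float]]],
    threshold: float,
) -> BinaryMask:
    """Semiautomatic threshold contouring of teeth inside a polygonal ROI.

    ``roi`` is a polygon as (x, y) vertices applied to every axial slice,
    or a mapping from z index to such a polygon (slices without an entry
    get an empty ROI).  The mask is ``vol >= threshold`` restricted to the
    ROI interior, then holes are filled per axial slice.
    """
    nx, ny, nz = vol.shape
    if isinstance(roi, Mapping):
        per_slice = {int(z): _roi_mask(poly, (nx, ny)) for z, poly in roi.items()}
        roi_masks = [per_slice.get(z, np.zeros((nx, ny), bool)) for z in range(nz)]
    else:
        one = _roi_mask(roi, (nx, ny))
        roi_masks = [one] * nz

    above = vol.data >= threshold
    out = np.zeros(vol.shape, dtype=bool)
    for z in range(nz):
        sl = above[:, :, z] & roi_masks[z]
        out[:, :, z] = ndimage.binary_fill_holes(sl)
    return BinaryMask(data=out, spacing=vol.spacing)


def _roi_mask(polygon: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ParameterError("ROI polygon needs at least 3 (x, y) vertices")
    if (pts < -0.5).any() or (pts[:, 0] > shape[0] - 0.5).any() or (
        pts[:, 1] > shape[1] - 0.5
    ).any():
        raise ParameterError("ROI polygon vertices must lie inside the slice extent")
    return polygon2mask(shape, pts)
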