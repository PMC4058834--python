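"""Volumes, ROI boxes and NIfTI I/O.

A :class:`Volume` is a 3-D scalar grid with voxel spacing and a modality tag
(CT intensity, PET-derived SUV, fuzzy tumor membership, or a binary mask).
Indexing is 0-based and :class:`RoiBox` is half-open on its upper corner, so
``box.shape`` is simply the elementwise difference of the two corners.

PET/CT registration is *not* performed here: the segmentation assumes the two
modalities were fused upstream and live on one common grid, and
:func:`check_same_grid` enforces that contract. Orientation/affine metadata
beyond voxel spacing is carried through untouched.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    GridMismatchError,
    MissingFileError,
    ModalityError,
    RoiBoundsError,
    ShapeMismatchError,
    UnwritablePathError,
    VolumeFormatError,
)

__all__ = [
    "Modality",
    "Volume",
    "RoiBox",
    "read_volume",
    "write_volume",
    "extract_roi",
    "embed_mask",
    "check_same_grid",
]

#: Relative tolerance used when comparing voxel spacings of two grids.
SPACING_RTOL = 1e-6


class Modality(str, enum.Enum):
    """What the scalar at each voxel means."""

    CT = "CT"
    SUV = "SUV"
    MEMBERSHIP = "MEMBERSHIP"
    MASK = "MASK"


@dataclass(frozen=True)
class Volume:
    """A single-channel 3-D image.

    Parameters
    ----------
    data:
        3-D array of scalars, converted to ``float64`` (``uint8`` for masks
        happens only at write time).
    spacing:
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    modality:
        One of :class:`Modality`. MEMBERSHIP volumes must lie in [0, 1] and
        MASK volumes must be exactly 0/1; this is validated on construction.
    affine:
        Optional 4x4 voxel-to-world matrix, passed through to disk untouched.
        When absent, a diagonal affine built from ``spacing`` is used.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.CT
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise DimensionalityError(
                f"Volume data must be 3-D, got {arr.ndim}-D with shape {arr.shape}"
            )
        object.__setattr__(self, "data", arr)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive reals, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "modality", Modality(self.modality))
        self._validate_values()

    def _validate_values(self) -> None:
        if self.modality is Modality.MEMBERSHIP:
            if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
                raise ModalityError("MEMBERSHIP volume has values outside [0, 1]")
        elif self.modality is Modality.MASK:
            if not np.isin(self.data, (0.0, 1.0)).all():
                raise ModalityError("MASK volume has values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "Volume":
        """New Volume on the same grid carrying different voxel values."""
        return replace(self, data=data, modality=modality or self.modality)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned voxel box, 0-based, half-open on the upper corner."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lower = tuple(int(v) for v in self.lower)
        upper = tuple(int(v) for v in self.upper)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if any(lo < 0 for lo in lower) or any(hi <= lo for lo, hi in zip(lower, upper)):
            raise RoiBoundsError(f"degenerate ROI box {lower}..{upper}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    def check_inside(self, parent_shape: tuple[int, int, int]) -> None:
        if any(hi > n for hi, n in zip(self.upper, parent_shape)):
            raise RoiBoundsError(
                f"ROI box {self.lower}..{self.upper} exceeds parent shape {tuple(parent_shape)}"
            )

    @classmethod
    def from_ints(cls, values: "tuple[int, ...] | list[int]") -> "RoiBox":
        """Build from six integers ``i0 j0 k0 i1 j1 k1`` (config/CLI form)."""
        vals = [int(v) for v in values]
        if len(vals) != 6:
            raise RoiBoundsError(f"expected 6 integers for an ROI box, got {len(vals)}")
        return cls(lower=tuple(vals[:3]), upper=tuple(vals[3:]))


def _infer_modality(path: Path) -> Modality:
    name = path.name.lower()
    for tag in ("membership", "mask", "truth", "suv", "ct"):
        if tag in name:
            return {"truth": Modality.MASK}.get(tag, Modality(tag.upper()))
    return Modality.CT


def read_volume(path: str | os.PathLike, modality: Modality | str | None = None) -> Volume:
    """Read a single-channel 3-D NIfTI image.

    ``modality`` may be given explicitly; otherwise it is inferred from the
    filename (``ct``, ``suv``, ``mask``/``truth``, ``membership``), defaulting
    to CT.
    """
    p = Path(path)
    if not p.exists():
        raise MissingFileError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise VolumeFormatError(f"cannot read {p} as a NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{p} is {data.ndim}-D, expected a 3-D volume")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    tag = Modality(modality) if modality is not None else _infer_modality(p)
    return Volume(data=data, spacing=spacing, modality=tag, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz); masks are stored as uint8."""
    p = Path(path)
    if p.is_dir():
        raise UnwritablePathError(f"{p} is a directory")
    if not p.parent.exists():
        raise UnwritablePathError(f"parent directory does not exist: {p.parent}")
    if volume.affine is not None:
        affine = np.asarray(volume.affine, dtype=np.float64)
    else:
        affine = np.diag(list(volume.spacing) + [1.0])
    if volume.modality is Modality.MASK:
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data  # float64, bit-exact round trip
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(p))
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {p}: {exc}") from exc


def extract_roi(volume: Volume, box: RoiBox) -> Volume:
    """Copy the sub-volume inside ``box``; spacing and modality are kept."""
    box.check_inside(volume.shape)
    return replace(volume, data=volume.data[box.slices].copy())


def embed_mask(roi_mask: Volume, box: RoiBox, parent_shape: tuple[int, int, int]) -> Volume:
    """Place an ROI-sized mask back onto the full grid, zero outside the box."""
    box.check_inside(parent_shape)
    if tuple(roi_mask.shape) != tuple(box.shape):
        raise ShapeMismatchError(
            f"mask shape {roi_mask.shape} does not match box extents {box.shape}"
        )
    full = np.zeros(tuple(parent_shape), dtype=np.float64)
    full[box.slices] = roi_mask.data
    return Volume(data=full, spacing=roi_mask.spacing, modality=roi_mask.modality)


def check_same_grid(a: Volume, b: Volume) -> None:
    """Raise :class:`GridMismatchError` unless the two volumes share a grid.

    Shapes must be identical; spacings must agree to relative tolerance
    ``SPACING_RTOL``. This is the co-registration contract: the algorithm
    never resamples.
    """
    if tuple(a.shape) != tuple(b.shape):
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    if not np.allclose(sa, sb, rtol=SPACING_RTOL, atol=0.0):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
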