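"""Geometry-aware containers and readers/writers for CT volumes, slices and masks.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` with 0-based indices;
* ``z`` runs inferior -> superior; volumes read from disk are reoriented to
  this canonical axial orientation;
* all voxel values are Hounsfield units (HU) at native precision — windowing
  and clipping happen only inside model preprocessing;
* physical positions are millimetres; ``origin`` is the physical position of
  voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BACKGROUND",
    "SM",
    "VAT",
    "SAT",
    "CLASS_NAMES",
    "FormatError",
    "GeometryError",
    "CTVolume",
    "CTSlice",
    "DiskAnnotation",
    "CompartmentMask",
    "ProbabilityMap",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "extract_slice",
]

# Compartment label codes (fixed across the whole package).
BACKGROUND, SM, VAT, SAT = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", SM: "SM", VAT: "VAT", SAT: "SAT"}


class FormatError(ValueError):
    """Unreadable, ambiguous or mixed-series input."""


class GeometryError(ValueError):
    """Inconsistent physical geometry (e.g. non-uniform slice spacing)."""


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values, ``z`` inferior -> superior.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, all strictly positive.
    origin : tuple of float
        Physical ``(z, y, x)`` position of voxel ``(0, 0, 0)`` in mm.
    patient_id : str
        Opaque case identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if self.voxels.shape[0] < 2:
            raise ValueError("a CT volume needs at least 2 slices in z")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("all spacing components must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def z_mm(self, z_index: float) -> float:
        """Physical z position (mm) of a (possibly fractional) slice index."""
        return float(self.origin[0] + z_index * self.spacing[0])

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class CTSlice:
    """A single axial slice of a :class:`CTVolume`."""

    pixels: np.ndarray
    spacing: tuple[float, float]
    z_index: int
    z_mm: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D (y, x)")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("pixel spacing must be > 0")

    def pixel_area_mm2(self) -> float:
        return float(self.spacing[0] * self.spacing[1])


@dataclass
class DiskAnnotation:
    """Manually placed center of the L3/L4 intervertebral disk.

    ``center`` is a continuous ``(z, y, x)`` voxel coordinate in the frame of
    the annotated volume.
    """

    center: tuple[float, float, float]
    frame_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.center)
        for v, n in zip(c, self.frame_shape):
            if not (0 <= v <= n - 1):
                raise ValueError(f"annotation center {c} outside volume grid {self.frame_shape}")
        self.center = c

    @classmethod
    def for_volume(cls, center, volume: CTVolume) -> "DiskAnnotation":
        return cls(center=tuple(center), frame_shape=volume.shape)

    def z_mm(self, volume: CTVolume) -> float:
        return volume.z_mm(self.center[0])


@dataclass
class CompartmentMask:
    """2D integer label map over {0: background, 1: SM, 2: VAT, 3: SAT}."""

    labels: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D (y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        bad = ~np.isin(self.labels, (BACKGROUND, SM, VAT, SAT))
        if bad.any():
            raise ValueError("mask contains label codes outside {0,1,2,3}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("pixel spacing must be > 0")

    def pixel_area_mm2(self) -> float:
        return float(self.spacing[0] * self.spacing[1])


@dataclass
class ProbabilityMap:
    """Per-class softmax stack (C classes leading axis), values in [0, 1].

    ``C = 2`` for the disk-blob task, ``C = 4`` for the tissue task; per-pixel
    class probabilities sum to 1 within 1e-5.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim < 2:
            raise ValueError("probs must be (C, *spatial)")
        if self.probs.min() < -1e-6 or self.probs.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        s = self.probs.sum(axis=0)
        if np.abs(s - 1.0).max() > 1e-4:
            raise ValueError("per-pixel class probabilities must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]


@dataclass
class BinaryVolume:
    """A 3D boolean mask aligned to a :class:`CTVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def shape(self):
        return self.mask.shape

    def volume_ml(self) -> float:
        """Foreground volume in millilitres (count x voxel volume / 1000)."""
        return float(self.mask.sum() * np.prod(self.spacing) / 1000.0)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_nifti(path: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    img = nib.as_closest_canonical(img)  # RAS+: x right, y anterior, z superior
    zooms = img.header.get_zooms()[:3]
    if any(z == 0 for z in zooms):
        raise GeometryError(f"zero voxel size in NIfTI header of {path}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # canonical nibabel axes are (x, y, z); package convention is (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    dx, dy, dz = (float(z) for z in zooms)
    ox, oy, oz = (float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=voxels, spacing=(dz, dy, dx), origin=(oz, oy, ox),
                    patient_id=os.path.basename(path).split(".")[0])


def _read_dicom_series(path: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no readable DICOM images under {path}")
    uids = {getattr(ds, "SeriesInstanceUID", "") for ds in datasets}
    if len(uids) > 1:
        raise FormatError(f"directory {path} mixes {len(uids)} DICOM series")

    def z_of(ds):
        return float(ds.ImagePositionPatient[2])

    datasets.sort(key=z_of)  # ascending z == inferior -> superior
    zs = np.array([z_of(ds) for ds in datasets])
    if len(zs) < 2:
        raise FormatError("DICOM series has fewer than 2 slices")
    dzs = np.diff(zs)
    dz = float(np.median(dzs))
    if dz <= 0:
        raise GeometryError("duplicate or non-monotone slice positions")
    if np.abs(dzs - dz).max() > 0.05 * dz:
        raise GeometryError(
            f"non-uniform slice spacing (max deviation {np.abs(dzs - dz).max():.2f} mm "
            f"from {dz:.2f} mm exceeds 5%)"
        )
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return CTVolume(voxels=voxels, spacing=(dz, dy, dx), origin=origin,
                    patient_id=str(getattr(datasets[0], "PatientID", "")))


def read_volume(path: str, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a single-series DICOM directory.

    Values are returned in HU (DICOM rescale slope/intercept applied), slices
    ordered inferior -> superior.
    """
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {format!r}")


def write_volume(volume: CTVolume, path: str) -> None:
    """Write a :class:`CTVolume` as NIfTI-1 with spacing and origin."""
    import nibabel as nib

    dz, dy, dx = volume.spacing
    oz, oy, ox = volume.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), path)


def write_mask(mask: CompartmentMask | BinaryVolume, path: str,
               format: str = "nifti") -> None:
    """Write a compartment mask or a binary volume losslessly.

    NIfTI output carries spacing; PNG stores the raw integer label codes.
    """
    if format == "nifti":
        import nibabel as nib

        if isinstance(mask, BinaryVolume):
            data = np.transpose(mask.mask.astype(np.uint8), (2, 1, 0))
            dz, dy, dx = mask.spacing
            affine = np.diag([dx, dy, dz, 1.0])
            oz, oy, ox = mask.origin
            affine[:3, 3] = (ox, oy, oz)
        elif isinstance(mask, CompartmentMask):
            data = mask.labels.astype(np.int16).T  # (x, y)
            dy, dx = mask.spacing
            affine = np.diag([dx, dy, 1.0, 1.0])
        else:
            raise TypeError(f"cannot write {type(mask).__name__}")
        nib.save(nib.Nifti1Image(data, affine), path)
    elif format == "png":
        import imageio.v3 as iio

        if not isinstance(mask, CompartmentMask):
            raise TypeError("PNG export is for 2D CompartmentMask only")
        iio.imwrite(path, mask.labels.astype(np.uint8))
    else:
        raise FormatError(f"unknown mask format {format!r}")


def read_mask(path: str, spacing: tuple[float, float] | None = None) -> CompartmentMask:
    """Read a 2D compartment mask written by :func:`write_mask`."""
    if path.endswith(".png"):
        import imageio.v3 as iio

        labels = iio.imread(path)
        if spacing is None:
            raise ValueError("PNG carries no spacing; pass spacing explicitly")
        return CompartmentMask(labels=labels.astype(np.int16), spacing=spacing)
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(f"expected a 2D mask, got shape {data.shape}")
    zooms = img.header.get_zooms()
    return CompartmentMask(labels=data.T.astype(np.int16),
                           spacing=(float(zooms[1]), float(zooms[0])))


def extract_slice(volume: CTVolume, z_index: int) -> CTSlice:
    """Extract the axial slice at ``z_index`` (0-based)."""
    z_index = int(z_index)
    if not (0 <= z_index < volume.n_slices):
        raise IndexError(
            f"z_index {z_index} out of range for volume with {volume.n_slices} slices"
        )
    return CTSlice(
        pixels=volume.voxels[z_index],
        spacing=(volume.spacing[1], volume.spacing[2]),
        z_index=z_index,
        z_mm=volume.z_mm(z_index),
        patient_id=volume.patient_id,
    )
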