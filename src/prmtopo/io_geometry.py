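"""Volume I/O and the geometric contract shared by the whole pipeline.

All downstream analysis assumes that the inspiratory scan has already been
deformably registered into the expiratory frame by upstream software, so the
three inputs (inspiration HU, expiration HU, lung mask) must live on one grid
with one voxel spacing.  This module reads/writes NIfTI (.nii/.nii.gz) and
MetaImage (.mha/.mhd) volumes, normalises them into simple array containers,
and enforces that contract.  It never registers or segments anything.

Arrays are stored in (x, y, z) index order with the axial (slice) axis last;
voxel indices are 0-based and spacing is in millimetres per axis.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "NONFINITE_SENTINEL_HU",
    "HUVolume",
    "LungMask",
    "PairedStudy",
    "GeometryReport",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_paired_study",
    "validate_geometry",
]

#: HU value substituted for non-finite voxels at load time.  It sits far above
#: the vessel/airway exclusion threshold (−500 HU), so such voxels are routed
#: to the Excluded class instead of poisoning the classifier.
NONFINITE_SENTINEL_HU = 32767.0

#: Relative tolerance when comparing voxel spacings between volumes.
SPACING_RTOL = 1e-3

#: Anisotropy ratio (max spacing / min spacing) above which a warning is
#: issued.  The cohorts this method targets are ~isotropic (≈0.7 mm);
#: configuration-count estimator bias grows with anisotropy.
ANISOTROPY_WARN_RATIO = 1.2

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_METAIMAGE_SUFFIXES = (".mha", ".mhd")


@dataclass(frozen=True)
class HUVolume:
    """A 3D scalar CT volume in Hounsfield Units.

    Parameters
    ----------
    values
        3D array of HU values, axes (x, y, z), axial axis last.
    spacing
        Per-axis voxel size in mm, strictly positive.
    phase
        Respiratory phase, ``"inspiration"`` or ``"expiration"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    phase: str = "unknown"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"HU volume must be 3D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def sanitized(self) -> "HUVolume":
        """Replace non-finite voxels with :data:`NONFINITE_SENTINEL_HU`."""
        if np.isfinite(self.values).all():
            return self
        values = np.where(np.isfinite(self.values), self.values, NONFINITE_SENTINEL_HU)
        return replace(self, values=values)


@dataclass(frozen=True)
class LungMask:
    """Binary lung segmentation on the same grid as its HU volumes."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"lung mask must be 3D, got shape {values.shape}")
        object.__setattr__(self, "values", values.astype(bool))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class PairedStudy:
    """Co-registered inspiration/expiration HU volumes plus lung mask.

    The inspiration volume is declared pre-registered into the expiration
    frame; all three members must share one grid shape and spacing.
    """

    inspiration: HUVolume
    expiration: HUVolume
    mask: LungMask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.expiration.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.expiration.spacing


@dataclass
class GeometryReport:
    """Result of :func:`validate_geometry`."""

    passed: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    anisotropy_ratio: float = 1.0

    def raise_on_error(self) -> None:
        if not self.passed:
            raise ValueError("geometry validation failed: " + "; ".join(self.errors))


def _format_of(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_METAIMAGE_SUFFIXES):
        return "metaimage"
    raise ValueError(
        f"unsupported volume format for {path!r}; expected one of "
        f"{_NIFTI_SUFFIXES + _METAIMAGE_SUFFIXES}"
    )


def _read_array(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if len(zooms) < 3 or any(not math.isfinite(z) or z <= 0 for z in zooms):
            raise ValueError(f"missing or invalid spacing metadata in {path}")
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms)
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()  # (x, y, z)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"missing or invalid spacing metadata in {path}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    return np.transpose(arr, (2, 1, 0)).astype(np.float64), tuple(float(s) for s in spacing)


def _write_array(values: np.ndarray, spacing: tuple[float, float, float],
                 path: str | os.PathLike, dtype: np.dtype) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _format_of(path)
    data = np.asarray(values, dtype=dtype)
    if fmt == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(spacing)
        nib.save(img, str(path))
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def load_volume(path: str | os.PathLike, phase: str = "unknown") -> HUVolume:
    """Load an HU volume, sanitizing non-finite voxels to the Excluded sentinel."""
    values, spacing = _read_array(path)
    return HUVolume(values, spacing, phase=phase).sanitized()


def save_volume(volume: HUVolume, path: str | os.PathLike) -> None:
    """Write an HU volume as float64 (lossless for integer and float HU)."""
    _write_array(volume.values, volume.spacing, path, np.dtype(np.float64))


def load_mask(path: str | os.PathLike) -> LungMask:
    """Load a 0/1 lung mask; any non-zero voxel counts as lung."""
    values, spacing = _read_array(path)
    return LungMask(values != 0, spacing)


def save_mask(mask: LungMask, path: str | os.PathLike) -> None:
    _write_array(mask.values.astype(np.uint8), mask.spacing, path, np.dtype(np.uint8))


def load_paired_study(
    insp_path: str | os.PathLike,
    exp_path: str | os.PathLike,
    mask_path: str | os.PathLike,
) -> PairedStudy:
    """Load and validate a registered inspiration/expiration/mask triplet.

    Raises
    ------
    FileNotFoundError
        If any input file is missing.
    ValueError
        On unsupported format, missing spacing metadata, geometry mismatch
        (which signals unregistered input) or an empty lung mask.
    """
    insp = load_volume(insp_path, phase="inspiration")
    exp = load_volume(exp_path, phase="expiration")
    mask = load_mask(mask_path)
    if mask.n_voxels == 0:
        raise ValueError("empty lung mask")
    study = PairedStudy(inspiration=insp, expiration=exp, mask=mask)
    validate_geometry(study).raise_on_error()
    return study


def validate_geometry(study: PairedStudy) -> GeometryReport:
    """Check that all three members share one grid and spacing.

    Shapes must match exactly; spacings must agree within relative tolerance
    ``1e-3``.  Per-axis anisotropy (max/min spacing ratio) above
    :data:`ANISOTROPY_WARN_RATIO` produces a warning, not an error.
    """
    report = GeometryReport(passed=True)
    shapes = {
        "inspiration": study.inspiration.shape,
        "expiration": study.expiration.shape,
        "mask": study.mask.shape,
    }
    ref_shape = shapes["expiration"]
    for name, shape in shapes.items():
        if shape != ref_shape:
            report.errors.append(
                f"shape mismatch ({name} {shape} vs expiration {ref_shape}); "
                "inputs may not be registered"
            )
    spacings = {
        "inspiration": study.inspiration.spacing,
        "expiration": study.expiration.spacing,
        "mask": study.mask.spacing,
    }
    ref_spacing = np.asarray(spacings["expiration"])
    for name, spacing in spacings.items():
        if not np.allclose(spacing, ref_spacing, rtol=SPACING_RTOL, atol=0.0):
            report.errors.append(
                f"spacing mismatch ({name} {spacing} vs expiration {tuple(ref_spacing)})"
            )
    ratio = float(ref_spacing.max() / ref_spacing.min())
    report.anisotropy_ratio = ratio
    if ratio > ANISOTROPY_WARN_RATIO:
        report.warnings.append(
            f"anisotropic spacing {tuple(ref_spacing)} (ratio {ratio:.2f}); "
            "surface/breadth estimates are biased for strongly anisotropic grids"
        )
    report.passed = not report.errors
    return report
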