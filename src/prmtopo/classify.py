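"""PRM preprocessing and voxel classification.

Parametric Response Mapping (PRM) jointly thresholds spatially aligned
inspiration/expiration CT.  Both volumes are first smoothed with a 3×3 2D
median filter on each axial slice to suppress CT noise (typical magnitude
~100 HU), then every in-mask voxel is classified:

======================  ======================  ==============
inspiration HU          expiration HU           class
======================  ======================  ==============
> −950                  > −856                  Normal
> −950                  ≤ −856                  fSAD (air trapping)
≤ −950                  ≤ −856                  Emphysema
≤ −950                  > −856                  Unclassified
> −500 on either scan                           Excluded (vessels/airways)
======================  ======================  ==============

The fourth quadrant carries no named class; it is kept as ``Unclassified``
and excluded from all binary class maps so that the relative volumes of the
three named classes stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .io_geometry import HUVolume, PairedStudy

__all__ = [
    "PRMClass",
    "PRMThresholds",
    "PRMMap",
    "ClassFractions",
    "BinaryClassMap",
    "median_filter_axial",
    "classify_prm",
    "relative_volumes",
    "extract_class_map",
]


class PRMClass(IntEnum):
    """Integer labels of the PRM map (values used in saved label volumes)."""

    OUTSIDE_LUNG = 0
    NORMAL = 1
    FSAD = 2
    EMPH = 3
    UNCLASSIFIED = 4
    EXCLUDED = 5


#: Classes that form binary maps for topological analysis.
BINARY_CLASSES = (PRMClass.NORMAL, PRMClass.FSAD, PRMClass.EMPH)

#: Classes counted inside the lung mask.
IN_MASK_CLASSES = (
    PRMClass.NORMAL,
    PRMClass.FSAD,
    PRMClass.EMPH,
    PRMClass.UNCLASSIFIED,
    PRMClass.EXCLUDED,
)

_CLASS_ALIASES = {
    "normal": PRMClass.NORMAL,
    "norm": PRMClass.NORMAL,
    "fsad": PRMClass.FSAD,
    "emph": PRMClass.EMPH,
    "emphysema": PRMClass.EMPH,
}


def resolve_class(class_id: "PRMClass | int | str") -> PRMClass:
    """Map a class name or integer onto a :class:`PRMClass` member."""
    if isinstance(class_id, PRMClass):
        return class_id
    if isinstance(class_id, str):
        try:
            return _CLASS_ALIASES[class_id.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown PRM class {class_id!r}") from None
    try:
        return PRMClass(int(class_id))
    except ValueError:
        raise ValueError(f"unknown PRM class {class_id!r}") from None


@dataclass(frozen=True)
class PRMThresholds:
    """HU cut points of the PRM classifier.

    ``insp_cut`` (−950 HU) separates emphysematous from normal inspiratory
    density, ``exp_cut`` (−856 HU) detects expiratory air trapping, and
    ``vessel_cut`` (−500 HU) excludes vessels/airways: any voxel above it on
    either scan is omitted from classification.
    """

    insp_cut: float = -950.0
    exp_cut: float = -856.0
    vessel_cut: float = -500.0

    def __post_init__(self) -> None:
        if not (self.vessel_cut > self.exp_cut > self.insp_cut):
            raise ValueError(
                "thresholds must satisfy vessel_cut > exp_cut > insp_cut, got "
                f"{self.vessel_cut} / {self.exp_cut} / {self.insp_cut}"
            )


@dataclass(frozen=True)
class PRMMap:
    """Per-voxel PRM label grid with its provenance."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"PRM label grid must be 3D, got shape {labels.shape}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def in_mask(self) -> np.ndarray:
        return self.labels != PRMClass.OUTSIDE_LUNG

    def count(self, label: PRMClass) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass(frozen=True)
class BinaryClassMap:
    """One PRM class as a binary grid; the input of all topology estimators."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"binary class map must be 3D, got shape {values.shape}")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class ClassFractions:
    """Relative class volumes (%PRM per class) under a stated denominator.

    ``denominator="in_mask"`` divides by all lung voxels (including Excluded
    and Unclassified), so the five in-mask fractions sum to 100%.
    ``denominator="classified_only"`` divides by Normal+fSAD+Emph counts.
    """

    percentages: dict[PRMClass, float]
    denominator: str
    n_denominator: int
    n_mask: int

    def __getitem__(self, class_id: "PRMClass | int | str") -> float:
        return self.percentages[resolve_class(class_id)]


def median_filter_axial(volume: HUVolume, axial_axis: int = 2) -> HUVolume:
    """Apply a 3×3 2D median filter to each axial slice.

    The filter footprint never spans the axial axis, so slices are smoothed
    independently.  Slice borders use edge replication.
    """
    if axial_axis not in (0, 1, 2):
        raise ValueError(f"axial_axis must be 0, 1 or 2, got {axial_axis}")
    if volume.shape[axial_axis] < 1:
        raise ValueError("axial axis has zero length")
    size = [3, 3, 3]
    size[axial_axis] = 1
    filtered = ndimage.median_filter(volume.values, size=tuple(size), mode="nearest")
    return HUVolume(filtered, volume.spacing, phase=volume.phase)


def classify_prm(study: PairedStudy, thresholds: PRMThresholds | None = None) -> PRMMap:
    """Classify every in-mask voxel of a registered study.

    The study is expected to be median-filtered already (see
    :func:`median_filter_axial`); this function only thresholds.  Non-finite
    HU values (or the load-time sentinel) land in the Excluded class.
    """
    from .io_geometry import validate_geometry

    thresholds = thresholds or PRMThresholds()
    validate_geometry(study).raise_on_error()

    insp = study.inspiration.values
    exp = study.expiration.values
    mask = study.mask.values

    excluded = (
        (insp > thresholds.vessel_cut)
        | (exp > thresholds.vessel_cut)
        | ~np.isfinite(insp)
        | ~np.isfinite(exp)
    )
    insp_high = insp > thresholds.insp_cut   # above emphysema cut
    exp_high = exp > thresholds.exp_cut      # no air trapping

    labels = np.full(study.shape, PRMClass.OUTSIDE_LUNG, dtype=np.uint8)
    labels[mask] = np.select(
        [
            excluded[mask],
            insp_high[mask] & exp_high[mask],
            insp_high[mask] & ~exp_high[mask],
            ~insp_high[mask] & ~exp_high[mask],
        ],
        [
            np.uint8(PRMClass.EXCLUDED),
            np.uint8(PRMClass.NORMAL),
            np.uint8(PRMClass.FSAD),
            np.uint8(PRMClass.EMPH),
        ],
        default=np.uint8(PRMClass.UNCLASSIFIED),
    )
    provenance = {
        "insp_cut_hu": thresholds.insp_cut,
        "exp_cut_hu": thresholds.exp_cut,
        "vessel_cut_hu": thresholds.vessel_cut,
        "label_dictionary": {c.name: int(c) for c in PRMClass},
    }
    return PRMMap(labels, study.spacing, provenance)


def relative_volumes(prm: PRMMap, denominator: str = "in_mask") -> ClassFractions:
    """Compute %PRM per class under the requested denominator convention."""
    counts = {c: prm.count(c) for c in IN_MASK_CLASSES}
    n_mask = sum(counts.values())
    if denominator == "in_mask":
        denom = n_mask
    elif denominator == "classified_only":
        denom = sum(counts[c] for c in BINARY_CLASSES)
    else:
        raise ValueError(
            f"denominator must be 'in_mask' or 'classified_only', got {denominator!r}"
        )
    if denom == 0:
        raise ValueError(f"zero-size denominator ({denominator!r})")
    percentages = {c: 100.0 * counts[c] / denom for c in IN_MASK_CLASSES}
    return ClassFractions(percentages, denominator, denom, n_mask)


def extract_class_map(prm: PRMMap, class_id: "PRMClass | int | str") -> BinaryClassMap:
    """Extract one named class (Normal/fSAD/Emph) as a binary grid."""
    cls = resolve_class(class_id)
    if cls not in BINARY_CLASSES:
        raise ValueError(f"binary maps exist only for {[c.name for c in BINARY_CLASSES]}")
    return BinaryClassMap(prm.labels == cls, prm.spacing, label=cls.name)
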