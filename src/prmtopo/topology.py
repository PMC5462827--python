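"""Global and Local (moving-window) topology of PRM binary class maps.

Global analysis evaluates the Minkowski measures of one class map once over
the whole lung; Local analysis evaluates them on a 21³-voxel moving window
centred on every 5th voxel of the native grid, producing a coarse 3D map per
metric.  Local values are normalized into densities:

* V, S, B by the masked window volume (units 1, mm⁻¹, mm⁻²),
* χ (and the clustering descriptor α) by the masked window voxel count.

Windows whose lung-mask coverage falls below ``min_coverage`` are undefined
and carry NaN, never 0; a coverage grid is always returned.

Normalization conventions
-------------------------
Raw measures (the ``V/S/B/chi`` fields of :class:`MinkowskiRecord`) treat the
masked foreground as an isolated body: everything outside the mask or grid is
background, so a border foreground voxel has exposed faces.  The *densities*
instead estimate stationary per-volume rates from configurations that are
fully observed inside the analysis region (window ∩ mask): the surface
density counts only faces between two in-region voxels and divides each
direction by its number of observable voxel pairs (minus-sampling edge
correction).  This makes the S density unbiased for random fields, exactly
invariant under foreground/background complement, and ≈ 0 for a wholly
foreground window — a solid region has no internal interface, which is the
behaviour the clustered-vs-dispersed contrast relies on.

The clustering descriptor α is a stand-in (the canonical definition is not
public): observed normalized χ minus the expected normalized χ of an iid
random field at the same local volume density, the expectation interpolated
from simulated reference curves.  Output metadata flags it as non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import BinaryClassMap, ClassFractions
from .io_geometry import LungMask
from .minkowski import (
    SURFACE_MODES,
    euler_characteristic,
    mean_breadth,
    surface_area,
)

__all__ = [
    "WindowSpec",
    "MinkowskiRecord",
    "TopologyMaps",
    "SubjectSummary",
    "global_minkowski",
    "local_minkowski_maps",
    "alpha_descriptor",
    "global_alpha",
    "summarize_subject",
    "display_map",
    "surface_density",
]

LOCAL_METRICS = ("v", "s", "b", "chi")


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry of the Local analysis.

    ``window_edge`` is the cubic window edge in voxels (odd, ≥ 3; default 21),
    ``stride`` the analysis-grid spacing in voxels (default 5), and
    ``min_coverage`` the minimum fraction of window voxels inside the lung
    mask required to emit a value (default 0.5).
    """

    window_edge: int = 21
    stride: int = 5
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.window_edge < 3 or self.window_edge % 2 == 0:
            raise ValueError(f"window_edge must be odd and >= 3, got {self.window_edge}")
        if not (1 <= self.stride <= self.window_edge):
            raise ValueError(
                f"stride must satisfy 1 <= stride <= window_edge, got {self.stride}"
            )
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError(f"min_coverage must be in (0, 1], got {self.min_coverage}")

    @property
    def half(self) -> int:
        return self.window_edge // 2


@dataclass(frozen=True)
class MinkowskiRecord:
    """Global Minkowski measures of one class map plus normalized densities."""

    V: float            # mm^3
    S: float            # mm^2
    B: float            # mm
    chi: int            # dimensionless count
    v_density: float    # V / masked volume, unitless in [0, 1]
    s_density: float    # mm^-1
    b_density: float    # mm^-2
    chi_density: float  # per masked voxel
    n_mask_voxels: int
    masked_volume_mm3: float
    alpha_density: float | None = None
    meta: dict = field(default_factory=dict)

    def density(self, metric: str) -> float:
        values = {
            "v": self.v_density,
            "s": self.s_density,
            "b": self.b_density,
            "chi": self.chi_density,
            "alpha": self.alpha_density,
        }
        if metric not in values:
            raise ValueError(f"unknown metric {metric!r}")
        value = values[metric]
        if value is None:
            raise ValueError("alpha density not computed (no reference curves)")
        return value


@dataclass
class TopologyMaps:
    """Local normalized Minkowski maps on the stride-subsampled grid.

    Map arrays are float with NaN at undefined sites.  ``coverage`` (masked
    fraction per window) is defined everywhere.  Site ``(i, j, k)`` of an
    analysis grid corresponds to native voxel ``(i*stride, j*stride,
    k*stride)``.
    """

    maps: dict[str, np.ndarray]
    coverage: np.ndarray
    window: WindowSpec
    spacing: tuple[float, float, float]
    native_shape: tuple[int, int, int]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, metric: str) -> np.ndarray:
        try:
            return self.maps[metric]
        except KeyError:
            raise ValueError(
                f"unknown or uncomputed metric {metric!r}; have {sorted(self.maps)}"
            ) from None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coverage.shape  # type: ignore[return-value]

    @property
    def defined(self) -> np.ndarray:
        """Boolean grid of sites that met the coverage requirement."""
        return self.coverage >= self.window.min_coverage

    def site_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Native-grid voxel indices of the analysis sites, per axis."""
        return tuple(
            np.arange(n, dtype=float) * self.window.stride for n in self.grid_shape
        )  # type: ignore[return-value]


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject scalars: mean Local densities, Global densities, %PRM."""

    class_label: str
    local_means: dict[str, float]
    global_densities: dict[str, float]
    fractions: dict[str, float]
    n_defined_sites: int
    n_sites: int
    weighting: str = "unweighted"

    def to_row(self) -> dict[str, float | int | str]:
        row: dict[str, float | int | str] = {"class": self.class_label}
        for k, v in self.local_means.items():
            row[f"local_{k}_mean"] = v
        for k, v in self.global_densities.items():
            row[f"global_{k}"] = v
        for k, v in self.fractions.items():
            row[f"pct_{k}"] = v
        row["n_defined_sites"] = self.n_defined_sites
        row["n_sites"] = self.n_sites
        row["weighting"] = self.weighting
        return row


def _check_geometry(class_map: BinaryClassMap, mask: LungMask) -> None:
    if class_map.shape != mask.shape:
        raise ValueError(
            f"class map shape {class_map.shape} != mask shape {mask.shape}"
        )
    if not np.allclose(class_map.spacing, mask.spacing, rtol=1e-3):
        raise ValueError(
            f"class map spacing {class_map.spacing} != mask spacing {mask.spacing}"
        )


def surface_density(
    fg: np.ndarray,
    region: np.ndarray,
    spacing: tuple[float, float, float],
    mode: str = "faces",
) -> float:
    """Edge-corrected surface area per unit volume (mm⁻¹) within a region.

    Counts interfaces whose both voxels lie inside ``region`` and divides each
    direction by its count of observable in-region voxel pairs (times the
    direction's step length), so the estimate is unbiased for stationary
    random sets regardless of the region's shape.  Returns 0 for regions too
    small to contain any pair.
    """
    if mode == "faces":
        directions = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        weights = [1.0, 1.0, 1.0]
    elif mode == "crofton13":
        from .minkowski import _CROFTON_DIRS, crofton_direction_weights

        directions = list(_CROFTON_DIRS)
        # S_V = 2 P_L for isotropic test lines (Crofton); w_k are the
        # direction solid-angle weights.  Note the deliberate scale
        # difference to "faces": face counting reports the polyhedral voxel
        # boundary, crofton13 the isotropic surface density, which is lower
        # for axis-aligned voxel interfaces.
        weights = list(2.0 * crofton_direction_weights(spacing))
    else:
        raise ValueError(f"unknown surface mode {mode!r}; expected one of {SURFACE_MODES}")

    s = np.asarray(spacing, dtype=float)
    total = 0.0
    for w, d in zip(weights, directions):
        from .minkowski import _pair_slices

        lo, hi = _pair_slices(d)
        both = region[lo] & region[hi]
        n_sites = int(np.count_nonzero(both))
        if n_sites == 0:
            continue
        n_exposed = int(np.count_nonzero((fg[lo] ^ fg[hi]) & both))
        step = float(np.linalg.norm(s * np.asarray(d)))
        total += w * n_exposed / (n_sites * step)
    return float(total)


def global_minkowski(
    class_map: BinaryClassMap,
    mask: LungMask,
    surface_mode: str = "faces",
    connectivity: int = 6,
) -> MinkowskiRecord:
    """Minkowski measures of one class map over the entire masked lung."""
    _check_geometry(class_map, mask)
    n_mask = mask.n_voxels
    if n_mask == 0:
        raise ValueError("empty mask")
    spacing = class_map.spacing
    voxvol = float(np.prod(spacing))
    fg = class_map.values & mask.values
    n_fg = int(np.count_nonzero(fg))

    v_raw = n_fg * voxvol
    s_raw = surface_area(fg, spacing, mode=surface_mode)
    b_raw = mean_breadth(fg, spacing)
    chi = euler_characteristic(fg, connectivity=connectivity)
    masked_volume = n_mask * voxvol

    return MinkowskiRecord(
        V=v_raw,
        S=s_raw,
        B=b_raw,
        chi=chi,
        v_density=n_fg / n_mask,
        s_density=surface_density(fg, mask.values, spacing, mode=surface_mode),
        b_density=b_raw / masked_volume,
        chi_density=chi / n_mask,
        n_mask_voxels=n_mask,
        masked_volume_mm3=masked_volume,
        meta={
            "surface_mode": surface_mode,
            "connectivity": connectivity,
            "class": class_map.label,
        },
    )


def local_minkowski_maps(
    class_map: BinaryClassMap,
    mask: LungMask,
    spec: WindowSpec | None = None,
    metrics: Iterable[str] = LOCAL_METRICS,
    surface_mode: str = "faces",
    connectivity: int = 6,
) -> TopologyMaps:
    """Compute Local normalized Minkowski maps on the analysis grid.

    Each analysis site (every ``stride``-th voxel per axis) carries the
    measures of the window restricted to the lung mask; out-of-grid voxels
    are treated as outside the mask.  Sites with coverage below
    ``spec.min_coverage`` are NaN.

    ``metrics`` selects which maps to compute (subset of ``v, s, b, chi``);
    restricting it speeds up large batch analyses.
    """
    spec = spec or WindowSpec()
    _check_geometry(class_map, mask)
    shape = class_map.shape
    if any(spec.window_edge > n for n in shape):
        raise ValueError(
            f"window edge {spec.window_edge} exceeds volume shape {shape}"
        )
    metrics = tuple(metrics)
    unknown = set(metrics) - set(LOCAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {LOCAL_METRICS}")

    spacing = class_map.spacing
    voxvol = float(np.prod(spacing))
    half, w = spec.half, spec.window_edge
    pad = [(half, half)] * 3
    mask_p = np.pad(mask.values, pad)
    fg_p = np.pad(class_map.values & mask.values, pad)

    sites = [np.arange(0, n, spec.stride) for n in shape]
    grid_shape = tuple(len(s) for s in sites)
    coverage = np.zeros(grid_shape)
    maps = {m: np.full(grid_shape, np.nan) for m in metrics}
    n_window = float(w**3)

    for ii, i in enumerate(sites[0]):
        for jj, j in enumerate(sites[1]):
            for kk, k in enumerate(sites[2]):
                w_mask = mask_p[i:i + w, j:j + w, k:k + w]
                n_mask = int(np.count_nonzero(w_mask))
                cov = n_mask / n_window
                coverage[ii, jj, kk] = cov
                if cov < spec.min_coverage:
                    continue
                w_fg = fg_p[i:i + w, j:j + w, k:k + w]
                if "v" in maps:
                    maps["v"][ii, jj, kk] = np.count_nonzero(w_fg) / n_mask
                if "s" in maps:
                    maps["s"][ii, jj, kk] = surface_density(
                        w_fg, w_mask, spacing, mode=surface_mode
                    )
                if "b" in maps:
                    maps["b"][ii, jj, kk] = mean_breadth(w_fg, spacing) / (
                        n_mask * voxvol
                    )
                if "chi" in maps:
                    maps["chi"][ii, jj, kk] = (
                        euler_characteristic(w_fg, connectivity=connectivity) / n_mask
                    )

    return TopologyMaps(
        maps=maps,
        coverage=coverage,
        window=spec,
        spacing=spacing,
        native_shape=shape,
        meta={
            "surface_mode": surface_mode,
            "connectivity": connectivity,
            "class": class_map.label,
        },
    )


def _curve_arrays(reference_curves: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    required = {"v_mean", "chi_mean"}
    if not required <= set(reference_curves.columns):
        raise ValueError(
            f"reference curves must provide columns {sorted(required)}, "
            f"got {list(reference_curves.columns)}"
        )
    curve = reference_curves.sort_values("v_mean")
    v = np.concatenate([[0.0], curve["v_mean"].to_numpy(), [1.0]])
    # an empty field has chi = 0; a full field has chi = 1 over the voxel
    # count, which is indistinguishable from 0 at map scale
    chi = np.concatenate([[0.0], curve["chi_mean"].to_numpy(), [0.0]])
    return v, chi


def alpha_descriptor(tm: TopologyMaps, reference_curves: pd.DataFrame) -> np.ndarray:
    """Clustering descriptor α on the analysis grid (non-canonical stand-in).

    α = observed normalized χ − expected normalized χ of an iid random field
    at the same local volume density (interpolated from ``reference_curves``,
    see :func:`prmtopo.synthetic.expected_random_curves`, ideally generated
    at the window size).  Negative α means fewer disjoint structures than a
    random field of equal density, i.e. clustering; α ≈ 0 for random fields.
    Sites with no foreground (local V = 0) are undefined (NaN), not 0.

    The result is stored on ``tm`` as metric ``"alpha"`` and returned.
    """
    if reference_curves is None or len(reference_curves) == 0:
        raise ValueError("missing reference curves for alpha")
    try:
        v_map = tm["v"]
        chi_map = tm["chi"]
    except ValueError as err:
        raise ValueError("alpha requires computed local v and chi maps") from err
    v_grid, chi_grid = _curve_arrays(reference_curves)
    expected = np.interp(v_map, v_grid, chi_grid)
    alpha = chi_map - expected
    alpha = np.where(np.isnan(v_map) | (v_map <= 0.0), np.nan, alpha)
    tm.maps["alpha"] = alpha
    tm.meta["alpha"] = "non-canonical stand-in: chi density minus random-field expectation at equal local V"
    return alpha


def global_alpha(record: MinkowskiRecord, reference_curves: pd.DataFrame) -> MinkowskiRecord:
    """Return a record with the Global α density filled in (same stand-in)."""
    if reference_curves is None or len(reference_curves) == 0:
        raise ValueError("missing reference curves for alpha")
    v_grid, chi_grid = _curve_arrays(reference_curves)
    if record.v_density <= 0.0:
        alpha = None
    else:
        alpha = float(record.chi_density - np.interp(record.v_density, v_grid, chi_grid))
    meta = dict(record.meta)
    meta["alpha"] = "non-canonical stand-in"
    return replace(record, alpha_density=alpha, meta=meta)


def summarize_subject(
    tm: TopologyMaps,
    global_record: MinkowskiRecord,
    fractions: ClassFractions,
    weighting: str = "unweighted",
) -> SubjectSummary:
    """Collapse Local maps to per-subject means and assemble the summary row.

    The subject value of each metric is the mean over defined analysis sites
    (the default, unweighted) or the coverage-weighted mean
    (``weighting="coverage"``).
    """
    defined = tm.defined
    n_defined = int(np.count_nonzero(defined))
    if n_defined == 0:
        raise ValueError("no defined analysis sites (coverage threshold too strict?)")
    if weighting not in ("unweighted", "coverage"):
        raise ValueError(f"weighting must be 'unweighted' or 'coverage', got {weighting!r}")

    local_means: dict[str, float] = {}
    for metric, grid in tm.maps.items():
        valid = defined & ~np.isnan(grid)
        if not valid.any():
            local_means[metric] = float("nan")
            continue
        if weighting == "coverage":
            wts = tm.coverage[valid]
            local_means[metric] = float(np.average(grid[valid], weights=wts))
        else:
            local_means[metric] = float(np.mean(grid[valid]))

    global_densities = {
        "v": global_record.v_density,
        "s": global_record.s_density,
        "b": global_record.b_density,
        "chi": global_record.chi_density,
    }
    if global_record.alpha_density is not None:
        global_densities["alpha"] = global_record.alpha_density

    from .classify import resolve_class

    frac = {
        name: fractions[resolve_class(name)]
        for name in ("normal", "fsad", "emph")
    }
    return SubjectSummary(
        class_label=tm.meta.get("class", ""),
        local_means=local_means,
        global_densities=global_densities,
        fractions=frac,
        n_defined_sites=n_defined,
        n_sites=int(np.prod(tm.grid_shape)),
        weighting=weighting,
    )


def display_map(
    tm: TopologyMaps,
    metric: str,
    mask: LungMask | None = None,
) -> np.ndarray:
    """Render a metric map at native resolution for display.

    The metric is multiplied by the local density V (highlighting regions of
    substantial disease), undefined sites are set to 0, and the analysis grid
    is trilinearly interpolated back to the native dimensions; voxels outside
    the lung mask are zeroed.
    """
    from scipy.interpolate import RegularGridInterpolator

    if metric not in ("s", "b", "chi", "alpha"):
        raise ValueError(f"display metric must be one of s/b/chi/alpha, got {metric!r}")
    if not tm.defined.any():
        raise ValueError("metric map is empty: no defined analysis sites")
    values = tm[metric] * tm["v"]
    values = np.nan_to_num(values, nan=0.0)

    coords = tm.site_coordinates()
    interp = RegularGridInterpolator(coords, values, method="linear",
                                     bounds_error=False, fill_value=None)
    native = [np.arange(n, dtype=float) for n in tm.native_shape]
    # clip to the site bounding box: edge voxels take the nearest site plane,
    # keeping interpolated values inside the range of contributing sites
    pts = np.stack(
        np.meshgrid(
            *[np.clip(ax, 0.0, c[-1]) for ax, c in zip(native, coords)],
            indexing="ij",
        ),
        axis=-1,
    )
    out = interp(pts)
    if mask is not None:
        if mask.shape != tm.native_shape:
            raise ValueError(
                f"mask shape {mask.shape} != native shape {tm.native_shape}"
            )
        out[~mask.values] = 0.0
    return out
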