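"""Minkowski measures (intrinsic volumes) of 3D binary voxel images.

The four measures of a voxel body X (union of closed axis-aligned voxel
boxes) are estimated from local voxel configurations:

* volume V  = voxel count × voxel volume (mm³),
* surface area S (mm²),
* mean breadth B = integral of mean curvature / 2π (mm); (l+w+h)/2 for a box,
* Euler–Poincaré characteristic χ = components − tunnels + cavities.

Two surface estimators are provided.  ``"faces"`` (default) is the exact
boundary area of the voxel polyhedron, i.e. 2×2×1 pair-configuration counting
with polyhedral weights — every face between foreground and background (or
the grid border) contributes its face area.  ``"crofton13"`` is a Crofton-
formula estimator that counts phase transitions along the 13 lattice
directions with spherical-design weights (from the spherical Voronoi areas of
the direction set), which removes most of the axis-alignment bias of face
counting for smooth isotropic bodies.

Mean breadth is computed by classifying every lattice edge by its four
incident voxels (convex / flat / concave / diagonal), which reproduces the
polyhedral integral of mean curvature exactly, and hence (l+w+h)/2 for solid
boxes.  χ is the alternating sum of cell counts of a cubical complex: the
"min" complex (a lower-dimensional cell is present when *all* incident voxels
are foreground) yields the 6-connected-foreground / 26-connected-background
Euler number, the "max" complex (present when *any* incident voxel is
foreground) yields the (26, 6) convention.

Everything outside the grid is background ("isolated scene"): a foreground
voxel on the border has exposed faces.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

__all__ = [
    "surface_area",
    "mean_breadth",
    "euler_characteristic",
    "crofton_directions",
    "crofton_direction_weights",
    "SURFACE_MODES",
]

SURFACE_MODES = ("faces", "crofton13")

#: The 13 lattice directions used by the Crofton surface estimator:
#: 3 axes, 6 face diagonals, 4 body diagonals (one of each ± pair).
_CROFTON_DIRS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
)


def _as_bool3d(grid: np.ndarray) -> np.ndarray:
    arr = np.asarray(grid)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D binary grid, got shape {arr.shape}")
    return arr.astype(bool, copy=False)


def _spacing3(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(spacing).ravel()) if np.ndim(spacing) else (float(spacing),) * 3
    if len(s) == 1:
        s = s * 3
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be a positive scalar or 3-tuple, got {spacing!r}")
    return s  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# surface area
# ---------------------------------------------------------------------------

def _pair_slices(ndim_shift: tuple[int, int, int]):
    """Slice pair (a, b) such that arr[a] and arr[b] are neighbours at the shift."""
    lo, hi = [], []
    for d in ndim_shift:
        if d == 0:
            lo.append(slice(None))
            hi.append(slice(None))
        elif d > 0:
            lo.append(slice(None, -d))
            hi.append(slice(d, None))
        else:
            lo.append(slice(-d, None))
            hi.append(slice(None, d))
    return tuple(lo), tuple(hi)


def _transition_count(fg: np.ndarray, direction: tuple[int, int, int]) -> int:
    """Number of fg/bg transitions along `direction`, border = background."""
    padded = np.pad(fg, 1)
    lo, hi = _pair_slices(direction)
    return int(np.count_nonzero(padded[lo] ^ padded[hi]))


def exposed_face_counts(fg: np.ndarray) -> tuple[int, int, int]:
    """Exposed boundary faces per axis (border counts as background)."""
    return tuple(
        _transition_count(fg, tuple(1 if i == ax else 0 for i in range(3)))
        for ax in range(3)
    )  # type: ignore[return-value]


def crofton_directions(spacing) -> np.ndarray:
    """Physical (mm) step vectors of the 13 Crofton directions."""
    s = np.asarray(_spacing3(spacing))
    return np.asarray(_CROFTON_DIRS, dtype=float) * s


@lru_cache(maxsize=8)
def _cached_weights(spacing_key: tuple[float, float, float]) -> tuple[float, ...]:
    from scipy.spatial import SphericalVoronoi

    vecs = crofton_directions(spacing_key)
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    points = np.vstack([units, -units])
    sv = SphericalVoronoi(points, radius=1.0)
    areas = sv.calculate_areas()
    w = (areas[:13] + areas[13:]) / (4.0 * np.pi)
    return tuple(float(v) for v in w)


def crofton_direction_weights(spacing) -> np.ndarray:
    """Isotropic weights of the 13 directions (spherical Voronoi fractions).

    The weight of direction k is the fraction of the unit sphere closer to
    ±ω_k than to any other sampled direction; the 13 weights sum to 1.
    """
    return np.asarray(_cached_weights(_spacing3(spacing)))


def surface_area(grid: np.ndarray, spacing=1.0, mode: str = "faces") -> float:
    """Estimate the boundary area (mm²) of the foreground.

    Parameters
    ----------
    grid
        3D binary array; anything outside the grid is background.
    spacing
        Voxel size in mm (scalar or per-axis 3-tuple).
    mode
        ``"faces"`` — exact polyhedral boundary area of the voxel body;
        ``"crofton13"`` — 13-direction Crofton estimator (less axis bias for
        smooth isotropic shapes).
    """
    fg = _as_bool3d(grid)
    s = _spacing3(spacing)
    if fg.size == 0 or not fg.any():
        return 0.0
    if mode == "faces":
        nx, ny, nz = exposed_face_counts(fg)
        return float(nx * s[1] * s[2] + ny * s[0] * s[2] + nz * s[0] * s[1])
    if mode == "crofton13":
        weights = crofton_direction_weights(s)
        lengths = np.linalg.norm(crofton_directions(s), axis=1)
        v_cell = float(np.prod(s))
        total = 0.0
        for k, direction in enumerate(_CROFTON_DIRS):
            n_k = _transition_count(fg, direction)
            total += weights[k] * n_k / lengths[k]
        return float(2.0 * v_cell * total)
    raise ValueError(f"unknown surface mode {mode!r}; expected one of {SURFACE_MODES}")


# ---------------------------------------------------------------------------
# mean breadth
# ---------------------------------------------------------------------------

# Exterior dihedral angle contributed by a lattice edge, keyed by the
# configuration of its 4 incident voxels: one foreground voxel -> convex
# quarter edge (π/2); three -> concave (−π/2); two sharing a face -> flat (0);
# two diagonal -> two independent convex wedges (π/2 each).  The integral of
# mean curvature is M = ½ Σ_e ℓ_e α_e and B = M / 2π.

def _plaquette_counts(fg: np.ndarray, edge_axis: int) -> tuple[int, int, int]:
    """(n_one, n_three, n_diag) over all lattice edges along `edge_axis`."""
    perp = [ax for ax in range(3) if ax != edge_axis]
    pad_width = [(0, 0)] * 3
    for ax in perp:
        pad_width[ax] = (1, 1)
    p = np.pad(fg, pad_width)

    def take(du: int, dv: int) -> np.ndarray:
        sl = [slice(None)] * 3
        sl[perp[0]] = slice(du, p.shape[perp[0]] - 1 + du)
        sl[perp[1]] = slice(dv, p.shape[perp[1]] - 1 + dv)
        return p[tuple(sl)]

    a, b, c, d = take(0, 0), take(1, 0), take(0, 1), take(1, 1)
    n = a.astype(np.uint8) + b + c + d
    n_one = int(np.count_nonzero(n == 1))
    n_three = int(np.count_nonzero(n == 3))
    # diagonal pairs: (a, d) or (b, c)
    n_diag = int(np.count_nonzero((n == 2) & ((a & d) | (b & c))))
    return n_one, n_three, n_diag


def mean_breadth(grid: np.ndarray, spacing=1.0) -> float:
    """Mean breadth B (mm) of the voxel body; (l+w+h)/2 for solid boxes.

    Computed from the exact polyhedral integral of mean curvature by
    classifying every lattice edge by its four incident voxels.  Can be
    negative for predominantly concave (sponge-like) foregrounds.
    """
    fg = _as_bool3d(grid)
    s = _spacing3(spacing)
    if fg.size == 0 or not fg.any():
        return 0.0
    half_pi = np.pi / 2.0
    m = 0.0  # twice the integral of mean curvature, Σ ℓ_e α_e
    for ax in range(3):
        n_one, n_three, n_diag = _plaquette_counts(fg, ax)
        alpha_sum = (n_one - n_three) * half_pi + n_diag * np.pi
        m += s[ax] * alpha_sum
    return float(m / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# Euler characteristic
# ---------------------------------------------------------------------------

def _cell_counts_max(fg: np.ndarray) -> tuple[int, int, int, int]:
    """(n0, n1, n2, n3) of the closed-voxel ("max") cubical complex."""
    p = np.pad(fg, 1)
    n3 = int(np.count_nonzero(fg))
    n2 = 0
    for ax in range(3):
        lo, hi = _pair_slices(tuple(1 if i == ax else 0 for i in range(3)))
        n2 += int(np.count_nonzero(p[lo] | p[hi]))
    n1 = 0
    for ax in range(3):
        perp = [a for a in range(3) if a != ax]
        acc = None
        for du, dv in product((0, 1), repeat=2):
            shift = [0, 0, 0]
            shift[perp[0]] = du
            shift[perp[1]] = dv
            sl = tuple(
                slice(d, p.shape[i] - 1 + d) if i in perp else slice(None)
                for i, d in enumerate(shift)
            )
            block = p[sl]
            acc = block if acc is None else (acc | block)
        n1 += int(np.count_nonzero(acc))
    acc = None
    for offs in product((0, 1), repeat=3):
        sl = tuple(slice(d, p.shape[i] - 1 + d) for i, d in enumerate(offs))
        block = p[sl]
        acc = block if acc is None else (acc | block)
    n0 = int(np.count_nonzero(acc))
    return n0, n1, n2, n3


def _cell_counts_min(fg: np.ndarray) -> tuple[int, int, int, int]:
    """(n0, n1, n2, n3) of the interior ("min") cubical complex."""
    n3 = int(np.count_nonzero(fg))
    n2 = 0
    for ax in range(3):
        lo, hi = _pair_slices(tuple(1 if i == ax else 0 for i in range(3)))
        n2 += int(np.count_nonzero(fg[lo] & fg[hi]))
    n1 = 0
    for ax in range(3):
        perp = [a for a in range(3) if a != ax]
        acc = None
        for du, dv in product((0, 1), repeat=2):
            shift = [0, 0, 0]
            shift[perp[0]] = du
            shift[perp[1]] = dv
            sl = tuple(
                slice(d, fg.shape[i] - 1 + d) if i in perp else slice(None)
                for i, d in enumerate(shift)
            )
            block = fg[sl]
            acc = block if acc is None else (acc & block)
        n1 += int(np.count_nonzero(acc)) if acc is not None and acc.size else 0
    acc = None
    for offs in product((0, 1), repeat=3):
        sl = tuple(slice(d, fg.shape[i] - 1 + d) for i, d in enumerate(offs))
        block = fg[sl]
        acc = block if acc is None else (acc & block)
    n0 = int(np.count_nonzero(acc)) if acc is not None and acc.size else 0
    return n0, n1, n2, n3


def euler_characteristic(grid: np.ndarray, connectivity: int = 6) -> int:
    """Euler–Poincaré characteristic χ = components − tunnels + cavities.

    Parameters
    ----------
    grid
        3D binary array.
    connectivity
        Foreground adjacency: ``6`` (default; background is then
        26-connected) or ``26`` (background 6-connected).  The two differ
        only on corner/edge-touching configurations.
    """
    fg = _as_bool3d(grid)
    if fg.size == 0:
        return 0
    if connectivity == 6:
        n0, n1, n2, n3 = _cell_counts_min(fg)
        return n3 - n2 + n1 - n0
    if connectivity == 26:
        n0, n1, n2, n3 = _cell_counts_max(fg)
        return n0 - n1 + n2 - n3
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
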