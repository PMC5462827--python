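"""Independent brute-force oracles for the Minkowski estimators.

Everything here is deliberately naive (pure-Python loops, direct geometric
definitions) and shares no code with the package implementation.
"""

from itertools import product

import numpy as np

_AXIS_NEIGHBOURS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def exposed_face_area(grid: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Sum of face areas between a foreground voxel and background/border."""
    fg = np.asarray(grid).astype(bool)
    sx, sy, sz = spacing
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    nx, ny, nz = fg.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not fg[i, j, k]:
                    continue
                for di, dj, dk in _AXIS_NEIGHBOURS:
                    ni, nj, nk = i + di, j + dj, k + dk
                    outside = not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz)
                    if outside or not fg[ni, nj, nk]:
                        axis = 0 if di else (1 if dj else 2)
                        total += face_area[axis]
    return total


def _iter_cells(shape):
    """All cells of the cubical lattice over a voxel grid.

    Yields (dim, incident_voxel_indices).  A cell of dimension d is spanned
    along d axes; its incident voxels are the up-to 2^(3-d) voxels touching
    it (those inside the grid).
    """
    nx, ny, nz = shape
    # a cell is located by a lattice vertex (i, j, k) in [0..n] per axis and
    # a subset of axes along which it extends
    for axes in range(8):
        span = [(axes >> a) & 1 for a in range(3)]
        dim = sum(span)
        ranges = [range(n + 1 - s) for n, s in zip(shape, span)]
        for i, j, k in product(*ranges):
            incident = []
            offsets = [([0] if s else [-1, 0]) for s in span]
            for di, dj, dk in product(*offsets):
                vi, vj, vk = i + di, j + dj, k + dk
                if 0 <= vi < nx and 0 <= vj < ny and 0 <= vk < nz:
                    incident.append((vi, vj, vk))
            yield dim, incident


def euler_cubical(grid: np.ndarray, connectivity: int = 6) -> int:
    """χ as the alternating sum of cubical-complex cell counts.

    connectivity 26: closed-voxel ("max") complex — a cell is present when
    *any* incident voxel is foreground; χ = n0 − n1 + n2 − n3.
    connectivity 6: interior ("min") complex — present when *all* voxels
    incident to the cell (in the infinite lattice) are foreground;
    χ = n3 − n2 + n1 − n0.
    """
    fg = np.asarray(grid).astype(bool)
    counts = [0, 0, 0, 0]
    for dim, incident in _iter_cells(fg.shape):
        full = 2 ** (3 - dim)
        n_fg = sum(fg[v] for v in incident)
        if connectivity == 26:
            present = n_fg > 0
        else:
            present = len(incident) == full and n_fg == full
        if present:
            counts[dim] += 1
    n0, n1, n2, n3 = counts
    if connectivity == 26:
        return n0 - n1 + n2 - n3
    return n3 - n2 + n1 - n0


def breadth_edge_sum(grid: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean breadth via direct enumeration of all lattice edges.

    Each edge contributes ℓ_e α_e with α from its 4 incident voxels
    (1 fg: π/2 convex; 3 fg: −π/2 concave; 2 diagonal fg: π, two wedges);
    B = Σ ℓ_e α_e / (4π).
    """
    fg = np.asarray(grid).astype(bool)
    nx, ny, nz = fg.shape
    shape = (nx, ny, nz)
    total = 0.0
    half_pi = np.pi / 2
    for axis in range(3):
        perp = [a for a in range(3) if a != axis]
        length = spacing[axis]
        ranges = []
        for a in range(3):
            ranges.append(range(shape[a]) if a == axis else range(shape[a] + 1))
        for pos in product(*ranges):
            voxels = []
            for du, dv in product((-1, 0), repeat=2):
                idx = list(pos)
                idx[perp[0]] += du
                idx[perp[1]] += dv
                if all(0 <= idx[a] < shape[a] for a in range(3)):
                    voxels.append(bool(fg[tuple(idx)]))
                else:
                    voxels.append(False)
            n = sum(voxels)
            if n == 1:
                alpha = half_pi
            elif n == 3:
                alpha = -half_pi
            elif n == 2 and voxels[0] == voxels[3]:  # (-1,-1)&(0,0) or (-1,0)&(0,-1)
                alpha = np.pi
            else:
                alpha = 0.0
            total += length * alpha
    return total / (4 * np.pi)
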