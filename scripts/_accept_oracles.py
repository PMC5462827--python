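"""Naive brute-force oracles used by acceptance.py (pure-Python loops,
independent of the package implementation)."""

from itertools import product

import numpy as np

_NEIGHBOURS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def exposed_face_area(grid) -> float:
    fg = np.asarray(grid).astype(bool)
    nx, ny, nz = fg.shape
    total = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not fg[i, j, k]:
                    continue
                for di, dj, dk in _NEIGHBOURS:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz) or not fg[ni, nj, nk]:
                        total += 1
    return float(total)


def euler_cubical(grid, connectivity: int = 6) -> int:
    """Alternating sum of cubical-complex cell counts (max / min complex)."""
    fg = np.asarray(grid).astype(bool)
    shape = fg.shape
    counts = [0, 0, 0, 0]
    for axes in range(8):
        span = [(axes >> a) & 1 for a in range(3)]
        dim = sum(span)
        full = 2 ** (3 - dim)
        ranges = [range(n + 1 - s) for n, s in zip(shape, span)]
        for i, j, k in product(*ranges):
            incident = []
            offsets = [([0] if s else [-1, 0]) for s in span]
            for di, dj, dk in product(*offsets):
                v = (i + di, j + dj, k + dk)
                if all(0 <= v[a] < shape[a] for a in range(3)):
                    incident.append(bool(fg[v]))
            n_fg = sum(incident)
            if connectivity == 26:
                present = n_fg > 0
            else:
                present = len(incident) == full and n_fg == full
            if present:
                counts[dim] += 1
    n0, n1, n2, n3 = counts
    return (n0 - n1 + n2 - n3) if connectivity == 26 else (n3 - n2 + n1 - n0)


def breadth_box(dims) -> float:
    """Closed-form mean breadth of a solid rectangular box."""
    return sum(dims) / 2.0
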