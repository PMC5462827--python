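"""Local-vs-Global agreement validation.

The robustness of a topology metric is judged by how well the subject mean of
its Local (windowed) values tracks the Global value computed once over the
whole volume: an ordinary least-squares regression of mean-Local on Global
across a collection of maps spanning distinct volume fractions.  Surface
area is expected to agree almost perfectly (R² > 0.999); agreement degrades
with metric complexity and is merely reported for χ-derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .classify import BinaryClassMap
from .io_geometry import LungMask
from .topology import WindowSpec, global_minkowski, local_minkowski_maps

__all__ = ["AgreementResult", "local_global_agreement"]


@dataclass(frozen=True)
class AgreementResult:
    """OLS fit of mean-Local vs Global for one metric over a map collection."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    n_maps: int
    local_means: tuple[float, ...]
    global_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r_squared}")


def local_global_agreement(
    maps: Sequence[BinaryClassMap],
    mask: LungMask | None,
    metric: str = "s",
    spec: WindowSpec | None = None,
    surface_mode: str = "faces",
    connectivity: int = 6,
    reference_curves=None,
) -> AgreementResult:
    """Regress subject mean-Local density on Global density across maps.

    Parameters
    ----------
    maps
        ≥ 3 binary class maps on a common grid, ideally spanning distinct
        volume fractions.
    mask
        Lung mask shared by all maps; ``None`` uses the full grid.
    metric
        One of ``v``, ``s``, ``b``, ``chi``, ``alpha`` (alpha additionally
        needs ``reference_curves``).
    """
    spec = spec or WindowSpec()
    if len(maps) < 3:
        raise ValueError(f"need at least 3 maps for a reported R^2, got {len(maps)}")
    if mask is None:
        first = maps[0]
        mask = LungMask(np.ones(first.shape, dtype=bool), first.spacing)

    wanted = ("v", "chi") if metric in ("chi", "alpha") else ("v", metric)
    local_means: list[float] = []
    global_values: list[float] = []
    for class_map in maps:
        record = global_minkowski(class_map, mask, surface_mode=surface_mode,
                                  connectivity=connectivity)
        tm = local_minkowski_maps(class_map, mask, spec, metrics=wanted,
                                  surface_mode=surface_mode, connectivity=connectivity)
        if metric == "alpha":
            from .topology import alpha_descriptor, global_alpha

            alpha_descriptor(tm, reference_curves)
            record = global_alpha(record, reference_curves)
        grid = tm[metric]
        valid = tm.defined & ~np.isnan(grid)
        if not valid.any():
            raise ValueError("a map produced no defined analysis sites")
        local_means.append(float(np.mean(grid[valid])))
        global_values.append(float(record.density(metric)))

    x = np.asarray(global_values)
    y = np.asarray(local_means)
    if np.allclose(x, x[0]) :
        raise ValueError("degenerate regression: all Global values identical")
    fit = stats.linregress(x, y)
    return AgreementResult(
        metric=metric,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_maps=len(maps),
        local_means=tuple(local_means),
        global_values=tuple(global_values),
    )
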