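"""End-to-end per-subject pipeline: load → filter → classify → topology.

Composes the whole workflow for one paired study and writes every product
(PRM label volume with JSON sidecar, class fractions CSV, Local topology
maps and display maps per class, subject summary CSV, and a run log
capturing every decision parameter).  All stages are deterministic for fixed
inputs and configuration; any stage failure is re-raised with the stage name
attached and no partial outputs are left in the output directory.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    PRMThresholds,
    classify_prm,
    extract_class_map,
    median_filter_axial,
    relative_volumes,
)
from .io_geometry import (
    HUVolume,
    LungMask,
    load_paired_study,
    save_volume,
    validate_geometry,
)
from .topology import (
    WindowSpec,
    alpha_descriptor,
    display_map,
    global_alpha,
    global_minkowski,
    local_minkowski_maps,
    summarize_subject,
)

__all__ = ["PipelineConfig", "PipelineError", "run_subject_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Every tunable of the subject pipeline, serializable to/from YAML."""

    insp_path: str = ""
    exp_path: str = ""
    mask_path: str = ""
    out_dir: str = "prmtopo_out"
    insp_cut: float = -950.0
    exp_cut: float = -856.0
    vessel_cut: float = -500.0
    apply_median_filter: bool = True
    axial_axis: int = 2
    window_edge: int = 21
    stride: int = 5
    min_coverage: float = 0.5
    classes: tuple[str, ...] = ("fsad", "emph")
    denominator: str = "in_mask"
    surface_mode: str = "faces"
    connectivity: int = 6
    weighting: str = "unweighted"
    compute_alpha: bool = False
    alpha_reps: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classes" in data:
            data["classes"] = tuple(data["classes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["classes"] = list(self.classes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def thresholds(self) -> PRMThresholds:
        return PRMThresholds(self.insp_cut, self.exp_cut, self.vessel_cut)

    def window(self) -> WindowSpec:
        return WindowSpec(self.window_edge, self.stride, self.min_coverage)


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except BaseException as err:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(name, err) from err


def _save_float_map(values: np.ndarray, spacing, path: Path) -> None:
    # NaN marks undefined analysis sites and survives the float64 round trip
    save_volume(HUVolume(np.asarray(values, dtype=np.float64), spacing), path)


def run_subject_pipeline(config: PipelineConfig) -> dict:
    """Run the full PRM + topology workflow for one subject.

    Returns a dict with the written paths, the class fractions and the
    per-class :class:`~prmtopo.topology.SubjectSummary` objects.  Outputs are
    staged in a temporary directory and moved into ``config.out_dir`` only on
    success, so a failing stage leaves no partial outputs.
    """
    out_dir = Path(config.out_dir)
    work = Path(tempfile.mkdtemp(prefix="prmtopo_"))
    try:
        result = _run(config, work)
    except BaseException:
        shutil.rmtree(work, ignore_errors=True)
        raise
    out_dir.mkdir(parents=True, exist_ok=True)
    for item in work.iterdir():
        target = out_dir / item.name
        if target.exists():
            target.unlink()
        shutil.move(str(item), target)
    work.rmdir()
    result["out_dir"] = str(out_dir)
    return result


def _run(config: PipelineConfig, out: Path) -> dict:
    with _stage("load"):
        study = load_paired_study(config.insp_path, config.exp_path, config.mask_path)
    with _stage("validate"):
        report = validate_geometry(study)
        report.raise_on_error()
    with _stage("median_filter"):
        if config.apply_median_filter:
            study = type(study)(
                inspiration=median_filter_axial(study.inspiration, config.axial_axis),
                expiration=median_filter_axial(study.expiration, config.axial_axis),
                mask=study.mask,
            )
    with _stage("classify"):
        prm = classify_prm(study, config.thresholds())
    with _stage("relative_volumes"):
        fractions = relative_volumes(prm, config.denominator)

    spacing = prm.spacing
    sidecar = {
        "software": f"prmtopo {__version__}",
        "thresholds_hu": {
            "insp_cut": config.insp_cut,
            "exp_cut": config.exp_cut,
            "vessel_cut": config.vessel_cut,
        },
        "median_filter": "3x3 axial" if config.apply_median_filter else "none",
        "axial_axis": config.axial_axis,
        "label_dictionary": prm.provenance.get("label_dictionary", {}),
        "window": {
            "edge_voxels": config.window_edge,
            "stride_voxels": config.stride,
            "min_coverage": config.min_coverage,
        },
        "surface_mode": config.surface_mode,
        "connectivity": config.connectivity,
        "denominator": config.denominator,
        "weighting": config.weighting,
        "alpha": (
            "non-canonical stand-in (chi minus random-field expectation)"
            if config.compute_alpha
            else "not computed"
        ),
        "seed": config.seed,
    }

    with _stage("write_prm"):
        save_volume(HUVolume(prm.labels.astype(np.float64), spacing), out / "prm_labels.nii.gz")
        (out / "prm_labels.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        frac_row = {f"pct_{k.name.lower()}": v for k, v in fractions.percentages.items()}
        frac_row["denominator"] = fractions.denominator
        frac_row["n_denominator"] = fractions.n_denominator
        pd.DataFrame([frac_row]).to_csv(out / "class_fractions.csv", index=False)

    curves = None
    if config.compute_alpha:
        with _stage("alpha_reference"):
            from .synthetic import expected_random_curves

            edge = config.window_edge
            curves = expected_random_curves(
                reps=config.alpha_reps,
                shape=(edge, edge, edge),
                seed=config.seed,
                surface_mode=config.surface_mode,
                connectivity=config.connectivity,
                spacing=spacing,
            )
            curves.to_csv(out / "alpha_reference_curves.csv", index=False)

    summaries = {}
    summary_rows = []
    for class_name in config.classes:
        with _stage(f"topology[{class_name}]"):
            class_map = extract_class_map(prm, class_name)
            record = global_minkowski(
                class_map, study.mask,
                surface_mode=config.surface_mode, connectivity=config.connectivity,
            )
            tm = local_minkowski_maps(
                class_map, study.mask, config.window(),
                surface_mode=config.surface_mode, connectivity=config.connectivity,
            )
            if config.compute_alpha:
                alpha_descriptor(tm, curves)
                record = global_alpha(record, curves)
            summary = summarize_subject(tm, record, fractions, config.weighting)
            summaries[class_name] = summary
            summary_rows.append(summary.to_row())
        with _stage(f"write_maps[{class_name}]"):
            for metric, grid in tm.maps.items():
                _save_float_map(grid, spacing, out / f"local_{metric}_{class_name}.nii.gz")
            _save_float_map(tm.coverage, spacing, out / f"coverage_{class_name}.nii.gz")
            disp = display_map(tm, "s", mask=study.mask)
            _save_float_map(disp, spacing, out / f"display_s_{class_name}.nii.gz")

    with _stage("write_summary"):
        pd.DataFrame(summary_rows).to_csv(out / "subject_summary.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    return {
        "fractions": fractions,
        "summaries": summaries,
        "files": sorted(p.name for p in out.iterdir()),
    }
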