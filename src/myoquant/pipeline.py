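"""Configured, logged, reproducible runs: simulate → segment → metrics → fit.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
which stages to execute, the scene grid to simulate (condition × dose ×
group × frames), segmentation parameters, metric conventions, and the
model specification for the final fit.  Outputs land in a run
directory together with a manifest recording the configuration, the
seeds, content hashes of the tables written and the package version —
enough to reproduce the run bit-for-bit for the deterministic stages.
A failing stage aborts the run, leaves partial outputs in place and
writes a ``FAILED`` marker into the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import MyoquantError, ValidationError
from .frames import ImageFrame, read_frame
from .glm import ModelSpec, build_design, effect_report, fit_binomial_glm, \
    fit_linear_model, fit_quasipoisson_glm
from .glmm import fit_binomial_glmm
from .metrics import summarise_assay
from .segment import SegmentationConfig, segment_frame, summarise_frame
from .simulate import SceneParams, generate_scene, write_scene

log = logging.getLogger("myoquant")

STAGES = ("simulate", "segment", "metrics", "fit")


@dataclass
class RunConfig:
    """Everything a run needs; see the package docs for the YAML schema."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    scene: dict = field(default_factory=dict)          # SceneParams overrides
    grid: list[dict] = field(default_factory=list)     # condition/dose/group/n_frames
    segmentation: dict = field(default_factory=dict)   # SegmentationConfig overrides
    metrics: dict = field(default_factory=dict)        # myhc_marker, fusion_gate, markers
    model: dict = field(default_factory=dict)          # ModelSpec fields
    input_dir: str | None = None                       # frames on disk when not simulating
    log_level: str = "INFO"
    schema_version: int = 1

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stages: {unknown}")
        if "simulate" in self.stages and not self.grid:
            self.grid = [{"condition": "control", "dose": 0.0,
                          "groups": ["g1"], "n_frames": 1}]
        if "segment" in self.stages and "simulate" not in self.stages \
                and not self.input_dir:
            raise ValidationError(
                "segment stage needs either a simulate stage or input_dir"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(paths, channel_map: dict[str, str] | None = None) -> list[dict]:
    """Check a batch of frame files for shape/channel/metadata consistency.

    Returns a machine-readable issue list (empty when all is well);
    never raises for data problems.
    """
    issues: list[dict] = []
    shapes: dict[tuple, list[str]] = {}
    required = list((channel_map or {"dapi": "dapi", "tubulin": "tubulin"}).values())
    for p in map(Path, paths):
        try:
            frame = read_frame(p)
        except Exception as exc:  # unreadable file is an issue, not a crash
            issues.append({"frame": p.name, "issue": "unreadable", "detail": str(exc)})
            continue
        for ch in required:
            if ch not in frame.channels:
                issues.append(
                    {"frame": p.name, "issue": "missing_channel", "detail": ch}
                )
        for key in ("condition", "frame_id"):
            if key not in frame.metadata:
                issues.append(
                    {"frame": p.name, "issue": "missing_metadata", "detail": key}
                )
        shapes.setdefault(frame.shape, []).append(p.name)
    if len(shapes) > 1:
        ref = max(shapes.items(), key=lambda kv: len(kv[1]))[0]
        for shape, names in shapes.items():
            if shape != ref:
                for name in names:
                    issues.append(
                        {"frame": name, "issue": "shape_mismatch",
                         "detail": f"{shape} != {ref}"}
                    )
    return issues


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    scenes_dir = outdir / "scenes"
    scenes_dir.mkdir(parents=True, exist_ok=True)
    written = []
    counter = 0
    for entry in config.grid:
        groups = entry.get("groups", ["g1"])
        for group in groups:
            for _ in range(int(entry.get("n_frames", 1))):
                scene_seed = int(config.seed) * 10007 + counter
                counter += 1
                params = SceneParams(
                    **{**config.scene, **entry.get("scene", {}),
                       **{k: entry[k] for k in ("condition", "dose") if k in entry},
                       "group": group, "seed": scene_seed % (2**31 - 1)},
                )
                scene = generate_scene(params)
                scene.frame.metadata["frame_id"] = f"frame_{counter:04d}"
                paths = write_scene(scene, scenes_dir)
                written.append({k: str(v) for k, v in paths.items()})
    return {"n_frames": counter, "files": written, "dir": str(scenes_dir)}


def _stage_segment(config: RunConfig, outdir: Path) -> dict:
    src = Path(config.input_dir) if config.input_dir else outdir / "scenes"
    tiffs = sorted(src.glob("*.tif")) + sorted(src.glob("*.tiff"))
    if not tiffs:
        raise ValidationError(f"no TIFF frames found in {src}")
    cells_dir = outdir / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)
    cfg = SegmentationConfig(**config.segmentation)
    tables, frame_rows = [], []
    for p in tiffs:
        frame = read_frame(p)
        seg = segment_frame(frame, cfg)
        summary = summarise_frame(seg, exclude_border=cfg.exclude_border)
        table = seg.to_table()
        table["n_nuclei_total"] = seg.n_nuclei_total
        out_csv = cells_dir / f"{p.stem}_cells.csv"
        table.to_csv(out_csv, index=False)
        tables.append(str(out_csv))
        frame_rows.append(
            {"frame_id": seg.metadata.get("frame_id", p.stem),
             "condition": seg.metadata.get("condition"),
             "dose": seg.metadata.get("dose"),
             "group": seg.metadata.get("group"),
             "n_cells": summary.n_cells, "n_retained": summary.n_retained,
             "mean_eccentricity": summary.mean_eccentricity,
             "n_nuclei_total": seg.n_nuclei_total,
             "n_nuclei_unassigned": seg.n_nuclei_unassigned}
        )
    frames_csv = outdir / "frames.csv"
    pd.DataFrame(frame_rows).to_csv(frames_csv, index=False)
    return {"cell_tables": tables, "frames_csv": str(frames_csv)}


def _stage_metrics(config: RunConfig, outdir: Path) -> dict:
    cells_dir = outdir / "cells"
    tables = sorted(cells_dir.glob("*_cells.csv"))
    if not tables:
        raise ValidationError(f"no cell tables found in {cells_dir}")
    mcfg = config.metrics
    rows = []
    for p in tables:
        cells = pd.read_csv(p)
        total = int(cells["n_nuclei_total"].iat[0]) if "n_nuclei_total" in cells else None
        summ = summarise_assay(
            cells,
            myhc_marker=mcfg.get("myhc_marker", "myhc"),
            fusion_gate=mcfg.get("fusion_gate"),
            markers=mcfg.get("markers", []),
            total_nuclei=total,
        )
        row = {
            "frame_id": summ.frame_id, "condition": summ.condition,
            "dose": summ.dose, "group": summ.group,
        }
        if summ.fusion_index is not None:
            row.update(
                fused=summ.fusion_index.numerator,
                total=summ.fusion_index.denominator,
                fusion_index=summ.fusion_index.ratio,
            )
        for name, cnt in summ.size_class_counts.items():
            row[f"n_{name}"] = cnt
        for m, frac in summ.marker_fractions.items():
            row[f"{m}_positive"] = frac.positive
            row[f"{m}_total"] = frac.total
            row[f"{m}_fraction"] = frac.ratio
        rows.append(row)
    out = outdir / "assay_summary.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return {"assay_summary": str(out), "n_frames": len(rows)}


def _stage_fit(config: RunConfig, outdir: Path) -> dict:
    data = pd.read_csv(outdir / "assay_summary.csv")
    model_cfg = dict(config.model)
    if "response" in model_cfg and isinstance(model_cfg["response"], list):
        model_cfg["response"] = tuple(model_cfg["response"])
    if "interactions" in model_cfg:
        model_cfg["interactions"] = [tuple(i) for i in model_cfg["interactions"]]
    spec = ModelSpec(**model_cfg)
    design = build_design(spec, data)
    mixed = (
        spec.random_intercept is not None
        and design.groups is not None
        and len(pd.unique(design.groups)) >= 2
        and spec.response_kind.startswith("binomial")
    )
    if mixed:
        fit = fit_binomial_glmm(design.X, design.y, design.groups,
                                trials=design.trials)
        extra = {"sigma_g2": fit.sigma2, "method": fit.method}
    elif spec.response_kind.startswith("binomial"):
        fit = fit_binomial_glm(design.X, design.y, design.trials)
        extra = {}
    elif spec.response_kind == "count":
        fit = fit_quasipoisson_glm(design.X, design.y)
        extra = {"dispersion": fit.dispersion}
    else:
        fit = fit_linear_model(design.X, design.y)
        extra = {"residual_variance": fit.dispersion}
    report = effect_report(
        fit, conditions=design.condition_contrasts(),
        omit_intercept_error=bool(config.model.get("omit_intercept_error", False))
        if isinstance(config.model, dict) else False,
        ratios=(fit.link != "identity"),
    )
    report_dir = outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    report.terms.to_csv(report_dir / "terms.csv")
    if report.conditions is not None:
        report.conditions.to_csv(report_dir / "conditions.csv")
    payload = {
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        **extra,
    }
    (report_dir / "fit.json").write_text(json.dumps(payload, indent=2))
    return {"report_dir": str(report_dir), **extra,
            "coefficients": payload["coefficients"]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "metrics": _stage_metrics,
    "fit": _stage_fit,
}


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict.  Any stage error aborts the run with the
    stage name in the exception context; the manifest is still written,
    marked ``FAILED`` at that stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest: dict = {
        "version": __version__, "seed": int(config.seed),
        "config": config.to_dict(), "stages": {},
    }
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s: starting", stage)
            try:
                result = _STAGE_FUNCS[stage](config, outdir)
            except Exception as exc:
                manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
                _write_manifest(manifest, outdir)
                raise MyoquantError(f"stage {stage!r} failed: {exc}") from exc
            manifest["stages"][stage] = {"status": "ok", **result}
            log.info("stage %s: done", stage)
        for key in ("assay_summary.csv", "frames.csv"):
            p = outdir / key
            if p.exists():
                manifest.setdefault("hashes", {})[key] = _sha256(p)
        _write_manifest(manifest, outdir)
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
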