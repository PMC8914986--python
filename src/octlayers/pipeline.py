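"""End-to-end orchestration: phantom → crops → segment → fuse → evaluate.

A single seed drives everything: per-run seeds are derived from it (the
"independent runs" of the evaluation protocol become independent derived
streams, all recorded in the manifest), and each image's phantom seed is
derived from its run seed.  Re-running with the same configuration is
bit-identical at the label/trace level.  When an output directory is given,
every stage's artifacts are persisted (images, COCO annotations, fused label
maps, boundary CSVs, reports) and listed in a manifest together with the
effective configuration and per-stage timings.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import dataio
from .dataio import specific_crop
from .metrics import EvalConfig, EvaluationReport, aggregate_runs, evaluate_report
from .phantom import (
    BoundarySet,
    PhantomSpec,
    boundaries_to_classmap,
    generate_phantom,
    write_boundaries_csv,
)
from .postproc import extract_boundaries, fuse_crops
from .profiles import get_profile
from .segment import (
    InstanceSet,
    OracleBackend,
    PerturbationSpec,
    PerturbedOracleBackend,
    instances_to_labelmap,
    select_instances,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("octlayers.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline execution."""

    profile: str = "retinal7"
    n_images: int = 5
    width: int = 1534
    height: int = 512
    crop_size: int = 512
    backend: str = "oracle"  # oracle | perturbed | an object honouring the contract
    perturbation: PerturbationSpec | None = None
    convention: str = "edge"
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    runs: int = 1
    integer_traces: bool = False
    speckle_level: float = 0.25
    out_dir: str | Path | None = None
    #: optional template overriding the phantom geometry (seed is replaced
    #: per image); width/height/profile must agree with the pipeline fields
    phantom_template: PhantomSpec | None = None

    def phantom_spec(self, seed: int) -> PhantomSpec:
        if self.phantom_template is not None:
            t = self.phantom_template
            if (t.width, t.height, t.profile) != (self.width, self.height, self.profile):
                raise ValueError("phantom_template geometry disagrees with the pipeline config")
            return replace(
                t, seed=seed, integer_traces=self.integer_traces or t.integer_traces
            )
        return PhantomSpec(
            width=self.width,
            height=self.height,
            profile=self.profile,
            seed=seed,
            speckle_level=self.speckle_level,
            integer_traces=self.integer_traces,
        )


@dataclass
class PipelineResult:
    reports: list[EvaluationReport]
    aggregate: dict
    manifest: dict
    out_dir: Path | None


def _derive_seeds(seed: int, n: int) -> list[int]:
    """n child seeds below 2**31 derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _make_backend(cfg: PipelineConfig, run_seed: int):
    if cfg.backend == "oracle":
        return OracleBackend(cfg.profile)
    if cfg.backend == "perturbed":
        pert = cfg.perturbation or PerturbationSpec()
        if cfg.perturbation is None or cfg.perturbation.seed == 0:
            pert = replace(pert, seed=run_seed)
        return PerturbedOracleBackend(cfg.profile, pert)
    if hasattr(cfg.backend, "segment"):
        return cfg.backend
    raise ValueError(
        f"unknown backend {cfg.backend!r}; expected 'oracle', 'perturbed' or an "
        "object with a segment(crop_image, window) method"
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full pipeline; see the module docstring."""
    profile = get_profile(cfg.profile)
    crops = specific_crop(cfg.width, cfg.crop_size)
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    timings: dict[str, float] = {}
    run_seeds = _derive_seeds(cfg.seed, cfg.runs)

    def _record(path: Path) -> None:
        files.append(str(path.relative_to(out_dir)))

    def _tick(stage: str, start: float) -> None:
        timings[stage] = timings.get(stage, 0.0) + (time.perf_counter() - start)

    reports: list[EvaluationReport] = []
    for run_idx, run_seed in enumerate(run_seeds):
        image_seeds = _derive_seeds(run_seed, cfg.n_images)
        backend = _make_backend(cfg, run_seed)
        predictions: dict[str, tuple[np.ndarray, BoundarySet]] = {}
        truth: dict[str, tuple[np.ndarray, BoundarySet]] = {}
        scans, gt_sets, names = [], [], []
        for img_idx, img_seed in enumerate(image_seeds):
            image_id = f"run{run_idx}_img{img_idx:03d}"
            t0 = time.perf_counter()
            try:
                bscan, gt_bounds = generate_phantom(cfg.phantom_spec(img_seed))
                gt_labels = boundaries_to_classmap(gt_bounds, cfg.height)
            except Exception as exc:
                raise RuntimeError(f"stage=phantom image={image_id}: {exc}") from exc
            _tick("phantom", t0)

            t0 = time.perf_counter()
            try:
                if hasattr(backend, "set_ground_truth"):
                    backend.set_ground_truth(gt_labels)
                crop_images = dataio.cut_crops(bscan.pixels, crops)
                label_maps = []
                for crop_img, window in zip(crop_images, crops.windows):
                    inst = backend.segment(crop_img, window)
                    selected, _missing = select_instances(inst, profile)
                    label_maps.append(
                        instances_to_labelmap(selected, profile, cfg.crop_size)
                    )
            except Exception as exc:
                raise RuntimeError(f"stage=segment image={image_id}: {exc}") from exc
            _tick("segment", t0)

            t0 = time.perf_counter()
            try:
                fused = fuse_crops(label_maps, crops)
                pred_bounds = extract_boundaries(fused, profile, cfg.convention)
            except Exception as exc:
                raise RuntimeError(f"stage=postproc image={image_id}: {exc}") from exc
            _tick("postproc", t0)

            predictions[image_id] = (fused.labels, pred_bounds)
            truth[image_id] = (gt_labels, gt_bounds)
            scans.append(bscan)
            gt_sets.append(gt_bounds)
            names.append(f"{image_id}.png")

            if out_dir is not None:
                t0 = time.perf_counter()
                _record(dataio.save_bscan(bscan, out_dir / f"{image_id}.png"))
                _record(dataio.save_labelmap(fused.labels, out_dir / f"{image_id}_fused.png"))
                gt_csv = out_dir / f"{image_id}_gt_boundaries.csv"
                write_boundaries_csv(gt_bounds, gt_csv)
                _record(gt_csv)
                pred_csv = out_dir / f"{image_id}_pred_boundaries.csv"
                write_boundaries_csv(pred_bounds, pred_csv)
                _record(pred_csv)
                _tick("io", t0)

        t0 = time.perf_counter()
        try:
            report = evaluate_report(predictions, truth, profile, cfg.eval_config)
        except Exception as exc:
            raise RuntimeError(f"stage=evaluate run={run_idx}: {exc}") from exc
        _tick("evaluate", t0)
        reports.append(report)
        log.info(
            "run %d: overall Dice %.2f%%, boundary MAE %.3f px",
            run_idx,
            report.aggregate["dice_overall"],
            report.aggregate["boundary_mean_absolute"],
        )

        if out_dir is not None:
            t0 = time.perf_counter()
            coco_path = out_dir / f"annotations_run{run_idx}.json"
            dataio.write_coco(scans, gt_sets, coco_path, file_names=names)
            _record(coco_path)
            report_path = out_dir / f"report_run{run_idx}.json"
            report.to_json(report_path)
            _record(report_path)
            _tick("io", t0)

    aggregate: dict = {"runs": cfg.runs, "run_seeds": run_seeds}
    for key in ("dice_overall", "boundary_mean_absolute", "boundary_mean_signed"):
        values = [r.aggregate[key] for r in reports]
        if len(values) >= 2:
            agg = aggregate_runs(values)
            aggregate[key] = {"mean": agg.mean, "sd": agg.sd, "n": agg.n}
        else:
            aggregate[key] = {"mean": values[0], "sd": None, "n": 1}

    manifest = {
        "config": _config_dict(cfg),
        "run_seeds": run_seeds,
        "crops": [
            {"offset": w.offset, "size": w.size, "role": w.role, "index": w.index}
            for w in crops.windows
        ],
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "files": sorted(files),
        "aggregate": aggregate,
    }
    if out_dir is not None:
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        manifest["files"] = sorted(files + ["manifest.json"])
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        reports=reports, aggregate=aggregate, manifest=manifest, out_dir=out_dir
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["out_dir"] = str(cfg.out_dir) if cfg.out_dir is not None else None
    if not isinstance(cfg.backend, str):
        d["backend"] = f"external:{type(cfg.backend).__name__}"
    return d
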