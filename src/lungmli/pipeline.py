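"""End-to-end run configuration and the full analysis pipeline.

One :class:`RunConfig` captures everything a run needs — cohort layout,
annotation settings, training recipe, line-intercept settings, method
selection — so any result table is regenerable from (config, seed) alone.

``run_pipeline`` executes: synthetic cohort generation -> classical
annotation (and, when requested, CNN training + prediction) -> per-image
mean linear intercept -> group statistics, and writes tidy CSV outputs plus
a JSON run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classical import MorphologyConfig, annotate, to_grayscale
from .metrics import compare_methods, cross_test, summarize, t_test
from .mli import DEFAULT_GUARD_GAP, compute_mli
from .model import SplitSpec, TrainConfig, build_model, predict_image, split_dataset, train
from .synthetic import ParenchymaSpec, control_spec, generate_cohort, smoker_spec

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("lungmli")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable description of a full analysis run."""

    seed: int = 0
    method: str = "classical"  # classical | dl | both
    n_mice: int = 3
    images_per_mouse: int = 12
    image_size: int = 128
    lumen_scale_control: float = 24.0
    lumen_scale_smoker: float = 36.0
    noise_sd: float = 8.0
    wall_thickness: float = 4.0
    n_lines: int = 10
    guard_gap: int = DEFAULT_GUARD_GAP
    pixel_size: float | None = None
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "morphology" in raw and isinstance(raw["morphology"], dict):
            m = dict(raw["morphology"])
            if "step_sequence" in m:
                m["step_sequence"] = tuple(m["step_sequence"])
            raw["morphology"] = MorphologyConfig(**m)
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = TrainConfig(**raw["training"])
        if "split" in raw and isinstance(raw["split"], dict):
            raw["split"] = SplitSpec(**raw["split"])
        return cls(**raw)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def _cohort_specs(config: RunConfig) -> tuple[ParenchymaSpec, ParenchymaSpec]:
    common = dict(
        width=config.image_size,
        height=config.image_size,
        noise_sd=config.noise_sd,
        wall_thickness=config.wall_thickness,
    )
    ctrl = control_spec(lumen_scale=config.lumen_scale_control, **common)
    smk = smoker_spec(lumen_scale=config.lumen_scale_smoker, **common)
    return ctrl, smk


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis end to end.

    Returns a results bundle with the per-image Lm table (one row per image
    and method), group statistics, method comparison, within-group
    cross-tests, segmentation metrics for the learned model (when trained),
    and the run log.  When ``config.out_dir`` is set, the tables are also
    written as CSV and the log as JSON.
    """
    t0 = time.time()
    if config.method not in ("classical", "dl", "both"):
        raise PipelineError(f"unknown method {config.method!r}")
    ctrl, smk = _cohort_specs(config)
    cohort = _stage("simulate")(
        generate_cohort,
        control=ctrl,
        smoker=smk,
        n_mice=config.n_mice,
        images_per_mouse=config.images_per_mouse,
        seed=config.seed,
    )
    logger.info("generated cohort of %d samples", len(cohort))

    annotations = _stage("annotate")(
        lambda: [annotate(s.image, config.morphology) for s in cohort]
    )

    methods: dict[str, list[np.ndarray]] = {}
    seg_metrics = None
    history = None
    if config.method in ("classical", "both"):
        methods["classical"] = annotations
    if config.method in ("dl", "both"):
        tr_cfg = dataclasses.replace(
            config.training,
            patch_size=min(config.training.patch_size, config.image_size),
            stride=min(config.training.stride, max(1, config.image_size // 2)),
            seed=config.seed,
        )
        split = dataclasses.replace(config.split, seed=config.seed)
        idx_train, idx_val, idx_test = _stage("split")(split_dataset, cohort, split)

        def _pairs(idx):
            from .patchwork import extract_patches

            pairs = []
            for i in idx:
                gray = to_grayscale(cohort[i].image).astype(np.float32) / 255.0
                img_ps = extract_patches(gray, tr_cfg.patch_size, tr_cfg.stride)
                lbl_ps = extract_patches(
                    annotations[i].astype(np.float32), tr_cfg.patch_size, tr_cfg.stride
                )
                pairs.extend(
                    (it, lt) for (it, _, _), (lt, _, _) in zip(img_ps.patches, lbl_ps.patches)
                )
            return pairs

        model = _stage("build_model")(build_model, tr_cfg)
        model, history = _stage("train")(
            train, model, _pairs(idx_train), _pairs(idx_val), tr_cfg
        )
        predictions = _stage("segment")(
            lambda: [predict_image(model, s.image, tr_cfg) for s in cohort]
        )
        methods["dl"] = predictions
        seg_metrics = summarize(
            [(predictions[i], cohort[i].truth_mask) for i in idx_test]
        )

    rows = []
    for method, masks in methods.items():
        for s, mask in zip(cohort, masks):
            res = _stage("mli")(
                compute_mli,
                mask,
                n_lines=config.n_lines,
                guard_gap=config.guard_gap,
                pixel_size=config.pixel_size,
            )
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "mouse_id": s.mouse_id,
                    "method": method,
                    "l": res.l,
                    "n": res.n,
                    "Lm": res.Lm,
                }
            )
    per_image = pd.DataFrame(rows)

    comparisons, comparison_table = _stage("compare_groups")(
        compare_methods, per_image
    )
    cross_tables = {}
    for method in methods:
        sub = per_image[per_image["method"] == method]
        for group in sorted(sub["group"].unique()):
            g = sub[sub["group"] == group]
            values = {m: v["Lm"].tolist() for m, v in g.groupby("mouse_id")}
            cross_tables[(method, group)] = _stage("cross_test")(cross_test, values)

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "method": config.method,
        "config": _as_plain(config),
        "n_samples": len(cohort),
        "elapsed_s": round(time.time() - t0, 3),
    }
    bundle = {
        "cohort": cohort,
        "per_image": per_image,
        "comparisons": comparisons,
        "comparison_table": comparison_table,
        "cross_tables": cross_tables,
        "seg_metrics": seg_metrics,
        "history": history,
        "run_log": run_log,
    }
    if config.out_dir:
        _write_outputs(bundle, config)
    return bundle


def _write_outputs(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["per_image"].to_csv(out / "mli_per_image.csv", index=False)
    bundle["comparison_table"].to_csv(out / "group_comparison.csv", index=False)
    cross = []
    for (method, group), table in bundle["cross_tables"].items():
        t = table.copy()
        t.insert(0, "method", method)
        t.insert(1, "group", group)
        cross.append(t)
    if cross:
        pd.concat(cross, ignore_index=True).to_csv(out / "cross_tests.csv", index=False)
    if bundle["history"] is not None:
        pd.DataFrame(bundle["history"]).to_csv(out / "training_history.csv", index=False)
    if bundle["seg_metrics"] is not None:
        pd.DataFrame([dataclasses.asdict(bundle["seg_metrics"])]).to_csv(
            out / "segmentation_metrics.csv", index=False
        )
    (out / "run_log.json").write_text(json.dumps(bundle["run_log"], indent=2))
    logger.info("wrote outputs to %s", out)
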