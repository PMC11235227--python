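"""Config-driven experiment pipeline: synthesise → fuse → features → MIL → report.

One :class:`ExperimentConfig` drives every stage; stage seeds are derived
from the global seed by stable hashing so each stage is independently
reproducible.  A manifest records per-stage config hashes; re-running skips
stages whose hash and outputs are unchanged unless forced, and a changed
stage invalidates its descendants.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import fusion, synthetic
from .evaluation import report_from_predictions
from .features import handcrafted_features
from .io import load_stack, save_stack
from .mil import ModelConfig, cross_validate
from .visualisation import attention_overlay

STAGES = ("slides", "fusion", "features", "bags", "mil", "evaluate", "visualise")


@dataclass
class ExperimentConfig:
    """All stage configurations plus the global seed and output directory."""

    out_dir: str = "experiment"
    seed: int = 0
    stain_profile: str = "PAS"
    n_slides: int = 2
    slide: synthetic.SlideConfig = field(default_factory=synthetic.SlideConfig)
    n_models: int = 4
    disagreement: float = 0.15
    n_false_positives: int = 1
    penalty_A: float = 1.0
    min_area_px: int = 32
    smoothness: float = 1.0
    pad_um: float = 1.32
    blur_sigma_px: float = 8.0
    bags: synthetic.BagSetConfig = field(default_factory=synthetic.BagSetConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_folds: int = 5
    n_seeds: int = 2

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "slide" in d and isinstance(d["slide"], dict):
            d["slide"] = synthetic.SlideConfig(
                **{**d["slide"], **_tupleize(synthetic.SlideConfig, d["slide"])}
            )
        if "bags" in d and isinstance(d["bags"], dict):
            d["bags"] = synthetic.BagSetConfig(
                **{**d["bags"], **_tupleize(synthetic.BagSetConfig, d["bags"])}
            )
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)


def _tupleize(cls, d: dict) -> dict:
    """YAML round-trips tuples as lists; restore tuple-typed fields."""
    out = {}
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            out[f.name] = tuple(d[f.name])
    return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _hash_config(obj: Any) -> str:
    return f"{zlib.crc32(json.dumps(obj, sort_keys=True, default=str).encode()):08x}"


def _stage_config(config: ExperimentConfig, stage: str) -> dict:
    d = config.to_dict()
    keys = {
        "slides": ["n_slides", "slide", "n_models", "disagreement", "n_false_positives", "seed"],
        "fusion": ["penalty_A", "min_area_px", "smoothness", "pad_um", "blur_sigma_px"],
        "features": ["stain_profile"],
        "bags": ["bags"],
        "mil": ["model", "n_folds", "n_seeds"],
        "evaluate": [],
        "visualise": [],
    }[stage]
    return {k: d[k] for k in keys}


def run_pipeline(config: ExperimentConfig, force: bool = False) -> Path:
    """Execute all stages in dependency order; returns the experiment dir.

    Stage outputs land under ``out_dir``; ``manifest.json`` records config
    hashes and seeds.  Unchanged completed stages are skipped unless
    ``force``; a changed stage re-runs together with all downstream stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    invalidated = False
    executed = []

    for stage in STAGES:
        cfg = _stage_config(config, stage)
        h = _hash_config(cfg)
        done = manifest.get(stage, {})
        outputs = [out / p for p in done.get("outputs", [])]
        fresh = done.get("config_hash") == h and all(p.exists() for p in outputs)
        if fresh and not force and not invalidated:
            continue
        invalidated = True
        produced = _run_stage(stage, config, out)
        manifest[stage] = {
            "config_hash": h,
            "seed": stage_seed(config.seed, stage),
            "outputs": [str(Path(p).relative_to(out)) for p in produced],
        }
        executed.append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["_last_run_stages"] = executed
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def _run_stage(stage: str, config: ExperimentConfig, out: Path) -> list[Path]:
    import imageio.v3 as iio

    produced: list[Path] = []
    if stage == "slides":
        sdir = out / "slides"
        sdir.mkdir(exist_ok=True)
        seed = stage_seed(config.seed, "slides")
        for i in range(config.n_slides):
            slide = synthetic.make_slide(config.slide, seed=seed + i)
            stack = synthetic.make_probability_stack(
                slide,
                n_models=config.n_models,
                disagreement=config.disagreement,
                seed=seed + 1000 + i,
                n_false_positives=config.n_false_positives,
            )
            iio.imwrite(sdir / f"slide_{i}.png", slide.image)
            (sdir / f"slide_{i}.json").write_text(
                json.dumps(synthetic.slide_manifest(slide))
            )
            save_stack(stack, sdir / f"stack_{i}.npz")
            produced += [sdir / f"slide_{i}.png", sdir / f"slide_{i}.json", sdir / f"stack_{i}.npz"]
    elif stage == "fusion":
        fdir = out / "fusion"
        fdir.mkdir(exist_ok=True)
        for i in range(config.n_slides):
            stack = load_stack(out / "slides" / f"stack_{i}.npz")
            fused = fusion.fuse_ensemble(stack, config.penalty_A)
            image = iio.imread(out / "slides" / f"slide_{i}.png")
            records = []
            for cname in ("tubule", "glomerulus", "vessel"):
                insts = fusion.extract_instances(
                    fused, cname, config.min_area_px, config.smoothness
                )
                if not insts:
                    continue
                ci = fused.class_index(cname)
                fusion.compute_quality_weights(insts, fused.p_sigma[ci])
                for inst in insts:
                    fusion.crop_instance(
                        image, inst, config.pad_um, stack.mpp, config.blur_sigma_px
                    )
                records += fusion.instances_to_records(insts)
                for inst in insts:
                    iio.imwrite(
                        fdir / f"slide{i}_{cname}_{inst.instance_id}.png", inst.crop
                    )
            (fdir / f"instances_{i}.json").write_text(json.dumps(records))
            produced.append(fdir / f"instances_{i}.json")
    elif stage == "features":
        rows = []
        for i in range(config.n_slides):
            stack = load_stack(out / "slides" / f"stack_{i}.npz")
            mpp = stack.mpp
            fused = fusion.fuse_ensemble(stack, config.penalty_A)
            image = iio.imread(out / "slides" / f"slide_{i}.png")
            all_insts = []
            for cname in ("tubule", "glomerulus", "vessel"):
                insts = fusion.extract_instances(
                    fused, cname, config.min_area_px, config.smoothness
                )
                if not insts:
                    continue
                ci = fused.class_index(cname)
                fusion.compute_quality_weights(insts, fused.p_sigma[ci])
                all_insts += insts
            total_area = sum(inst.area_px for inst in all_insts) * mpp**2
            for k, inst in enumerate(all_insts):
                fusion.crop_instance(image, inst, config.pad_um, mpp, config.blur_sigma_px)
                r0, c0, r1, c1 = inst.bbox
                rec = handcrafted_features(
                    inst.crop,
                    inst.mask[r0:r1, c0:c1],
                    slide_context=(total_area, len(all_insts)),
                    mpp=mpp,
                    stain_profile=config.stain_profile,
                )
                rec["slide"] = i
                rec["instance"] = k
                rec["class_label"] = inst.class_label
                rec["g"] = inst.g
                rows.append(rec)
        df = pd.DataFrame(rows)
        df.to_csv(out / "features.csv", index=False)
        produced.append(out / "features.csv")
    elif stage == "bags":
        cfg = dataclasses.replace(config.bags, seed=stage_seed(config.seed, "bags"))
        bagset = synthetic.make_bags(cfg)
        for b in bagset:
            b.g = fusion.quality_weights_from_s2(b.sigma2)
        inst_df, bag_df = bagset.to_frames()
        inst_df.to_csv(out / "instances.csv", index=False)
        bag_df.to_csv(out / "bags.csv", index=False)
        produced += [out / "instances.csv", out / "bags.csv"]
    elif stage == "mil":
        from .containers import BagSet

        bagset = BagSet.from_frames(
            pd.read_csv(out / "instances.csv"), pd.read_csv(out / "bags.csv")
        )
        mcfg = dataclasses.replace(
            config.model, n_features=config.bags.n_features, n_classes=config.bags.n_classes
        )
        cv = cross_validate(
            bagset,
            mcfg,
            n_folds=config.n_folds,
            n_seeds=config.n_seeds,
            seed=stage_seed(config.seed, "mil"),
        )
        cv.predictions.to_csv(out / "predictions.csv", index=False)
        produced.append(out / "predictions.csv")
    elif stage == "evaluate":
        preds = pd.read_csv(out / "predictions.csv")
        report = report_from_predictions({"synthetic_bags": preds})
        (out / "report.json").write_text(
            json.dumps(
                {
                    "per_task": report.per_task.to_dict(orient="records"),
                    "roc_auc_pooled": report.roc_auc_pooled,
                    "roc_auc_pooled_se": report.roc_auc_pooled_se,
                    "pr_auc_pooled": report.pr_auc_pooled,
                    "pr_auc_pooled_se": report.pr_auc_pooled_se,
                },
                indent=2,
            )
        )
        produced.append(out / "report.json")
    elif stage == "visualise":
        # colour the first slide's instances by their quality weight g
        # (normalised to sum 1), demonstrating the boundary-confined overlay
        fused = fusion.fuse_ensemble(
            load_stack(out / "slides" / "stack_0.npz"), config.penalty_A
        )
        image = iio.imread(out / "slides" / "slide_0.png")
        insts = []
        for cname in ("tubule", "glomerulus", "vessel"):
            found = fusion.extract_instances(
                fused, cname, config.min_area_px, config.smoothness
            )
            if found:
                ci = fused.class_index(cname)
                fusion.compute_quality_weights(found, fused.p_sigma[ci])
                insts += found
        if insts:
            g = np.array([inst.g for inst in insts], dtype=float)
            weights = g / g.sum() if g.sum() > 0 else np.full(len(g), 1.0 / len(g))
            fig = attention_overlay(image, insts, weights)
            fig.save(out / "overlay_quality.png")
            produced.append(out / "overlay_quality.png")
    return produced
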