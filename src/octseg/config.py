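"""Run configuration and the end-to-end pipeline.

One YAML (or JSON) file resolves every stage's parameters; unset values take
the defaults used on the real cohort: common dimension 526 x 975, patches of
width 75, inference slices of width 512, Savitzky-Golay window 449 of order
1, opening fraction 0.3, f_c = 0.007 with P = 4 descriptors, K = 9 patient
folds, batch size 4, momentum 0.97, initial learning rate 0.001 dropped 10x
every 20 epochs, 60 epochs.  All randomness fans out deterministically from
one root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import octio
from .octio import (OCTImage, LabelMask, rescale_to_common, extract_patches,
                    load_image, load_mask, read_manifest, save_mask,
                    save_probability_map)
from .phantoms import PhantomSpec, generate_cohort, write_cohort
from .network import NetworkConfig, ModelState, train
from .crossval import FoldPlan, make_folds, ensemble_predict, argmax_labels
from .postproc import PostprocConfig, SGFilterSpec, refine_mask, sidecar_dict
from . import metrics as M

log = logging.getLogger("octseg")


@dataclass
class RunConfig:
    out_dir: str = "octseg_run"
    manifest: str | None = None
    seed: int = 0
    K: int = 9
    common_dim: tuple[int, int] | None = None    # None: keep native size
    patch_width: int = octio.PATCH_WIDTH
    slice_width: int = octio.SLICE_WIDTH
    axial_pixel_um: float = 1.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    sg_window: int = 449
    sg_order: int = 1
    opening_fraction: float = 0.3
    f_c: float = 0.007
    fixed_p: int | None = 4
    baseline_correction: str = "shallow_align"
    # phantom simulation (used when no manifest is given)
    simulate_patients: int = 2
    simulate_images_per_patient: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def postproc_config(self) -> PostprocConfig:
        return PostprocConfig(
            sg=SGFilterSpec(window=self.sg_window, order=self.sg_order),
            opening_fraction=self.opening_fraction,
            f_c=self.f_c, fixed_p=self.fixed_p,
            baseline_correction=self.baseline_correction)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "network" in kwargs:
            net = dict(kwargs["network"])
            if "kernel_shape" in net:
                net["kernel_shape"] = tuple(net["kernel_shape"])
            kwargs["network"] = NetworkConfig(**net)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**kwargs["phantom"])
        if kwargs.get("common_dim") is not None:
            kwargs["common_dim"] = tuple(kwargs["common_dim"])
        return cls(**kwargs)

    def snapshot(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _load_dataset(config: RunConfig) -> list[tuple[str, OCTImage, LabelMask]]:
    if config.manifest is None:
        raise FileNotFoundError("no manifest configured; run simulate first")
    if not Path(config.manifest).exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest}")
    data = []
    for pid, ipath, mpath in read_manifest(config.manifest):
        img = load_image(ipath, axial_pixel_um=config.axial_pixel_um)
        mask = load_mask(mpath)
        if config.common_dim is not None:
            img, mask = rescale_to_common(img, mask, config.common_dim)
        data.append((pid, img, mask))
    return data


def simulate_stage(config: RunConfig, out_dir: Path) -> Path:
    """Generate a phantom cohort and point the config at its manifest."""
    records = generate_cohort(config.simulate_patients,
                              config.simulate_images_per_patient,
                              config.phantom, seed=config.seed)
    manifest = write_cohort(records, out_dir / "cohort")
    config.manifest = str(manifest)
    log.info("simulated %d images -> %s", len(records), manifest)
    return manifest


def train_stage(config: RunConfig, out_dir: Path,
                dataset=None) -> tuple[FoldPlan, dict]:
    """Train the K*(K-1) patient-wise cross-validation models."""
    dataset = dataset or _load_dataset(config)
    plan = make_folds([pid for pid, _, _ in dataset], config.K)
    plan.to_json(out_dir / "fold_plan.json")
    by_patient: dict[str, list] = {}
    for pid, img, mask in dataset:
        by_patient.setdefault(pid, []).append((img, mask))

    def patches_of(pids):
        out = []
        for p in pids:
            for img, mask in by_patient[p]:
                out.extend(extract_patches(img, mask, config.patch_width))
        return out

    models: dict[str, list[ModelState]] = {}
    mdir = out_dir / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    for ti, (test, splits) in enumerate(plan.external.items()):
        models[test] = []
        for k, split in enumerate(splits):
            net_cfg = dataclasses.replace(
                config.network, seed=config.seed + 1009 * ti + 101 * k)
            ms = train(patches_of(split.train_patients),
                       patches_of([split.val_patient]), net_cfg,
                       log_path=mdir / f"log_{test}_{k}.csv")
            ms.save(mdir / f"model_{test}_{k}.pkl")
            models[test].append(ms)
            log.info("trained model test=%s val=%s best_epoch=%d",
                     test, split.val_patient, ms.best_epoch)
    return plan, models


def predict_stage(config: RunConfig, out_dir: Path, models: dict,
                  dataset=None) -> list[tuple[str, str, LabelMask, LabelMask]]:
    """Ensemble-predict every scan of every test patient."""
    dataset = dataset or _load_dataset(config)
    pdir = out_dir / "predictions"
    pdir.mkdir(parents=True, exist_ok=True)
    results = []
    counters: dict[str, int] = {}
    for pid, img, gt in dataset:
        i = counters.get(pid, 0)
        counters[pid] = i + 1
        name = f"{pid}_{i:03d}"
        pmap = ensemble_predict(models[pid], img, config.slice_width)
        pred = argmax_labels(pmap)
        save_probability_map(pmap, pdir / f"{name}_probs.tiff")
        save_mask(pred, pdir / f"{name}_pred.png")
        results.append((pid, name, pred, gt))
    return results


def postprocess_stage(config: RunConfig, out_dir: Path, predictions):
    """Refine every predicted mask; returns refined predictions and GT info."""
    ppcfg = config.postproc_config()
    rdir = out_dir / "refined"
    rdir.mkdir(parents=True, exist_ok=True)
    refined = []
    for pid, name, pred, gt in predictions:
        final, follicles, profile = refine_mask(pred, ppcfg)
        save_mask(final, rdir / f"{name}_refined.png")
        (rdir / f"{name}_sidecar.json").write_text(
            json.dumps(sidecar_dict(follicles, profile, ppcfg)))
        refined.append((pid, name, final, follicles, profile, gt))
    return refined


def evaluate_stage(config: RunConfig, out_dir: Path, refined) -> M.MetricsReport:
    """Dice/Jaccard, ET, RMSE/MAE and follicle RSR against the ground truth."""
    ppcfg = config.postproc_config()
    rows = []
    counts: dict[str, list[tuple[int, int]]] = {}
    for pid, name, final, follicles, profile, gt in refined:
        _, gt_follicles, gt_profile = refine_mask(gt, ppcfg)
        et_pred = M.epidermal_thickness(profile, config.axial_pixel_um)
        et_gt = M.epidermal_thickness(gt_profile, config.axial_pixel_um)
        rows.append({
            "patient_id": pid, "image": name,
            "dice_epidermis": M.dice(final, gt, 1),
            "dice_dermis": M.dice(final, gt, 2),
            "jaccard_epidermis": M.jaccard(final, gt, 1),
            "jaccard_dermis": M.jaccard(final, gt, 2),
            "et_gt_um": et_gt, "et_pred_um": et_pred,
        })
        counts.setdefault(pid, []).append((len(gt_follicles), len(follicles)))
    fc_rows = []
    for pid, pairs in counts.items():
        f_gt = int(round(np.mean([a for a, _ in pairs])))
        f_p = int(round(np.mean([b for _, b in pairs])))
        fc_rows.append({"patient_id": pid, "f_gt": max(f_gt, 1), "f_p": f_p})
    report = M.aggregate_report(pd.DataFrame(rows), pd.DataFrame(fc_rows))
    report.write(out_dir / "metrics")
    return report


def run_pipeline(config: RunConfig) -> M.MetricsReport:
    """simulate (if needed) -> folds -> train -> predict -> refine -> evaluate."""
    if config.manifest is not None and not Path(config.manifest).exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.snapshot(out / "config_snapshot.yaml")
    if config.manifest is None:
        simulate_stage(config, out)
    dataset = _load_dataset(config)
    plan, models = train_stage(config, out, dataset)
    predictions = predict_stage(config, out, models, dataset)
    refined = postprocess_stage(config, out, predictions)
    report = evaluate_stage(config, out, refined)
    log.info("cohort summary: %s", report.cohort)
    return report
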