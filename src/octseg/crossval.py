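"""Patient-wise external K-fold with internal leave-one-fold-out validation.

With K patient folds, each external test fold i trains K-1 models, one per
internal validation fold j != i (train on the remaining K-2 folds), giving
K*(K-1) models overall.  The test patient's scans are predicted by averaging
the K-1 per-model probability maps before the final per-pixel argmax, so no
model ever sees its test patient during training or validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .octio import OCTImage, LabelMask, ProbabilityMap, split_for_inference, \
    recombine_slices, SLICE_WIDTH
from .network.model import ModelState, OCTNet


@dataclass(frozen=True)
class InternalSplit:
    val_patient: str
    train_patients: tuple[str, ...]


@dataclass(frozen=True)
class FoldPlan:
    patients: tuple[str, ...]
    # external test patient -> list of internal (train, val) assignments
    external: dict[str, list[InternalSplit]]

    @property
    def n_models(self) -> int:
        return sum(len(v) for v in self.external.values())

    def to_json(self, path: str | Path) -> None:
        d = {test: [{"val": s.val_patient, "train": list(s.train_patients)}
                    for s in splits]
             for test, splits in self.external.items()}
        Path(path).write_text(json.dumps(
            {"patients": list(self.patients), "external": d}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        ext = {test: [InternalSplit(s["val"], tuple(s["train"]))
                      for s in splits]
               for test, splits in d["external"].items()}
        return cls(patients=tuple(d["patients"]), external=ext)


def make_folds(patient_ids: list[str], K: int | None = None) -> FoldPlan:
    """One fold per patient (or the first K distinct patients, sorted)."""
    patients = sorted(set(patient_ids))
    if K is None:
        K = len(patients)
    if len(patients) < K:
        raise ValueError(f"{len(patients)} patients < K={K}")
    if K < 2:
        raise ValueError("K must be >= 2")
    patients = patients[:K]
    external: dict[str, list[InternalSplit]] = {}
    for test in patients:
        rest = [p for p in patients if p != test]
        splits = []
        for val in rest:
            train = tuple(p for p in rest if p != val)
            # K=2 degenerate case: the single other patient is both the
            # training and the validation fold
            splits.append(InternalSplit(val_patient=val,
                                        train_patients=train or (val,)))
        external[test] = splits
    return FoldPlan(patients=tuple(patients), external=external)


def _model_probability_map(model: ModelState | OCTNet, image: OCTImage,
                           slice_width: int) -> ProbabilityMap:
    net = model.build() if isinstance(model, ModelState) else model
    w = image.shape[1]
    sw = min(slice_width, w)
    parts = []
    for pixels, off in split_for_inference(image, sw):
        probs = net.forward(pixels[None, None], training=False)[0]
        parts.append((ProbabilityMap(probs=probs), off))
    return recombine_slices(parts, w)


def ensemble_predict(models: list[ModelState | OCTNet], image: OCTImage,
                     slice_width: int = SLICE_WIDTH) -> ProbabilityMap:
    """Mean of the per-model probability maps (tiled inference per model)."""
    if not models:
        raise ValueError("empty model list")
    acc = None
    for m in models:
        pm = _model_probability_map(m, image, slice_width)
        acc = pm.probs if acc is None else acc + pm.probs
    return ProbabilityMap(probs=acc / len(models))


def argmax_labels(prob: ProbabilityMap) -> LabelMask:
    """Per-pixel most probable class; ties go to the lowest class index."""
    return LabelMask(labels=np.argmax(prob.probs, axis=0).astype(np.uint8))
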