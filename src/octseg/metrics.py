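"""Evaluation: Dice/Jaccard, follicle counting and relative success rate,
epidermal thickness with RMSE/MAE, and per-patient / cohort aggregation.

Epidermal thickness (ET) is the mean surface-to-DEJ distance over columns
that do not intersect a detected follicle, converted to micrometres with the
axial pixel pitch; per-patient RMSE and MAE compare the per-image ET series
of prediction and ground truth.  The relative success rate for follicle
counts is RSR = 1 - |F_GT - F_P| / F_GT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .octio import LabelMask, BoundaryProfile
from .postproc import PostprocConfig, refine_mask


def _layer_sets(a: LabelMask, b: LabelMask, layer: int):
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return a.labels == layer, b.labels == layer


def dice(a: LabelMask, b: LabelMask, layer: int) -> float:
    """2|A n B| / (|A| + |B|) on one layer; both empty -> 1 (vacuous match)."""
    A, B = _layer_sets(a, b, layer)
    denom = A.sum() + B.sum()
    return 1.0 if denom == 0 else float(2.0 * np.logical_and(A, B).sum() / denom)


def jaccard(a: LabelMask, b: LabelMask, layer: int) -> float:
    """|A n B| / |A u B| on one layer; both empty -> 1 (vacuous match)."""
    A, B = _layer_sets(a, b, layer)
    union = np.logical_or(A, B).sum()
    return 1.0 if union == 0 else float(np.logical_and(A, B).sum() / union)


def count_follicles(mask: LabelMask, config: PostprocConfig | None = None) -> int:
    """Follicles surviving the baseline split and area opening on a mask."""
    _, follicles, _ = refine_mask(mask, config)
    return len(follicles)


def rsr(f_gt: int, f_p: int) -> float:
    """Relative success rate 1 - |F_GT - F_P| / F_GT of follicle counts."""
    if f_gt < 1:
        raise ValueError("RSR undefined for F_GT = 0")
    if f_p < 0:
        raise ValueError("F_P must be non-negative")
    return 1.0 - abs(f_gt - f_p) / f_gt


def epidermal_thickness(profile: BoundaryProfile,
                        axial_pixel_um: float = 1.0) -> float:
    """Mean (s_dej - surface) over valid non-follicle columns, in um.

    Follicle columns (those intersecting a surviving component, recorded in
    the profile) are excluded so the thin epidermis is measured, the relevant
    quantity for thinning disorders.
    """
    if axial_pixel_um <= 0:
        raise ValueError("axial_pixel_um must be positive")
    w = profile.s_dej.size
    use = profile.valid.copy()
    fc = profile.follicle_columns
    if fc.size:
        use[fc[(fc >= 0) & (fc < w)]] = False
    if not use.any():
        raise ValueError("no valid non-follicle columns for thickness")
    return float((profile.s_dej[use] - profile.surface[use]).mean()
                 * axial_pixel_um)


def thickness_errors(G: np.ndarray, P: np.ndarray) -> tuple[float, float]:
    """(RMSE, MAE) between per-image thickness series G and P."""
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    if G.shape != P.shape or G.ndim != 1 or G.size == 0:
        raise ValueError("G and P must be equal-length non-empty vectors")
    d = G - P
    return float(np.sqrt((d ** 2).mean())), float(np.abs(d).mean())


@dataclass
class MetricsReport:
    """Per-image table, per-patient table and cohort summary."""

    per_image: pd.DataFrame
    per_patient: pd.DataFrame
    cohort: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(out / "per_image.csv", index=False)
        self.per_patient.to_csv(out / "per_patient.csv", index=False)
        (out / "cohort.json").write_text(json.dumps(self.cohort, indent=1))


def aggregate_report(per_image: pd.DataFrame,
                     follicle_counts: pd.DataFrame | None = None) -> MetricsReport:
    """Aggregate per-image metrics into per-patient rows and a cohort summary.

    ``per_image`` needs columns patient_id, dice_epidermis, dice_dermis,
    jaccard_epidermis, jaccard_dermis, et_gt_um, et_pred_um.
    ``follicle_counts`` (optional) has one row per patient: patient_id,
    f_gt, f_p.  Cohort RSR/RMSE/MAE are unweighted means over patients.
    """
    rows = []
    for pid, g in per_image.groupby("patient_id", sort=True):
        rmse, mae = thickness_errors(g["et_gt_um"].to_numpy(),
                                     g["et_pred_um"].to_numpy())
        rows.append({
            "patient_id": pid,
            "n_images": len(g),
            "dice_epidermis": g["dice_epidermis"].mean(),
            "dice_dermis": g["dice_dermis"].mean(),
            "jaccard_epidermis": g["jaccard_epidermis"].mean(),
            "jaccard_dermis": g["jaccard_dermis"].mean(),
            "et_gt_um": g["et_gt_um"].mean(),
            "et_gt_sd_um": g["et_gt_um"].std(ddof=1) if len(g) > 1 else 0.0,
            "et_pred_um": g["et_pred_um"].mean(),
            "et_pred_sd_um": g["et_pred_um"].std(ddof=1) if len(g) > 1 else 0.0,
            "rmse_um": rmse,
            "mae_um": mae,
        })
    per_patient = pd.DataFrame(rows)
    if follicle_counts is not None:
        fc = follicle_counts.copy()
        fc["rsr"] = [rsr(int(a), int(b))
                     for a, b in zip(fc["f_gt"], fc["f_p"])]
        per_patient = per_patient.merge(fc, on="patient_id", how="left")
    cohort = {
        "dice_epidermis": float(per_image["dice_epidermis"].mean()),
        "dice_epidermis_sd": float(per_image["dice_epidermis"].std(ddof=1))
        if len(per_image) > 1 else 0.0,
        "dice_dermis": float(per_image["dice_dermis"].mean()),
        "jaccard_epidermis": float(per_image["jaccard_epidermis"].mean()),
        "jaccard_dermis": float(per_image["jaccard_dermis"].mean()),
        "et_gt_um": float(per_patient["et_gt_um"].mean()),
        "et_pred_um": float(per_patient["et_pred_um"].mean()),
        "rmse_um": float(per_patient["rmse_um"].mean()),
        "mae_um": float(per_patient["mae_um"].mean()),
    }
    if "rsr" in per_patient:
        cohort["rsr"] = float(per_patient["rsr"].mean())
    return MetricsReport(per_image=per_image.reset_index(drop=True),
                         per_patient=per_patient, cohort=cohort)
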