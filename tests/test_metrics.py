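"""Dice/Jaccard, follicle counting, RSR, epidermal thickness, error metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octseg import (LabelMask, generate_phantom, dice, jaccard, rsr,
                    count_follicles, epidermal_thickness, thickness_errors,
                    aggregate_report, extract_boundaries, refine_mask)
from octseg.octio import BoundaryProfile

from conftest import wide_flat_spec


def _mask_from(binary, layer=1):
    return LabelMask(labels=(binary.astype(np.uint8) * layer))


def test_dice_jaccard_identical_and_disjoint():
    a = np.zeros((10, 10), dtype=bool)
    a[2:5] = True
    b = np.zeros_like(a)
    b[6:9] = True
    ma, mb = _mask_from(a), _mask_from(b)
    assert dice(ma, ma, 1) == 1.0 and jaccard(ma, ma, 1) == 1.0
    assert dice(ma, mb, 1) == 0.0 and jaccard(ma, mb, 1) == 0.0


def test_dice_jaccard_hand_example():
    a = np.zeros((20, 20), dtype=bool)
    b = np.zeros_like(a)
    a.ravel()[:100] = True
    b.ravel()[20:120] = True  # |A|=|B|=100, overlap 80
    ma, mb = _mask_from(a), _mask_from(b)
    assert dice(ma, mb, 1) == pytest.approx(0.8)
    assert jaccard(ma, mb, 1) == pytest.approx(80 / 120)


def test_dice_both_empty_convention():
    z = _mask_from(np.zeros((5, 5), dtype=bool))
    assert dice(z, z, 1) == 1.0 and jaccard(z, z, 1) == 1.0


def test_jaccard_dice_identity_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = _mask_from(rng.random((15, 15)) > 0.5)
        b = _mask_from(rng.random((15, 15)) > 0.5)
        d, j = dice(a, b, 1), jaccard(a, b, 1)
        assert j == pytest.approx(d / (2 - d))


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice(_mask_from(np.zeros((3, 3), dtype=bool)),
             _mask_from(np.zeros((4, 4), dtype=bool)), 1)


def test_rsr_table_examples():
    assert round(rsr(3, 4), 2) == 0.67
    assert round(rsr(4, 6), 2) == 0.50
    assert rsr(5, 5) == 1.0


@settings(derandomize=True, max_examples=200)
@given(f_gt=st.integers(1, 50), f_p=st.integers(0, 100))
def test_rsr_matches_direct_formula(f_gt, f_p):
    assert rsr(f_gt, f_p) == pytest.approx(1 - abs(f_gt - f_p) / f_gt)
    assert rsr(f_gt, f_p) <= 1.0
    # scaling both counts preserves RSR
    assert rsr(3 * f_gt, 3 * f_p) == pytest.approx(rsr(f_gt, f_p))


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.floats(0, 200), st.floats(0, 200)),
                min_size=1, max_size=30))
def test_rmse_mae_ordering_property(pairs):
    g = np.array([a for a, _ in pairs])
    p = np.array([b for _, b in pairs])
    rmse, mae = thickness_errors(g, p)
    assert rmse + 1e-12 >= mae >= 0.0


def test_rsr_domain_errors():
    with pytest.raises(ValueError):
        rsr(0, 3)
    with pytest.raises(ValueError):
        rsr(3, -1)


def test_count_follicles_on_phantoms():
    for nf in (0, 3):
        _, mask, _ = generate_phantom(wide_flat_spec(n_follicles=nf, seed=4))
        assert count_follicles(mask) == nf


def test_merged_follicles_count_as_one_fewer():
    spec3 = wide_flat_spec(n_follicles=3, seed=12)
    _, mask3, _ = generate_phantom(spec3)
    # one wide invagination replacing two: double halfwidth, fewer centers
    spec_m = wide_flat_spec(n_follicles=2, follicle_halfwidth_px=30.0, seed=12)
    _, mask_m, _ = generate_phantom(spec_m)
    assert count_follicles(mask3) - count_follicles(mask_m) == 1


def test_flat_band_thickness(flat_band_mask):
    profile = extract_boundaries(flat_band_mask)
    assert epidermal_thickness(profile, 1.0) == pytest.approx(30.0)
    assert epidermal_thickness(profile, 2.0) == pytest.approx(60.0)


def test_follicle_columns_excluded_from_thickness():
    flat = wide_flat_spec(n_follicles=0, seed=5)
    _, mask0, _ = generate_phantom(flat)
    _, mask1, _ = generate_phantom(wide_flat_spec(n_follicles=1, seed=5))
    p0 = extract_boundaries(mask0)
    _, _, p1 = refine_mask(mask1)
    et0 = epidermal_thickness(p0, flat.axial_pixel_um)
    et1 = epidermal_thickness(p1, flat.axial_pixel_um)
    assert et1 == pytest.approx(et0, abs=flat.axial_pixel_um)
    assert et0 == pytest.approx(
        flat.epidermis_thickness_px * flat.axial_pixel_um)


def test_thickness_errors_examples():
    assert thickness_errors([10.0], [13.0]) == (3.0, 3.0)
    rmse, mae = thickness_errors([0.0, 0.0], [3.0, 4.0])
    assert rmse == pytest.approx(np.sqrt(12.5))
    assert mae == pytest.approx(3.5)
    assert thickness_errors([5, 5], [5, 5]) == (0.0, 0.0)
    with pytest.raises(ValueError):
        thickness_errors([1, 2], [1])


def test_rmse_never_below_mae():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        g = rng.normal(size=8) * 10
        p = g + rng.normal(size=8) * 3
        rmse, mae = thickness_errors(g, p)
        assert rmse >= mae >= 0.0


def _per_image_frame():
    rows = []
    for pid, ets in [("P01", (50, 52)), ("P02", (70, 71))]:
        for i, et in enumerate(ets):
            rows.append({"patient_id": pid, "image": f"{pid}_{i}",
                         "dice_epidermis": 0.8, "dice_dermis": 0.95,
                         "jaccard_epidermis": 0.7, "jaccard_dermis": 0.9,
                         "et_gt_um": et, "et_pred_um": et + 2.0})
    return pd.DataFrame(rows)


def test_aggregate_report_per_patient_and_cohort():
    fc = pd.DataFrame([{"patient_id": "P01", "f_gt": 3, "f_p": 4},
                       {"patient_id": "P02", "f_gt": 4, "f_p": 4}])
    report = aggregate_report(_per_image_frame(), fc)
    assert len(report.per_patient) == 2
    row = report.per_patient.set_index("patient_id").loc["P01"]
    assert row["rmse_um"] == pytest.approx(2.0)
    assert row["mae_um"] == pytest.approx(2.0)
    assert row["rsr"] == pytest.approx(1 - 1 / 3)
    assert report.cohort["rsr"] == pytest.approx((2 / 3 + 1.0) / 2)
    assert report.cohort["rmse_um"] == pytest.approx(2.0)


def test_single_patient_cohort_equals_patient():
    frame = _per_image_frame()
    report = aggregate_report(frame[frame.patient_id == "P01"])
    assert report.cohort["rmse_um"] == pytest.approx(
        report.per_patient.iloc[0]["rmse_um"])
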