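"""Boundary extraction, baseline correction, follicle isolation, recombination."""

import numpy as np
import pytest

from octseg import LabelMask, generate_phantom
from octseg.octio import BoundaryProfile
from octseg.postproc import (PostprocConfig, SGFilterSpec, extract_boundaries,
                             fit_baseline, correct_baseline, detect_follicles,
                             area_opening, refine_mask, smooth_and_recombine,
                             FollicleSet, FollicleComponent)

from conftest import wide_flat_spec


def test_flat_band_boundaries(flat_band_mask):
    profile = extract_boundaries(flat_band_mask)
    assert np.all(profile.surface == 50)
    assert np.all(profile.s_dej == 80)
    assert profile.valid.all()


def test_invalid_column_interpolated(flat_band_mask):
    lab = flat_band_mask.labels.copy()
    lab[:, 100] = 0
    lab[50:81, 99] = 1
    lab[50:83, 101] = 1   # s_dej 82 to the right, 80 to the left
    profile = extract_boundaries(LabelMask(labels=lab))
    assert not profile.valid[100]
    assert profile.s_dej[100] == pytest.approx(81.0)


def test_edge_invalid_columns_extend_nearest(flat_band_mask):
    lab = flat_band_mask.labels.copy()
    lab[:, :3] = 0
    profile = extract_boundaries(LabelMask(labels=lab))
    assert np.all(profile.s_dej[:3] == 80)


def test_no_epidermis_rejected():
    with pytest.raises(ValueError, match="class 1"):
        extract_boundaries(LabelMask(labels=np.zeros((10, 10), dtype=np.uint8)))


def test_extracted_boundaries_match_phantom_truth():
    _, mask, truth = generate_phantom(wide_flat_spec(n_follicles=2, seed=8))
    profile = extract_boundaries(mask)
    assert np.array_equal(profile.surface, truth.surface)
    assert np.array_equal(profile.s_dej, truth.s_dej)


def _profile_with(bl, s_dej):
    w = len(s_dej)
    return BoundaryProfile(surface=np.zeros(w), s_dej=np.asarray(s_dej, float),
                           valid=np.ones(w, dtype=bool),
                           bl=np.asarray(bl, float))


def test_baseline_shift_to_shallowest_dej():
    s_dej = np.full(500, 100.0)
    s_dej[250] = 95.0
    profile = correct_baseline(_profile_with(np.full(500, 100.0), s_dej))
    assert np.allclose(profile.blc, 95.0)


def test_already_aligned_baseline_unchanged():
    s_dej = np.linspace(80, 90, 500)
    profile = correct_baseline(_profile_with(s_dej.copy(), s_dej))
    assert np.allclose(profile.blc, profile.bl)


def test_follicle_lies_below_corrected_baseline():
    spec = wide_flat_spec(n_follicles=1, follicle_depth_px=40, seed=3)
    _, mask, truth = generate_phantom(spec)
    profile = extract_boundaries(mask)
    fit_baseline(profile, SGFilterSpec(window=449, order=1))
    correct_baseline(profile)
    deep = truth.s_dej >= truth.s_dej.min() + spec.follicle_depth_px / 2
    assert np.all(truth.s_dej[deep] > profile.blc[deep] + 1)


def test_detect_follicles_flat_phantom_empty():
    _, mask, _ = generate_phantom(wide_flat_spec(n_follicles=0, seed=1))
    profile = extract_boundaries(mask)
    fit_baseline(profile, SGFilterSpec(window=449, order=1))
    correct_baseline(profile)
    assert len(detect_follicles(mask, profile)) == 0


def test_detect_three_separated_follicles():
    _, mask, _ = generate_phantom(wide_flat_spec(n_follicles=3, seed=2))
    profile = extract_boundaries(mask)
    fit_baseline(profile, SGFilterSpec(window=449, order=1))
    correct_baseline(profile)
    follicles = detect_follicles(mask, profile)
    assert len(follicles) == 3
    assert (follicles.areas > 0).all()


def _fset(areas):
    comps = []
    r0 = 0
    for a in areas:
        comps.append(FollicleComponent(rows=np.full(a, r0), cols=np.arange(a)))
        r0 += 2
    return FollicleSet(components=comps)


def test_area_opening_rule():
    out = area_opening(_fset([100, 90, 20]), fraction=0.3)
    assert out.alpha == pytest.approx(30.0)
    assert sorted(out.areas.tolist()) == [90, 100]


def test_area_opening_single_and_equal_components_survive():
    assert len(area_opening(_fset([40]), 0.3)) == 1
    assert len(area_opening(_fset([50, 50, 50]), 0.3)) == 3
    empty = area_opening(FollicleSet(), 0.3)
    assert len(empty) == 0 and empty.alpha == 0.0


def test_area_opening_idempotent_and_anti_extensive():
    once = area_opening(_fset([120, 80, 30, 10]), 0.3)
    twice = area_opening(once, 0.3)
    assert twice.areas.tolist() == once.areas.tolist()
    assert len(once) <= 4


def test_recombine_without_follicles_keeps_upper_epidermis(flat_band_mask):
    profile = extract_boundaries(flat_band_mask)
    fit_baseline(profile, SGFilterSpec(window=449, order=1))
    correct_baseline(profile)
    out = smooth_and_recombine(flat_band_mask, FollicleSet(), profile)
    assert np.array_equal(out.labels, flat_band_mask.labels)


def test_refine_mask_partitions_and_counts():
    _, mask, _ = generate_phantom(wide_flat_spec(n_follicles=2, seed=6))
    final, follicles, profile = refine_mask(mask)
    assert final.shape == mask.shape
    assert set(np.unique(final.labels)) <= {0, 1, 2}
    assert len(follicles) == 2
    assert profile.follicle_columns.size > 0


def test_refine_preserves_smooth_phantom_epidermis():
    """Already-smooth follicles should barely change under refinement."""
    _, mask, _ = generate_phantom(wide_flat_spec(n_follicles=2, seed=9))
    final, _, _ = refine_mask(mask)
    a = mask.labels == 1
    b = final.labels == 1
    changed = np.logical_xor(a, b).sum()
    assert changed / a.sum() < 0.05
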