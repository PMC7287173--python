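"""Refinement of a network label mask into the final segmentation.

Steps: (1) extract the per-column skin-surface and dermo-epidermal junction
(DEJ) rows from the epidermis class; (2) smooth the DEJ signal with a
degree-1, 449-sample Savitzky-Golay filter to get the junction baseline;
(3) shift the baseline so its shallowest point meets the shallowest DEJ
point, separating the flat epidermis from follicular invaginations;
(4) take the 8-connected components of epidermis pixels strictly below the
corrected baseline and remove those smaller than alpha = 0.3 x the largest
component (morphological area opening); (5) smooth each surviving follicle
outline by Fourier-descriptor truncation; (6) recombine the upper epidermis
with the rasterized smoothed follicles into a 3-class mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from ..octio import LabelMask, BoundaryProfile, N_CLASSES
from .sgolay import SGFilterSpec, savitzky_golay
from .contours import (contour_resample, fourier_descriptors,
                       reconstruct_contour, descriptor_count_from_cutoff)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class FollicleComponent:
    """One below-baseline connected component and its contour descriptors."""

    rows: np.ndarray
    cols: np.ndarray
    contour: np.ndarray | None = None            # complex s[n], power-of-two length
    descriptors: np.ndarray | None = None        # S[k]
    smoothed: np.ndarray | None = None           # truncated reconstruction
    retained: int | None = None                  # P

    @property
    def area(self) -> int:
        return int(self.rows.size)


@dataclass
class FollicleSet:
    components: list[FollicleComponent] = field(default_factory=list)
    alpha: float = 0.0
    f_c: float | None = None

    def __len__(self) -> int:
        return len(self.components)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components], dtype=int)


@dataclass(frozen=True)
class PostprocConfig:
    sg: SGFilterSpec = field(default_factory=SGFilterSpec)
    opening_fraction: float = 0.3
    f_c: float = 0.007
    fixed_p: int | None = 4              # None -> P = round(f_c * N) per contour
    baseline_correction: str = "shallow_align"   # or "literal_rows"
    min_component_px: int = 3


def extract_boundaries(mask: LabelMask) -> BoundaryProfile:
    """Per-column surface (first class-1 row) and DEJ (last class-1 row).

    Columns without epidermis pixels are flagged invalid and filled by linear
    interpolation between the nearest valid columns (edges extend the nearest
    value), so the baseline filter sees a complete signal.
    """
    lab = mask.labels
    is_epi = lab == 1
    valid = is_epi.any(axis=0)
    if not valid.any():
        raise ValueError("mask contains no epidermis (class 1) pixels")
    h = lab.shape[0]
    first = np.where(valid, is_epi.argmax(axis=0), 0).astype(float)
    last = np.where(valid, h - 1 - is_epi[::-1].argmax(axis=0), 0).astype(float)
    cols = np.arange(lab.shape[1])
    vc = cols[valid]
    surface = np.interp(cols, vc, first[valid])
    s_dej = np.interp(cols, vc, last[valid])
    return BoundaryProfile(surface=surface, s_dej=s_dej, valid=valid)


def fit_baseline(profile: BoundaryProfile, sg: SGFilterSpec) -> BoundaryProfile:
    profile.bl = savitzky_golay(profile.s_dej, sg)
    return profile


def correct_baseline(profile: BoundaryProfile,
                     mode: str = "shallow_align") -> BoundaryProfile:
    """Shift the baseline by the scalar dif so it hugs the flat epidermis.

    ``shallow_align`` aligns the baseline's shallowest point with the
    shallowest DEJ point (the stated max-alignment read in height-up
    coordinates, where image height minus row makes shallow = max);
    ``literal_rows`` applies the same formula directly on row indices.
    """
    if profile.bl is None:
        raise ValueError("run fit_baseline first")
    bl, s_dej = profile.bl, profile.s_dej
    if mode == "shallow_align":
        dif = bl.min() - s_dej.min()
    elif mode == "literal_rows":
        dif = s_dej.max() - bl.max()
    else:
        raise ValueError(f"unknown baseline correction mode {mode!r}")
    profile.blc = bl - dif
    return profile


def detect_follicles(mask: LabelMask, profile: BoundaryProfile) -> FollicleSet:
    """8-connected components of class-1 pixels strictly below the baseline."""
    if profile.blc is None:
        raise ValueError("corrected baseline blc not available")
    rows = np.arange(mask.shape[0])[:, None]
    candidate = (mask.labels == 1) & (rows > profile.blc[None, :])
    labeled, n = ndimage.label(candidate, structure=_EIGHT)
    comps = []
    for i in range(1, n + 1):
        r, c = np.nonzero(labeled == i)
        comps.append(FollicleComponent(rows=r, cols=c))
    return FollicleSet(components=comps)


def area_opening(follicles: FollicleSet, fraction: float = 0.3) -> FollicleSet:
    """Drop components with area below alpha = fraction * max component area."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if not follicles.components:
        return FollicleSet(components=[], alpha=0.0, f_c=follicles.f_c)
    alpha = fraction * follicles.areas.max()
    kept = [c for c in follicles.components if c.area >= alpha]
    return FollicleSet(components=kept, alpha=float(alpha), f_c=follicles.f_c)


def smooth_follicles(follicles: FollicleSet, config: PostprocConfig) -> FollicleSet:
    """Resample, transform and truncate each component's contour.

    Components too small to carry a 2-D contour are kept unsmoothed (their
    raw pixels are rasterized as-is downstream).
    """
    for comp in follicles.components:
        try:
            s = contour_resample(comp.rows, comp.cols)
        except ValueError:
            continue
        comp.contour = s
        comp.descriptors = fourier_descriptors(s)
        n = s.size
        p = config.fixed_p if config.fixed_p is not None else \
            descriptor_count_from_cutoff(n, config.f_c)
        p = min(p, n)
        comp.retained = p
        comp.smoothed = reconstruct_contour(comp.descriptors, p=p)
    follicles.f_c = config.f_c
    return follicles


def smooth_and_recombine(mask: LabelMask, follicles: FollicleSet,
                         profile: BoundaryProfile) -> LabelMask:
    """Final 3-class mask: upper epidermis plus smoothed follicle regions.

    Class 1 is the union of class-1 pixels at or above the corrected baseline
    with the filled smoothed contours; class 0 lies above the surface curve;
    class 2 fills the rest.
    """
    if profile.blc is None:
        raise ValueError("corrected baseline blc not available")
    h, w = mask.shape
    rows = np.arange(h)[:, None]
    epi = (mask.labels == 1) & (rows <= profile.blc[None, :])
    for comp in follicles.components:
        if comp.smoothed is not None and comp.smoothed.size >= 3:
            rr, cc = draw_polygon(comp.smoothed.imag, comp.smoothed.real,
                                  shape=(h, w))
            epi[rr, cc] = True
        else:
            epi[comp.rows, comp.cols] = True
    out = np.full((h, w), 2, dtype=np.uint8)
    out[rows < profile.surface[None, :]] = 0
    out[epi] = 1
    return LabelMask(labels=out)


def refine_mask(mask: LabelMask, config: PostprocConfig | None = None,
                ) -> tuple[LabelMask, FollicleSet, BoundaryProfile]:
    """Run the full refinement chain on a 3-class label mask."""
    config = config or PostprocConfig()
    profile = extract_boundaries(mask)
    fit_baseline(profile, config.sg)
    correct_baseline(profile, config.baseline_correction)
    follicles = detect_follicles(mask, profile)
    follicles = area_opening(follicles, config.opening_fraction)
    follicles = smooth_follicles(follicles, config)
    cols = sorted({int(c) for comp in follicles.components
                   for c in np.unique(comp.cols)})
    profile.follicle_columns = np.array(cols, dtype=int)
    final = smooth_and_recombine(mask, follicles, profile)
    return final, follicles, profile


def sidecar_dict(follicles: FollicleSet, profile: BoundaryProfile,
                 config: PostprocConfig) -> dict:
    """JSON-serializable record of the refinement of one image."""
    return {
        "surface": profile.surface.tolist(),
        "s_dej": profile.s_dej.tolist(),
        "bl": None if profile.bl is None else profile.bl.tolist(),
        "blc": None if profile.blc is None else profile.blc.tolist(),
        "alpha": follicles.alpha,
        "f_c": config.f_c,
        "sg_window": config.sg.window,
        "sg_order": config.sg.order,
        "follicles": [
            {"area": comp.area,
             "n_points": None if comp.contour is None else int(comp.contour.size),
             "retained_p": comp.retained,
             "contour": None if comp.contour is None else
             [[z.real, z.imag] for z in comp.contour],
             "smoothed": None if comp.smoothed is None else
             [[z.real, z.imag] for z in comp.smoothed]}
            for comp in follicles.components],
    }
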