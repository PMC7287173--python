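"""Synthetic skin-OCT phantoms with exact ground truth.

A phantom B-scan emulates the gross structure of a cheek OCT image: a dark
air/gel region above a bright entrance surface, a bright epidermis band, and
a dimmer dermis below, with hair follicles modelled as smooth (Gaussian)
downward invaginations of the dermo-epidermal junction (DEJ).  Intensity is
piecewise layer brightness attenuated exponentially with depth below the
surface and corrupted by multiplicative gamma speckle.  Because the geometry
is generated analytically, every phantom carries a pixel-exact label mask and
the true per-column surface/DEJ curves, so the whole downstream pipeline can
be tested without real data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .octio import OCTImage, LabelMask, BoundaryProfile, save_image, save_mask

CLASS_UPPER = 0      # air / gel above the skin surface
CLASS_EPIDERMIS = 1  # epidermis together with follicular invaginations
CLASS_DERMIS = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one synthetic B-scan.

    Depths are in pixels along the axial (row) axis; row 0 is shallowest.
    """

    height_px: int = 200
    width_px: int = 512
    axial_pixel_um: float = 2.2
    surface_depth_px: float = 40.0
    epidermis_thickness_px: float = 30.0
    n_follicles: int = 3
    follicle_depth_px: float = 40.0
    follicle_halfwidth_px: float = 15.0
    speckle_level: float = 0.3
    attenuation_per_px: float = 0.004
    surface_waviness_amp_px: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("height_px and width_px must be positive")
        if (self.surface_depth_px + self.epidermis_thickness_px
                + self.follicle_depth_px >= self.height_px):
            raise ValueError(
                "invariant violated: surface_depth_px + epidermis_thickness_px"
                " + follicle_depth_px must be < height_px")
        if self.n_follicles < 0:
            raise ValueError("n_follicles must be non-negative")
        if self.n_follicles > 0:
            # centers need >= 4*halfwidth separation plus 2*halfwidth margins
            need = 4.0 * self.follicle_halfwidth_px * (self.n_follicles + 1)
            if need > self.width_px:
                raise ValueError(
                    "invariant violated: follicle centers separated by at least"
                    " 4*follicle_halfwidth_px do not fit into width_px")
        for name in ("epidermis_thickness_px", "follicle_halfwidth_px",
                     "axial_pixel_um", "surface_depth_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("speckle_level", "attenuation_per_px",
                     "surface_waviness_amp_px", "follicle_depth_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.surface_waviness_amp_px >= self.epidermis_thickness_px:
            raise ValueError(
                "invariant violated: surface_waviness_amp_px must be smaller"
                " than epidermis_thickness_px (surface stays above the DEJ)")
        if self.surface_waviness_amp_px >= self.surface_depth_px:
            raise ValueError(
                "invariant violated: surface_waviness_amp_px must be smaller"
                " than surface_depth_px (surface stays inside the image)")


# layer brightness before attenuation/speckle, in [0, 1]
_BRIGHT_SURFACE = 0.95
_BRIGHT_EPIDERMIS = 0.75
_BRIGHT_DERMIS = 0.45
_BRIGHT_UPPER = 0.05


def _follicle_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Lateral follicle positions, pairwise separated by >= 4*halfwidth.

    The usable lateral range (a 2*halfwidth margin off each edge) is split
    into n equal sub-intervals; each center is jittered inside its own
    sub-interval, which guarantees both the separation and the margins.
    """
    n = spec.n_follicles
    if n == 0:
        return np.empty(0)
    sep = 4.0 * spec.follicle_halfwidth_px
    margin = 2.0 * spec.follicle_halfwidth_px
    interval = (spec.width_px - 2.0 * margin) / n
    slots = margin + (np.arange(n) + 0.5) * interval
    slack = max(0.0, (interval - sep) / 2.0)
    jitter = rng.uniform(-slack, slack, size=n)
    return slots + jitter


def _follicle_bump(x: np.ndarray, center: float, depth: float,
                   halfwidth: float) -> np.ndarray:
    """Gaussian invagination with compact support (zero beyond 2*halfwidth).

    Truncating and renormalizing the Gaussian keeps neighbouring follicles at
    the minimum 4*halfwidth separation strictly disjoint on the pixel grid,
    so connected-component counting on the true mask is exact by construction.
    """
    z = (x - center) / halfwidth
    g = (np.exp(-0.5 * z * z) - np.exp(-2.0)) / (1.0 - np.exp(-2.0))
    return depth * np.clip(g, 0.0, None)


def true_boundaries(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer surface and DEJ row per column, plus follicle centers.

    The entrance surface undulates gently; the non-follicular DEJ sits at a
    constant depth (surface mean + epidermis thickness) with follicles as
    downward bumps, so the band thickness varies with the surface wave.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.width_px)
    phase = rng.uniform(0, 2 * np.pi)
    wavelength = max(spec.width_px / 1.5, 64.0)
    surface = spec.surface_depth_px + spec.surface_waviness_amp_px * np.sin(
        2 * np.pi * x / wavelength + phase)
    centers = _follicle_centers(spec, rng)
    bump = np.zeros(spec.width_px)
    for c in centers:
        bump += _follicle_bump(x, c, spec.follicle_depth_px,
                               spec.follicle_halfwidth_px)
    dej = spec.surface_depth_px + spec.epidermis_thickness_px + bump
    surface_row = np.round(surface).astype(int)
    dej_row = np.round(dej).astype(int)
    return surface_row, dej_row, centers


def generate_phantom(spec: PhantomSpec) -> tuple[OCTImage, LabelMask, BoundaryProfile]:
    """Render one phantom B-scan with its exact mask and boundary profile.

    The epidermis class occupies, per column, exactly the rows from the
    surface row to the DEJ row inclusive; each follicle is a Gaussian bump of
    the DEJ curve.  Same spec (incl. seed) gives a bit-identical result.
    """
    spec.validate()
    surface_row, dej_row, _ = true_boundaries(spec)
    h, w = spec.height_px, spec.width_px
    rows = np.arange(h)[:, None]

    labels = np.full((h, w), CLASS_DERMIS, dtype=np.uint8)
    labels[rows < surface_row[None, :]] = CLASS_UPPER
    in_epi = (rows >= surface_row[None, :]) & (rows <= dej_row[None, :])
    labels[in_epi] = CLASS_EPIDERMIS

    img = np.where(labels == CLASS_UPPER, _BRIGHT_UPPER,
                   np.where(labels == CLASS_EPIDERMIS, _BRIGHT_EPIDERMIS,
                            _BRIGHT_DERMIS)).astype(np.float64)
    # bright entrance line at the surface itself
    img[rows == surface_row[None, :]] = _BRIGHT_SURFACE
    depth_below = np.clip(rows - surface_row[None, :], 0, None)
    img *= np.exp(-spec.attenuation_per_px * depth_below)

    if spec.speckle_level > 0:
        rng = np.random.default_rng(spec.seed + 1)
        s2 = spec.speckle_level ** 2
        speckle = rng.gamma(shape=1.0 / s2, scale=s2, size=(h, w))
        img *= speckle
    img = np.clip(img, 0.0, 1.0)

    image = OCTImage(pixels=img, axial_pixel_um=spec.axial_pixel_um,
                     source_id=f"phantom-seed{spec.seed}")
    mask = LabelMask(labels=labels)
    profile = BoundaryProfile(
        surface=surface_row.astype(float),
        s_dej=dej_row.astype(float),
        valid=np.ones(w, dtype=bool),
    )
    return image, mask, profile


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    image: OCTImage
    mask: LabelMask
    spec: PhantomSpec


def generate_cohort(n_patients: int, images_per_patient: int,
                    base_spec: PhantomSpec, seed: int) -> list[CohortRecord]:
    """Deterministic multi-patient phantom dataset for patient-wise folding.

    Per-patient epidermal thickness and follicle count are jittered from the
    base spec so patients differ, mimicking a real cohort where each subject
    contributes a fixed number of B-scans.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2 so cross-validation folds exist")
    if images_per_patient < 1:
        raise ValueError("images_per_patient must be positive")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        thick = base_spec.epidermis_thickness_px * float(rng.uniform(0.8, 1.2))
        n_fol = int(rng.integers(max(0, base_spec.n_follicles - 1),
                                 base_spec.n_follicles + 2))
        for i in range(images_per_patient):
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = replace(base_spec, epidermis_thickness_px=thick,
                           n_follicles=n_fol, seed=img_seed)
            image, mask, _ = generate_phantom(spec)
            image = replace(image, source_id=f"{pid}-{i:03d}")
            records.append(CohortRecord(pid, image, mask, spec))
    return records


def write_cohort(records: list[CohortRecord], out_dir: str | Path,
                 image_format: str = "png") -> Path:
    """Write images, masks and a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["patient_id", "image_path", "mask_path"])
        for rec in records:
            ipath = out / "images" / f"{rec.image.source_id}.{image_format}"
            mpath = out / "masks" / f"{rec.image.source_id}_mask.png"
            save_image(rec.image, ipath)
            save_mask(rec.mask, mpath)
            wr.writerow([rec.patient_id, str(ipath), str(mpath)])
    return manifest
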