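"""Image/mask containers, file I/O, rescaling, patch extraction and tiling.

All B-scans are brought to one common working dimension (default 526 x 975,
the dataset-wide minimum) before training or inference.  Training consumes
full-height non-overlapping patches; inference splits a scan into two
fixed-width slices whose probability maps are averaged back together over the
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
import tifffile
from skimage.transform import resize

N_CLASSES = 3
COMMON_DIM = (526, 975)   # rows x cols working dimension
PATCH_WIDTH = 75          # training patch width (patches are full height)
SLICE_WIDTH = 512         # inference tile width


@dataclass(frozen=True)
class OCTImage:
    """A 2-D B-scan; rows are depth (row 0 shallowest), columns lateral."""

    pixels: np.ndarray
    axial_pixel_um: float | None = None
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("OCTImage requires a non-empty 2-D raster")
        if not np.all(np.isfinite(px)):
            raise ValueError("OCTImage intensities must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "OCTImage":
        """Min-max normalize intensities into [0, 1]."""
        px = self.pixels
        lo, hi = px.min(), px.max()
        out = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
        return replace(self, pixels=out)


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel class map over {0: upper bound, 1: epidermis+follicles, 2: dermis}."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("LabelMask requires a non-empty 2-D raster")
        if not np.isin(np.unique(lab), np.arange(N_CLASSES)).all():
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def one_hot(self) -> np.ndarray:
        """(n_classes, rows, cols) one-hot float encoding g_l(x)."""
        return (self.labels[None, :, :] ==
                np.arange(N_CLASSES)[:, None, None]).astype(np.float64)


@dataclass
class BoundaryProfile:
    """Per-column boundary depth signals (row coordinates, row 0 shallowest)."""

    surface: np.ndarray                  # skin surface row per column
    s_dej: np.ndarray                    # dermo-epidermal junction row
    valid: np.ndarray                    # columns where class 1 is present
    bl: np.ndarray | None = None         # Savitzky-Golay baseline of s_dej
    blc: np.ndarray | None = None        # corrected baseline
    follicle_columns: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class probabilities p_l(x), shape (n_classes, rows, cols)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 3:
            raise ValueError("ProbabilityMap must be (classes, rows, cols)")
        if p.min() < -1e-8 or np.abs(p.sum(axis=0) - 1.0).max() > 1e-5:
            raise ValueError("class probabilities must be >=0 and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]


# ---------------------------------------------------------------- file I/O

def save_image(image: OCTImage, path: str | Path) -> None:
    path = Path(path)
    px = np.clip(image.pixels, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (px * 65535).astype(np.uint16))
    else:
        PILImage.fromarray((px * 255).round().astype(np.uint8)).save(path)


def load_image(path: str | Path, axial_pixel_um: float | None = None) -> OCTImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(np.float64)
        arr /= 65535.0 if arr.max() > 255 else max(arr.max(), 1.0)
    else:
        arr = np.asarray(PILImage.open(path).convert("L"), dtype=np.float64) / 255.0
    return OCTImage(pixels=arr, axial_pixel_um=axial_pixel_um,
                    source_id=path.stem)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    PILImage.fromarray(mask.labels, mode="L").save(path)


def load_mask(path: str | Path) -> LabelMask:
    return LabelMask(labels=np.asarray(PILImage.open(path), dtype=np.uint8))


def save_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    tifffile.imwrite(Path(path), pmap.probs.astype(np.float32),
                     photometric="minisblack")


def load_probability_map(path: str | Path) -> ProbabilityMap:
    return ProbabilityMap(probs=tifffile.imread(Path(path)).astype(np.float64))


def read_manifest(path: str | Path) -> list[tuple[str, Path, Path]]:
    """Rows of (patient_id, image_path, mask_path) from a cohort manifest CSV."""
    import csv
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((rec["patient_id"], Path(rec["image_path"]),
                         Path(rec["mask_path"])))
    return rows


# ----------------------------------------------------------- geometry ops

def rescale_to_common(image: OCTImage, mask: LabelMask | None = None,
                      target: tuple[int, int] = COMMON_DIM,
                      ) -> tuple[OCTImage, LabelMask | None]:
    """Resample to the common working dimension.

    Intensities use bilinear interpolation; masks nearest-neighbor so labels
    stay categorical (no label can be invented).
    """
    rows, cols = target
    if rows <= 0 or cols <= 0:
        raise ValueError("target dimensions must be positive")
    if image.shape == (rows, cols):
        out_img = image
    else:
        px = resize(image.pixels, (rows, cols), order=1, mode="reflect",
                    anti_aliasing=False, preserve_range=True)
        out_img = replace(image, pixels=px)
    out_mask = None
    if mask is not None:
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        if mask.shape == (rows, cols):
            out_mask = mask
        else:
            lab = resize(mask.labels, (rows, cols), order=0, mode="edge",
                         anti_aliasing=False, preserve_range=True)
            out_mask = LabelMask(labels=lab.astype(np.uint8))
    return out_img, out_mask


def extract_patches(image: OCTImage, mask: LabelMask, patch_width: int = PATCH_WIDTH,
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Non-overlapping full-height patches, left to right.

    The image width must divide evenly by ``patch_width`` (975 = 13 x 75 at
    the common dimension); lateral concatenation of the patches reconstructs
    the image exactly.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    if w % patch_width != 0:
        raise ValueError(
            f"image width {w} not divisible by patch width {patch_width}"
            f" (residue {w % patch_width})")
    n = w // patch_width
    return [(image.pixels[:, i * patch_width:(i + 1) * patch_width],
             mask.labels[:, i * patch_width:(i + 1) * patch_width])
            for i in range(n)]


def split_for_inference(image: OCTImage, slice_width: int = SLICE_WIDTH,
                        ) -> list[tuple[np.ndarray, int]]:
    """Split a scan into at most two fixed-width slices with column offsets.

    Width w with slice_width < w <= 2*slice_width yields slices at offsets 0
    and w - slice_width (overlapping in the middle).  w == slice_width is the
    degenerate single-slice case.
    """
    h, w = image.shape
    if slice_width <= 0:
        raise ValueError("slice_width must be positive")
    if w < slice_width:
        raise ValueError(f"image width {w} smaller than slice width {slice_width}")
    if w > 2 * slice_width:
        raise ValueError(
            f"image width {w} exceeds 2 x slice_width = {2 * slice_width};"
            " two slices cannot cover it")
    if w == slice_width:
        return [(image.pixels.copy(), 0)]
    return [(image.pixels[:, :slice_width], 0),
            (image.pixels[:, w - slice_width:], w - slice_width)]


def recombine_slices(slice_maps: list[tuple[ProbabilityMap, int]],
                     full_width: int) -> ProbabilityMap:
    """Merge tiled probability maps; overlaps take the arithmetic mean."""
    if not slice_maps:
        raise ValueError("no slices to recombine")
    n_classes, rows = slice_maps[0][0].probs.shape[:2]
    acc = np.zeros((n_classes, rows, full_width))
    cnt = np.zeros(full_width)
    for pmap, off in slice_maps:
        w = pmap.probs.shape[2]
        if off < 0 or off + w > full_width:
            raise ValueError("slice extends outside the full width")
        acc[:, :, off:off + w] += pmap.probs
        cnt[off:off + w] += 1
    if (cnt == 0).any():
        gap = np.flatnonzero(cnt == 0)
        raise ValueError(f"coverage gap: columns [{gap[0]}, {gap[-1]}] uncovered")
    return ProbabilityMap(probs=acc / cnt[None, None, :])
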