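"""Closed-contour Fourier descriptors for follicle shape smoothing.

A component's boundary (the outline of its union of unit pixel squares) is
resampled to N points equispaced in arc length, N a power of two, and encoded
as the complex sequence s[n] = x[n] + j y[n] (x lateral column, y depth row).
Its Fourier descriptors are the DFT S[k] of that sequence.  Truncating the
spectrum to the P lowest-|frequency| bins (k = 0, then the pairs (k, N-k) by
increasing k) and inverting yields a smoothed closed contour: low-order
descriptors carry the overall shape, high-order ones the boundary roughness.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union


def next_power_of_two(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def component_boundary_polygon(pixel_rows: np.ndarray, pixel_cols: np.ndarray):
    """Exterior ring of the union of unit squares centered on the pixels."""
    if pixel_rows.size < 3:
        raise ValueError("component needs at least 3 pixels for a contour")
    if (pixel_rows.max() - pixel_rows.min() < 1
            or pixel_cols.max() - pixel_cols.min() < 1):
        raise ValueError("degenerate line-like component has no 2-D contour")
    squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
               for r, c in zip(pixel_rows.tolist(), pixel_cols.tolist())]
    geom = unary_union(squares)
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    return geom.exterior


def contour_resample(pixel_rows: np.ndarray, pixel_cols: np.ndarray,
                     n_points: int | None = None) -> np.ndarray:
    """Resample a component outline to N equispaced-arc-length complex points.

    N defaults to the smallest power of two >= the boundary perimeter (so
    consecutive points are at most one pixel apart).
    """
    ring = component_boundary_polygon(pixel_rows, pixel_cols)
    perimeter = ring.length
    if n_points is None:
        n_points = max(4, next_power_of_two(int(np.ceil(perimeter))))
    elif n_points & (n_points - 1):
        raise ValueError("n_points must be a power of two")
    pts = [ring.interpolate(i * perimeter / n_points) for i in range(n_points)]
    xy = np.array([(p.x, p.y) for p in pts])
    return xy[:, 0] + 1j * xy[:, 1]


def fourier_descriptors(s: np.ndarray) -> np.ndarray:
    """DFT of the complex contour: S[k] = sum_n s[n] exp(-2*pi*j*k*n/N)."""
    s = np.asarray(s, dtype=np.complex128)
    n = s.size
    if n & (n - 1):
        raise ValueError("contour length must be a power of two")
    return np.fft.fft(s)


def retained_bins(n: int, p: int) -> np.ndarray:
    """Indices of the P lowest-|frequency| descriptors of an N-point DFT.

    Order: k=0, then the +/- pairs (k, N-k) by increasing k; when P is even
    the final pair is truncated to its positive-frequency bin k.
    """
    if p < 1:
        raise ValueError("must retain at least one descriptor")
    if p > n:
        raise ValueError("cannot retain more descriptors than exist")
    order = [0]
    k = 1
    while len(order) < n:
        order.append(k)
        if len(order) < n and (n - k) != k:
            order.append(n - k)
        k += 1
    return np.array(order[:p])


def descriptor_count_from_cutoff(n: int, f_c: float) -> int:
    """P = f_c * N rounded to the nearest integer, at least 1."""
    return max(1, int(round(f_c * n)))


def reconstruct_contour(S: np.ndarray, p: int | None = None,
                        f_c: float | None = None) -> np.ndarray:
    """Inverse DFT over the retained low-frequency descriptors only.

    Either a fixed descriptor count ``p`` or a frequency cutoff ``f_c``
    (giving P = round(f_c * N)) selects the retained bins.  With p == N the
    original contour is recovered exactly.
    """
    S = np.asarray(S, dtype=np.complex128)
    n = S.size
    if p is None:
        if f_c is None:
            raise ValueError("provide a descriptor count p or a cutoff f_c")
        p = descriptor_count_from_cutoff(n, f_c)
    keep = retained_bins(n, p)
    St = np.zeros_like(S)
    St[keep] = S[keep]
    return np.fft.ifft(St)


def smooth_contour(s: np.ndarray, p: int | None = None,
                   f_c: float | None = None) -> np.ndarray:
    """Descriptor-truncation smoothing of a closed complex contour."""
    return reconstruct_contour(fourier_descriptors(s), p=p, f_c=f_c)
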