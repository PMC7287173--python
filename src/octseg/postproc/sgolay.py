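"""Savitzky-Golay smoothing by local least-squares polynomial fits.

The filter output at each sample is the value of a degree-d polynomial fitted
by least squares over a symmetric window of N = 2M+1 samples.  In matrix
form, with basis vectors s_i(m) = m^i for -M <= m <= M stacked into
S (N x (d+1)), the projection

    B = S (S^T S)^{-1} S^T

maps a window onto its fitted values; the center column b_0 of B is the FIR
steady-state response.  The first and last M output samples (input-on /
input-off transients, where the sliding window would leave the signal) are
taken from the off-center columns of B applied to the first and last full
window, i.e. the fitted polynomial of that window evaluated at the transient
positions.  Consequently the filter reproduces any polynomial of degree <= d
exactly, transients included.

The dermo-epidermal junction baseline uses d = 1 with a large window
(449 samples) so that follicular invaginations are averaged out and only the
global trend of the junction remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SGFilterSpec:
    """Window length (odd, N = 2M+1) and polynomial order d, 0 <= d <= M."""

    window: int = 449
    order: int = 1

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        if not (0 <= self.order <= self.half_width):
            raise ValueError("order must satisfy 0 <= d <= M")

    @property
    def half_width(self) -> int:
        return self.window // 2


def sg_smoothing_matrix(spec: SGFilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """The N x N least-squares projection B and its center column b_0.

    B applied to a window returns the degree-d fit at every window position;
    b_0 is the steady-state FIR response (even-symmetric, so correlation and
    convolution coincide).
    """
    M = spec.half_width
    m = np.arange(-M, M + 1, dtype=np.float64)
    S = np.vander(m, spec.order + 1, increasing=True)  # columns s_i = m^i
    # solve (S^T S) C = S^T for the pseudo-inverse row block; SPD for d <= M
    B = S @ np.linalg.solve(S.T @ S, S.T)
    b0 = B[:, M].copy()
    return B, b0


def savitzky_golay(x: np.ndarray, spec: SGFilterSpec) -> np.ndarray:
    """Filter a 1-D signal; output length equals input length L (L >= N)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    L, N, M = x.size, spec.window, spec.half_width
    if L < N:
        raise ValueError(f"signal length {L} shorter than window {N}")
    B, b0 = sg_smoothing_matrix(spec)
    y = np.empty(L)
    # steady state: centered response slid over the interior samples
    y[M:L - M] = np.correlate(x, b0, mode="valid")
    if M > 0:
        # transients: first/last full window's fit at off-center positions
        y[:M] = (B @ x[:N])[:M]
        y[L - M:] = (B @ x[L - N:])[M + 1:]
    return y
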