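"""Bicubic interpolation: the Keys convolution kernel and a 2D resampler.

The kernel is the classic piecewise cubic

    W(x) = (a+2)|x|^3 - (a+3)|x|^2 + 1          for |x| <= 1
    W(x) = a|x|^3 - 5a|x|^2 + 8a|x| - 4a        for 1 < |x| < 2
    W(x) = 0                                    otherwise

with sharpness parameter ``a`` (default -0.5, for which the four weights
``W(k - t)``, k in {-1, 0, 1, 2}, sum to exactly 1 at every fractional
offset t, and the interpolant reproduces linear trends exactly).

A point inside the unit cell of a 4x4 sample neighborhood is interpolated
separably:  value = sum_ij a_ij * W(i - 1 - dx) * W(j - 1 - dy).

A second coefficient mode ("hermite") builds the bicubic surface from the
four corner heights of the inner cell and finite-difference estimates of the
slopes h'x, h'y and the cross derivative h''xy at each corner. With centered
differences this coincides with the a = -0.5 convolution kernel on interior
cells (Catmull-Rom), which the tests exploit as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "kernel_w", "interpolate_patch", "hermite_patch", "upsample"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel sharpness ``a``; support is fixed at |x| < 2."""

    a: float = -0.5


def kernel_w(x, spec: KernelSpec = KernelSpec()):
    """Evaluate the piecewise-cubic kernel W(x); accepts scalars or arrays."""
    a = spec.a
    ax = np.abs(np.asarray(x, dtype=float))
    near = (a + 2.0) * ax**3 - (a + 3.0) * ax**2 + 1.0
    far = a * ax**3 - 5.0 * a * ax**2 + 8.0 * a * ax - 4.0 * a
    out = np.where(ax <= 1.0, near, np.where(ax < 2.0, far, 0.0))
    return float(out) if np.isscalar(x) else out


def _weights(frac: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel weights for the 4 taps around each fractional position.

    ``frac`` in [0, 1) measures the query offset past sample index 1 of the
    4-tap window; tap i sits at distance |i - 1 - frac|.
    """
    taps = np.arange(4.0)
    return kernel_w(taps[None, :] - 1.0 - np.asarray(frac, dtype=float)[:, None], spec)


def interpolate_patch(
    patch: np.ndarray, dx: float, dy: float, spec: KernelSpec = KernelSpec()
) -> float:
    """Interpolate at fractional offset (dx, dy) inside a 4x4 neighborhood.

    ``patch[j, i]`` holds sample (row j, column i); the query point lies in
    the cell between samples (1, 1) and (2, 2), at offsets dx, dy in [0, 1).
    Integer offsets reproduce the samples exactly.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (4, 4):
        raise ValueError(f"patch must be 4x4, got {patch.shape}")
    wx = _weights(np.array([dx]), spec)[0]
    wy = _weights(np.array([dy]), spec)[0]
    return float(wy @ patch @ wx)


# -- Hermite (derivative-based) coefficient mode ----------------------------

# Inverse of the bicubic Hermite constraint matrix: maps the 16-vector
# [f, f_x, f_y, f_xy at corners (0,0),(1,0),(0,1),(1,1)] to polynomial
# coefficients a_ij of sum a_ij x^i y^j.
_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0], [-3.0, 3.0, -2.0, -1.0], [2.0, -2.0, 1.0, 1.0]])


def hermite_patch(
    patch: np.ndarray, dx: float, dy: float
) -> float:
    """Bicubic interpolation built from corner heights and finite-difference
    derivatives of the inner cell of a 4x4 neighborhood.

    The slopes h'x, h'y and the cross derivative h''xy at the four inner
    corners are estimated with centered differences from the surrounding
    samples; the 16 constraints determine the a_ij of the bicubic polynomial.
    """
    p = np.asarray(patch, dtype=float)
    if p.shape != (4, 4):
        raise ValueError(f"patch must be 4x4, got {p.shape}")

    def f(j, i):
        return p[j, i]

    def fx(j, i):
        return 0.5 * (p[j, i + 1] - p[j, i - 1])

    def fy(j, i):
        return 0.5 * (p[j + 1, i] - p[j - 1, i])

    def fxy(j, i):
        return 0.25 * (p[j + 1, i + 1] - p[j + 1, i - 1] - p[j - 1, i + 1] + p[j - 1, i - 1])

    # Constraints: rows carry the y-direction data (values then h'y), columns
    # the x-direction data, over the inner-cell corners (1,1)..(2,2).
    F = np.array(
        [
            [f(1, 1), f(1, 2), fx(1, 1), fx(1, 2)],
            [f(2, 1), f(2, 2), fx(2, 1), fx(2, 2)],
            [fy(1, 1), fy(1, 2), fxy(1, 1), fxy(1, 2)],
            [fy(2, 1), fy(2, 2), fxy(2, 1), fxy(2, 2)],
        ]
    )
    # Coefficients of sum_ij c[i, j] * dy^i * dx^j
    C = _H @ F @ _H.T
    ypow = np.array([1.0, dy, dy**2, dy**3])
    xpow = np.array([1.0, dx, dx**2, dx**3])
    return float(ypow @ C @ xpow)


def _pad_indices(idx: np.ndarray, n: int, edge: str) -> np.ndarray:
    if edge == "replicate":
        return np.clip(idx, 0, n - 1)
    if edge == "reflect":
        # reflect without repeating the edge sample: ..., 2, 1, 0, 1, 2, ...
        period = 2 * (n - 1) if n > 1 else 1
        idx = np.abs(idx) % period
        return np.where(idx >= n, period - idx, idx)
    raise ValueError(f"unknown edge mode {edge!r}")


def upsample(
    grid: np.ndarray,
    factor: float,
    spec: KernelSpec = KernelSpec(),
    edge: str = "replicate",
) -> np.ndarray:
    """Resample a 2D grid by a positive scale factor.

    Output size is ``round(input_size * factor)`` per axis. Output pixel
    centers map to input coordinates by the align-centers convention
    ``x_in = (x_out + 0.5) / factor - 0.5``; borders are extended by the
    chosen edge rule. Multi-channel input (H, W, C) is resampled per channel.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    g = np.asarray(grid, dtype=float)
    if g.ndim == 3:
        return np.stack([upsample(g[..., c], factor, spec, edge) for c in range(g.shape[-1])], axis=-1)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("grid must be 2D and at least 2x2")
    h, w = g.shape
    oh, ow = int(round(h * factor)), int(round(w * factor))

    def axis_terms(n_out: int, n_in: int):
        coords = (np.arange(n_out) + 0.5) / factor - 0.5
        base = np.floor(coords).astype(int)
        frac = coords - base
        taps = base[:, None] + np.arange(-1, 3)[None, :]
        return _pad_indices(taps, n_in, edge), _weights(frac, spec)

    iy, wy = axis_terms(oh, h)
    ix, wx = axis_terms(ow, w)
    rows = np.einsum("ot,otc->oc", wy, g[iy, :])  # (oh, w): rows resampled in y
    return np.einsum("pt,opt->op", wx, rows[:, ix])  # then in x -> (oh, ow)
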