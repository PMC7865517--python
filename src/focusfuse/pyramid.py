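"""Gaussian/Laplacian pyramids and level-wise multi-focus fusion.

The Gaussian pyramid is built by separable low-pass filtering with the
5-tap binomial kernel h = [1, 4, 6, 4, 1]/16 followed by factor-2
decimation (ceil semantics, so odd dimensions are supported at every
depth). Each Laplacian band is the difference between a Gaussian level
and the expanded next level,

    b_k = I_k - E[I_{k+1}],

which makes the decomposition exactly invertible: collapsing the bands
onto the residual reconstructs the source to floating-point rounding.

Fusion builds one pyramid per focal plane, selects the locally
highest-contrast coefficient at every band position across the seven
pyramids, combines the low-pass residuals, and reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .stackio import FocalStack

BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

__all__ = [
    "BINOMIAL5",
    "GaussianPyramid",
    "LaplacianPyramid",
    "FusionRule",
    "reduce_image",
    "expand_image",
    "build_gaussian_pyramid",
    "build_laplacian_pyramid",
    "collapse_laplacian_pyramid",
    "fuse_lp_stack",
    "max_levels",
]


@dataclass
class GaussianPyramid:
    """Low-pass levels [I0 .. IN], I0 = source image."""

    levels: list[np.ndarray]
    kernel: np.ndarray = field(default_factory=lambda: BINOMIAL5.copy())


@dataclass
class LaplacianPyramid:
    """Band-pass levels [b0 .. bN-1] plus the deepest low-pass residual."""

    bands: list[np.ndarray]
    residual: np.ndarray
    kernel: np.ndarray = field(default_factory=lambda: BINOMIAL5.copy())

    @property
    def n_levels(self) -> int:
        return len(self.bands)


@dataclass
class FusionRule:
    """Per-coefficient combination rules for band and residual levels.

    band_rule:
        ``salience-weighted`` (default) combines the seven coefficients
        with weights proportional to a power of their local energy
        (mean squared band value over an ``energy_window`` square) — the
        selection/averaging compromise of the classic LP-fusion
        literature. Where one plane clearly dominates (an in-focus edge)
        the weights approach pure selection; where activities tie (flat
        regions, where differences are sensor noise) they approach a
        plain average, which suppresses noise instead of amplifying it.
        ``max-local-energy`` hard-selects the coefficient with the
        largest local energy; ``max-abs`` selects the largest magnitude
        outright.
    residual_rule:
        ``mean`` (default) or ``max`` across the low-pass residuals.
    salience_exponent:
        Sharpness/denoising trade-off for ``salience-weighted``; higher
        values approach hard selection.
    """

    band_rule: str = "salience-weighted"
    residual_rule: str = "mean"
    energy_window: int = 5
    salience_exponent: float = 4.0

    def __post_init__(self) -> None:
        if self.band_rule not in ("max-abs", "max-local-energy", "salience-weighted"):
            raise ValueError(f"unknown band_rule {self.band_rule!r}")
        if self.residual_rule not in ("mean", "max"):
            raise ValueError(f"unknown residual_rule {self.residual_rule!r}")


def _as_kernel(kernel) -> np.ndarray:
    k = np.asarray(kernel, dtype=float)
    if k.ndim != 1 or k.size % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    return k


def reduce_image(img: np.ndarray, kernel=BINOMIAL5) -> np.ndarray:
    """Low-pass filter separably (reflect borders) and decimate by 2.

    Output dimensions are ``ceil(input / 2)`` on each axis.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {img.shape}")
    k = _as_kernel(kernel)
    sm = ndi.convolve1d(img, k, axis=0, mode="reflect")
    sm = ndi.convolve1d(sm, k, axis=1, mode="reflect")
    return sm[::2, ::2]


def _expand_axis(a: np.ndarray, n_out: int, kernel: np.ndarray, axis: int) -> np.ndarray:
    n = a.shape[axis]
    if n_out not in (2 * n, 2 * n - 1):
        raise ValueError(
            f"target length {n_out} incompatible with source length {n} "
            f"(must be 2n or 2n-1)"
        )
    a = np.moveaxis(a, axis, -1)
    r = len(kernel) // 2
    pad = [(0, 0)] * (a.ndim - 1) + [(r, r)]
    ap = np.pad(a, pad, mode="symmetric")
    up = np.zeros(ap.shape[:-1] + (2 * ap.shape[-1],), dtype=float)
    up[..., ::2] = ap
    conv = ndi.convolve1d(up, 2.0 * kernel, axis=-1, mode="constant")
    start = 2 * r
    out = conv[..., start : start + n_out]
    return np.moveaxis(out, -1, axis)


def expand_image(img: np.ndarray, target_shape: tuple[int, int], kernel=BINOMIAL5) -> np.ndarray:
    """Upsample-and-smooth to ``target_shape`` (the expand operator E).

    Zero-interleaves the samples and convolves with the gain-2 kernel
    2·h, padding symmetrically at the coarse-sample level so constants
    are exact fixed points everywhere, borders included. Each target axis
    must equal 2n or 2n−1 for source length n.
    """
    img = np.asarray(img, dtype=float)
    k = _as_kernel(kernel)
    out = _expand_axis(img, target_shape[0], k, axis=0)
    out = _expand_axis(out, target_shape[1], k, axis=1)
    return out


def max_levels(shape: tuple[int, int]) -> int:
    """Largest band count keeping the deepest Gaussian level >= 2x2."""
    n = 0
    h, w = shape
    while h >= 4 and w >= 4:  # reducing a >=4 side leaves >=2
        h = -(-h // 2)
        w = -(-w // 2)
        n += 1
    return n


def build_gaussian_pyramid(img: np.ndarray, n_levels: int, kernel=BINOMIAL5) -> GaussianPyramid:
    """Levels [I0 .. I_n_levels]; each level is reduce() of the previous."""
    img = np.asarray(img, dtype=float)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    cap = max_levels(img.shape)
    if n_levels > cap:
        raise ValueError(
            f"{n_levels} levels too deep for image of shape {img.shape}; "
            f"at most {cap} possible"
        )
    k = _as_kernel(kernel)
    levels = [img]
    for _ in range(n_levels):
        levels.append(reduce_image(levels[-1], k))
    return GaussianPyramid(levels=levels, kernel=k)


def build_laplacian_pyramid(img: np.ndarray, n_levels: int, kernel=BINOMIAL5) -> LaplacianPyramid:
    """Decompose into band-pass levels b_k = I_k − E[I_{k+1}] + residual."""
    gp = build_gaussian_pyramid(img, n_levels, kernel)
    bands = [
        gp.levels[k] - expand_image(gp.levels[k + 1], gp.levels[k].shape, gp.kernel)
        for k in range(n_levels)
    ]
    return LaplacianPyramid(bands=bands, residual=gp.levels[-1], kernel=gp.kernel)


def collapse_laplacian_pyramid(lp: LaplacianPyramid, clip: bool = True) -> np.ndarray:
    """Invert the decomposition: I_k = b_k + E[I_{k+1}], from the residual up."""
    img = lp.residual
    for band in reversed(lp.bands):
        exp = expand_image(img, band.shape, lp.kernel)
        img = band + exp
    return np.clip(img, 0.0, 1.0) if clip else img


def _select_bands(bands: np.ndarray, rule: FusionRule) -> np.ndarray:
    # bands: (n_images, H, W) at one pyramid level
    if rule.band_rule == "max-abs":
        idx = np.argmax(np.abs(bands), axis=0)
        return np.take_along_axis(bands, idx[None], axis=0)[0]
    energy = np.stack(
        [ndi.uniform_filter(b * b, size=rule.energy_window, mode="reflect")
         for b in bands]
    )
    if rule.band_rule == "max-local-energy":
        idx = np.argmax(energy, axis=0)
        return np.take_along_axis(bands, idx[None], axis=0)[0]
    w = (energy + 1e-12) ** rule.salience_exponent
    w /= w.sum(axis=0, keepdims=True)
    return (w * bands).sum(axis=0)


def fuse_lp_stack(
    stack: FocalStack | np.ndarray,
    n_levels: int = 5,
    rule: FusionRule | None = None,
    kernel=BINOMIAL5,
) -> np.ndarray:
    """Fuse the 7 focal planes by level-wise Laplacian-pyramid selection.

    Builds one pyramid per plane, keeps the highest-contrast coefficient
    at every band position (per ``rule``), combines the residuals, and
    reconstructs the all-in-focus image, clipped to [0, 1].
    """
    rule = rule or FusionRule()
    planes = stack.planes if isinstance(stack, FocalStack) else np.asarray(stack, float)
    pyramids = [build_laplacian_pyramid(p, n_levels, kernel) for p in planes]
    fused_bands = [
        _select_bands(np.stack([pyr.bands[k] for pyr in pyramids]), rule)
        for k in range(n_levels)
    ]
    residuals = np.stack([pyr.residual for pyr in pyramids])
    if rule.residual_rule == "mean":
        fused_res = residuals.mean(axis=0)
    else:
        fused_res = residuals.max(axis=0)
    fused = LaplacianPyramid(bands=fused_bands, residual=fused_res,
                             kernel=_as_kernel(kernel))
    return collapse_laplacian_pyramid(fused, clip=True)
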