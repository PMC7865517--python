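"""Six full-reference similarity metrics with one report object.

All metrics take two [0, 1]-scaled grayscale images of identical shape.
RMSE and PSNR are evaluated on the 8-bit scale (intensities ×255, peak
255) so that PSNR's conventional dB range applies; SAM, UQI, SSIM and
MS-SSIM are scale-free or defined on [0, 1] directly.

SSIM here uses the additive constants C1 = 0.01 and C2 = 0.03 literally
on the [0, 1] scale (not the K-factor parameterization squared against
the dynamic range), evaluated in a sliding 11×11 Gaussian-weighted
window (σ = 1.5) and averaged. UQI is the global (whole-image) universal
quality index; a windowed variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

#: MS-SSIM per-scale exponent weights (standard published values),
#: renormalized to the first n_scales entries at call time.
MS_SSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])

__all__ = [
    "MetricUndefinedError",
    "SimilarityReport",
    "rmse",
    "sam",
    "psnr",
    "uqi",
    "ssim",
    "ms_ssim",
    "similarity_report",
]


class MetricUndefinedError(ValueError):
    """A metric's denominator degenerates (constant or zero image)."""


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error on the 8-bit scale (0 = identical)."""
    x, y = _pair(x, y)
    d = 255.0 * (x - y)
    return float(np.sqrt(np.mean(d * d)))


def sam(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle (radians) between the images flattened to vectors.

    Each whole image is treated as a single vector with one component per
    pixel — the usual grayscale convention; 0 means identical direction,
    and the value is invariant to positive rescaling of either image.
    """
    x, y = _pair(x, y)
    u = x.ravel()
    v = y.ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise MetricUndefinedError("spectral angle undefined for an all-zero image")
    c = float(np.dot(u, v) / (nu * nv))
    return float(math.acos(min(1.0, max(-1.0, c))))


def sam_stack(planes_x: np.ndarray, planes_y: np.ndarray) -> float:
    """Mean per-pixel spectral angle treating a 7-plane stack as a spectrum.

    Diagnostic variant for stack-level comparison: each pixel contributes
    the angle between its 7-component spectra; pixels with a zero vector
    in either stack are excluded.
    """
    x = np.asarray(planes_x, dtype=float)
    y = np.asarray(planes_y, dtype=float)
    if x.shape != y.shape or x.ndim != 3:
        raise ValueError("expected two (n_planes, H, W) arrays of equal shape")
    nu = np.linalg.norm(x, axis=0)
    nv = np.linalg.norm(y, axis=0)
    ok = (nu > 0) & (nv > 0)
    if not np.any(ok):
        raise MetricUndefinedError("no pixel has a nonzero spectrum in both stacks")
    dot = np.sum(x * y, axis=0)
    c = np.clip(dot[ok] / (nu[ok] * nv[ok]), -1.0, 1.0)
    return float(np.mean(np.arccos(c)))


def psnr(x: np.ndarray, y: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio 20·log10(max/RMSE) in dB; inf if equal."""
    r = rmse(x, y)
    if r == 0.0:
        return math.inf
    return float(20.0 * math.log10(max_value / r))


def _global_stats(x: np.ndarray, y: np.ndarray):
    mx, my = float(x.mean()), float(y.mean())
    vx = float(np.mean((x - mx) ** 2))  # population variance
    vy = float(np.mean((y - my) ** 2))
    cov = float(np.mean((x - mx) * (y - my)))
    return mx, my, vx, vy, cov


def uqi(x: np.ndarray, y: np.ndarray, windowed: bool = False, window: int = 8) -> float:
    """Universal quality index; 1 for identical images.

    UQI = 4·σxy·μx·μy / ((σx²+σy²)(μx²+μy²)) with population statistics,
    computed over the whole image by default. ``windowed=True`` averages
    the index over sliding ``window``×``window`` neighborhoods instead.
    """
    x, y = _pair(x, y)
    if not windowed:
        mx, my, vx, vy, cov = _global_stats(x, y)
        den = (vx + vy) * (mx * mx + my * my)
        if den == 0.0:
            which = "variance" if (vx + vy) == 0.0 else "mean"
            raise MetricUndefinedError(
                f"UQI undefined: joint {which} statistic is zero"
            )
        return float(4.0 * cov * mx * my / den)
    f = lambda a: ndi.uniform_filter(a, size=window, mode="reflect")
    mx, my = f(x), f(y)
    vx = f(x * x) - mx * mx
    vy = f(y * y) - my * my
    cov = f(x * y) - mx * my
    den = (vx + vy) * (mx * mx + my * my)
    ok = den > 1e-12
    if not np.any(ok):
        raise MetricUndefinedError("UQI undefined everywhere: degenerate windows")
    q = 4.0 * cov[ok] * mx[ok] * my[ok] / den[ok]
    return float(np.mean(q))


def _windowed_maps(x, y, sigma, truncate):
    f = lambda a: ndi.gaussian_filter(a, sigma, truncate=truncate, mode="reflect")
    mx, my = f(x), f(y)
    vx = f(x * x) - mx * mx
    vy = f(y * y) - my * my
    cov = f(x * y) - mx * my
    return mx, my, vx, vy, cov


def _crop(a: np.ndarray, pad: int) -> np.ndarray:
    return a[pad:-pad, pad:-pad] if pad > 0 else a


_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5 -> 11x11 window


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    c1: float = 0.01,
    c2: float = 0.03,
    windowed: bool = True,
) -> float:
    """Structural similarity in [-1, 1]; 1 for identical images.

    SSIM = (2μxμy+C1)(2σxy+C2) / ((μx²+μy²+C1)(σx²+σy²+C2)), evaluated
    per 11×11 Gaussian-weighted window and averaged over the interior
    (a 5-px border is excluded, as is conventional). Images smaller than
    the window fall back to global statistics, logged.
    """
    x, y = _pair(x, y)
    if c1 <= 0 or c2 <= 0:
        raise ValueError("c1 and c2 must be positive")
    if windowed and min(x.shape) < 11:
        log.warning(
            "image %s smaller than the 11x11 SSIM window; using global statistics",
            x.shape,
        )
        windowed = False
    if not windowed:
        mx, my, vx, vy, cov = _global_stats(x, y)
        return float(
            (2 * mx * my + c1) * (2 * cov + c2)
            / ((mx * mx + my * my + c1) * (vx + vy + c2))
        )
    mx, my, vx, vy, cov = _windowed_maps(x, y, _SSIM_SIGMA, _SSIM_TRUNCATE)
    smap = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )
    return float(np.mean(_crop(smap, 5)))


def _downsample2(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    a = a[: h - h % 2, : w - w % 2]
    return 0.25 * (a[::2, ::2] + a[1::2, ::2] + a[::2, 1::2] + a[1::2, 1::2])


def ms_ssim(
    x: np.ndarray,
    y: np.ndarray,
    n_scales: int = 5,
    c1: float = 0.01,
    c2: float = 0.03,
) -> float:
    """Multi-scale SSIM in [0, 1]; 1 for identical images.

    Contrast/structure terms are averaged per scale (2× low-pass
    decimation between scales); luminance enters at the coarsest scale
    only. The standard per-scale exponents are renormalized to the first
    ``n_scales`` entries, so ``n_scales=1`` reduces exactly to SSIM.
    Negative mean contrast terms are floored at 0 before exponentiation.
    """
    x, y = _pair(x, y)
    if not 1 <= n_scales <= len(MS_SSIM_WEIGHTS):
        raise ValueError(f"n_scales must be in 1..{len(MS_SSIM_WEIGHTS)}")
    need = 11 * 2 ** (n_scales - 1)
    if min(x.shape) < need:
        feasible = max(1, int(math.floor(math.log2(min(x.shape) / 11))) + 1)
        raise ValueError(
            f"image of shape {x.shape} too small for {n_scales} scales "
            f"(needs min side >= {need}); at most {feasible} scales feasible"
        )
    w = MS_SSIM_WEIGHTS[:n_scales] / MS_SSIM_WEIGHTS[:n_scales].sum()
    result = 1.0
    for j in range(n_scales):
        last = j == n_scales - 1
        mx, my, vx, vy, cov = _windowed_maps(x, y, _SSIM_SIGMA, _SSIM_TRUNCATE)
        cs = (2 * cov + c2) / (vx + vy + c2)
        if last:
            lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
            term = float(np.mean(_crop(lum * cs, 5)))
        else:
            term = float(np.mean(_crop(cs, 5)))
        result *= max(0.0, term) ** w[j]
        if not last:
            x = _downsample2(x)
            y = _downsample2(y)
    return float(result)


@dataclass
class SimilarityReport:
    """The six metric values for one image pair (None if undefined)."""

    rmse: float | None
    sam: float | None
    psnr: float | None
    uqi: float | None
    ssim: float | None
    ms_ssim: float | None
    errors: dict[str, str] | None = None

    FIELDS = ("rmse", "sam", "psnr", "uqi", "ssim", "ms_ssim")

    def to_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self.FIELDS}

    def __str__(self) -> str:
        parts = []
        for name in self.FIELDS:
            v = getattr(self, name)
            parts.append(f"{name}={'n/a' if v is None else format(v, '.4f')}")
        return "SimilarityReport(" + ", ".join(parts) + ")"


def similarity_report(x: np.ndarray, y: np.ndarray, ms_scales: int | None = None) -> SimilarityReport:
    """Compute all six metrics; undefined metrics become None with a reason.

    ``ms_scales`` defaults to the deepest feasible ladder (at most 5) for
    the image size.
    """
    x, y = _pair(x, y)
    if ms_scales is None:
        ms_scales = max(1, min(5, int(math.floor(math.log2(min(x.shape) / 11))) + 1))
    values: dict[str, float | None] = {}
    errors: dict[str, str] = {}
    calls = {
        "rmse": lambda: rmse(x, y),
        "sam": lambda: sam(x, y),
        "psnr": lambda: psnr(x, y),
        "uqi": lambda: uqi(x, y),
        "ssim": lambda: ssim(x, y),
        "ms_ssim": lambda: ms_ssim(x, y, n_scales=ms_scales),
    }
    for name, call in calls.items():
        try:
            values[name] = call()
        except (MetricUndefinedError, ValueError) as exc:
            values[name] = None
            errors[name] = str(exc)
    return SimilarityReport(**values, errors=errors or None)
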