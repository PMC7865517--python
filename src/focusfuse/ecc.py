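"""ZNCC similarity, ECC gradient-based registration, align-then-average fusion.

The enhanced-correlation-coefficient (ECC) objective is the zero-mean
normalized cross-correlation between the template and the warped moving
image. Registration maximizes it by the forward-additive update of
Evangelidis & Psarakis: at each iteration the moving image and its
gradients are bilinearly sampled at the warped template coordinates, the
warp Jacobian is assembled, and the closed-form ECC parameter increment
is applied until the update norm drops below ``eps``.

Coordinates are (x, y) = (column, row); a warp maps template coordinates
to moving-image coordinates, so the registered image is
``moving(W(x))`` sampled on the template grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .stackio import FocalStack
from .pyramid import reduce_image

log = logging.getLogger(__name__)

MOTION_TYPES = ("translation", "euclidean", "affine", "homography")

__all__ = [
    "MOTION_TYPES",
    "WarpModel",
    "RegistrationResult",
    "ConstantImageError",
    "zncc",
    "ecc_register",
    "warp_image",
    "fuse_ecc",
]


class ConstantImageError(ValueError):
    """Similarity undefined because an image has zero variance."""


@dataclass
class WarpModel:
    """2-D geometric transform mapping template coords to moving coords.

    params layout by motion type:
      translation: (tx, ty)
      euclidean:   (theta, tx, ty)   -- rotation in radians about (0, 0)
      affine:      (a11, a12, a21, a22, tx, ty)
      homography:  8 entries of the 3x3 matrix, h33 fixed at 1
    """

    motion_type: str
    params: np.ndarray

    def __post_init__(self) -> None:
        if self.motion_type not in MOTION_TYPES:
            raise ValueError(f"unknown motion type {self.motion_type!r}")
        self.params = np.asarray(self.params, dtype=float).copy()

    @classmethod
    def identity(cls, motion_type: str) -> "WarpModel":
        n = {"translation": 2, "euclidean": 3, "affine": 6, "homography": 8}[motion_type]
        p = np.zeros(n)
        if motion_type == "affine":
            p[0] = p[3] = 1.0
        if motion_type == "homography":
            p[0] = p[4] = 1.0  # h11, h22
        return cls(motion_type, p)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of the warp."""
        p = self.params
        m = np.eye(3)
        if self.motion_type == "translation":
            m[0, 2], m[1, 2] = p
        elif self.motion_type == "euclidean":
            c, s = np.cos(p[0]), np.sin(p[0])
            m[:2, :] = [[c, -s, p[1]], [s, c, p[2]]]
        elif self.motion_type == "affine":
            m[:2, :] = [[p[0], p[1], p[4]], [p[2], p[3], p[5]]]
        else:
            m = np.array(
                [[p[0], p[1], p[2]], [p[3], p[4], p[5]], [p[6], p[7], 1.0]]
            )
        return m

    def apply(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map template coordinate arrays to moving-image coordinates."""
        m = self.matrix()
        xw = m[0, 0] * xs + m[0, 1] * ys + m[0, 2]
        yw = m[1, 0] * xs + m[1, 1] * ys + m[1, 2]
        if self.motion_type == "homography":
            d = m[2, 0] * xs + m[2, 1] * ys + 1.0
            xw, yw = xw / d, yw / d
        return xw, yw

    def inverse(self) -> "WarpModel":
        minv = np.linalg.inv(self.matrix())
        minv /= minv[2, 2]
        if self.motion_type == "translation":
            return WarpModel("translation", minv[:2, 2])
        if self.motion_type == "euclidean":
            theta = np.arctan2(minv[1, 0], minv[0, 0])
            return WarpModel("euclidean", [theta, minv[0, 2], minv[1, 2]])
        if self.motion_type == "affine":
            return WarpModel(
                "affine",
                [minv[0, 0], minv[0, 1], minv[1, 0], minv[1, 1], minv[0, 2], minv[1, 2]],
            )
        return WarpModel("homography", minv.ravel()[:8])


@dataclass
class RegistrationResult:
    warp: WarpModel
    final_score: float
    iterations_used: int
    converged: bool


def zncc(i1: np.ndarray, i2: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation in [-1, 1].

    (1/NM) Σij (I1 − μ1)(I2 − μ2) / (σ1 σ2) with population standard
    deviations; 1 for identical (up to positive affine intensity maps),
    −1 for sign-flipped patterns.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise ValueError(f"shape mismatch: {i1.shape} vs {i2.shape}")
    s1, s2 = i1.std(), i2.std()
    if s1 == 0.0 or s2 == 0.0:
        raise ConstantImageError("ZNCC undefined for a constant image")
    v = np.mean((i1 - i1.mean()) * (i2 - i2.mean())) / (s1 * s2)
    return float(np.clip(v, -1.0, 1.0))


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample at (x, y); returns values and in-bounds mask."""
    h, w = img.shape
    mask = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    vals = ndi.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return vals.reshape(xs.shape), mask


def warp_image(
    img: np.ndarray, warp: WarpModel, out_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``img`` on the template grid through ``warp``.

    Returns (warped, mask); mask marks pixels whose source coordinate was
    inside the moving image.
    """
    img = np.asarray(img, dtype=float)
    shape = out_shape or img.shape
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    xw, yw = warp.apply(xs, ys)
    vals, mask = _sample(img, xw, yw)
    return vals, mask


def _jacobian_cols(motion_type, xs, ys, params, gx, gy):
    """Steepest-descent images: columns of G = ∇I_w · dW/dp."""
    if motion_type == "translation":
        return [gx, gy]
    if motion_type == "euclidean":
        c, s = np.cos(params[0]), np.sin(params[0])
        dxdt = -s * xs - c * ys
        dydt = c * xs - s * ys
        return [gx * dxdt + gy * dydt, gx, gy]
    if motion_type == "affine":
        return [gx * xs, gx * ys, gy * xs, gy * ys, gx, gy]
    # homography
    h = np.concatenate([params, [1.0]]).reshape(3, 3)
    d = h[2, 0] * xs + h[2, 1] * ys + 1.0
    xw = (h[0, 0] * xs + h[0, 1] * ys + h[0, 2]) / d
    yw = (h[1, 0] * xs + h[1, 1] * ys + h[1, 2]) / d
    return [
        gx * xs / d, gx * ys / d, gx / d,
        gy * xs / d, gy * ys / d, gy / d,
        -(gx * xw + gy * yw) * xs / d,
        -(gx * xw + gy * yw) * ys / d,
    ]


def _ecc_single_scale(template, moving, warp, max_iters, eps):
    h, w = template.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    gy_full, gx_full = np.gradient(moving)

    def score_of(wm: WarpModel) -> float:
        iw, mask = warp_image(moving, wm, template.shape)
        t = template[mask]
        v = iw[mask]
        if t.std() == 0 or v.std() == 0:
            return -1.0
        return float(
            np.mean((t - t.mean()) * (v - v.mean())) / (t.std() * v.std())
        )

    best = WarpModel(warp.motion_type, warp.params)
    best_score = score_of(best)
    params = warp.params.copy()
    n_worse = 0
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        wm = WarpModel(warp.motion_type, params)
        xw, yw = wm.apply(xs, ys)
        iw, mask = _sample(moving, xw, yw)
        gx, _ = _sample(gx_full, xw, yw)
        gy, _ = _sample(gy_full, xw, yw)
        cols = _jacobian_cols(wm.motion_type, xs, ys, params, gx, gy)

        m = mask.ravel()
        t0 = template.ravel()[m]
        v0 = iw.ravel()[m]
        t0 = t0 - t0.mean()
        v0 = v0 - v0.mean()
        G = np.stack([c.ravel()[m] for c in cols], axis=1)
        G = G - G.mean(axis=0)

        H = G.T @ G
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        Gt = G.T @ t0
        Gv = G.T @ v0
        norm_v2 = float(v0 @ v0)
        den = float(t0 @ v0 - Gt @ Hinv @ Gv)
        num = float(norm_v2 - Gv @ Hinv @ Gv)
        if not np.isfinite(den) or not np.isfinite(num):
            break
        if den > 0:
            lam = num / den
        else:
            # images nearly uncorrelated at this warp; take the projected
            # update that keeps the step direction well defined
            lam = float(np.sqrt(max(num, 1e-30) / max(t0 @ t0 - Gt @ Hinv @ Gt, 1e-30)))
        err = lam * t0 - v0
        dp = Hinv @ (G.T @ err)
        params = params + dp

        sc = score_of(WarpModel(wm.motion_type, params))
        if np.isnan(sc):
            break
        if sc > best_score:
            best_score = sc
            best = WarpModel(wm.motion_type, params.copy())
            n_worse = 0
        else:
            n_worse += 1
            if n_worse >= 5:
                break
        if float(np.linalg.norm(dp)) < eps:
            converged = True
            break
    return RegistrationResult(best, best_score, it, converged)


def _halve_warp(wm: WarpModel) -> WarpModel:
    """Map a warp to the next-coarser pyramid level (translations halve)."""
    p = wm.params.copy()
    if wm.motion_type == "translation":
        p /= 2.0
    elif wm.motion_type == "euclidean":
        p[1:] /= 2.0
    elif wm.motion_type == "affine":
        p[4:] /= 2.0
    else:
        p[2] /= 2.0
        p[5] /= 2.0
        p[6] *= 2.0
        p[7] *= 2.0
    return WarpModel(wm.motion_type, p)


def _double_warp(wm: WarpModel) -> WarpModel:
    p = wm.params.copy()
    if wm.motion_type == "translation":
        p *= 2.0
    elif wm.motion_type == "euclidean":
        p[1:] *= 2.0
    elif wm.motion_type == "affine":
        p[4:] *= 2.0
    else:
        p[2] *= 2.0
        p[5] *= 2.0
        p[6] /= 2.0
        p[7] /= 2.0
    return WarpModel(wm.motion_type, p)


def ecc_register(
    template: np.ndarray,
    moving: np.ndarray,
    motion_type: str = "euclidean",
    max_iters: int = 50,
    eps: float = 1e-6,
    n_pyramid_levels: int = 1,
    init: WarpModel | None = None,
) -> RegistrationResult:
    """Estimate the warp maximizing the ECC between template and moving.

    Single-scale by default; ``n_pyramid_levels > 1`` runs a coarse-to-
    fine ladder (Gaussian pyramid, translations rescaled between levels)
    for larger displacements. The returned warp never scores below the
    initial warp (identity unless ``init`` is given): the best-so-far
    iterate is kept, with ``converged=False`` flagging runs stopped by
    divergence or the iteration cap.
    """
    template = np.asarray(template, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if template.shape != moving.shape:
        raise ValueError(f"shape mismatch: {template.shape} vs {moving.shape}")
    if template.std() == 0 or moving.std() == 0:
        raise ConstantImageError("cannot register a constant image")
    if motion_type not in MOTION_TYPES:
        raise ValueError(f"unknown motion type {motion_type!r}")

    warp = init or WarpModel.identity(motion_type)
    if n_pyramid_levels <= 1:
        return _ecc_single_scale(template, moving, warp, max_iters, eps)

    t_levels = [template]
    m_levels = [moving]
    for _ in range(n_pyramid_levels - 1):
        t_levels.append(reduce_image(t_levels[-1]))
        m_levels.append(reduce_image(m_levels[-1]))
    wm = warp
    for _ in range(n_pyramid_levels - 1):
        wm = _halve_warp(wm)
    res = None
    for lvl in range(n_pyramid_levels - 1, -1, -1):
        res = _ecc_single_scale(t_levels[lvl], m_levels[lvl], wm, max_iters, eps)
        wm = _double_warp(res.warp) if lvl > 0 else res.warp
    return res


def fuse_ecc(
    stack: FocalStack | np.ndarray,
    reference_index: int = 3,
    motion_type: str = "euclidean",
    max_iters: int = 50,
    eps: float = 1e-6,
    n_pyramid_levels: int = 1,
) -> np.ndarray:
    """Register every plane to the reference plane and average.

    Each non-reference plane is ECC-registered to the reference and
    resampled into its frame; the fused image is the per-pixel mean over
    the aligned planes, averaging only in-bounds contributions where a
    warp pushes a plane off the frame. A constant (zero-variance) plane
    cannot be registered and is averaged unregistered, logged.
    """
    planes = stack.planes if isinstance(stack, FocalStack) else np.asarray(stack, float)
    n = planes.shape[0]
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index must be in 0..{n - 1}")
    ref = planes[reference_index]
    acc = ref.astype(float).copy()
    cnt = np.ones_like(acc)
    for i in range(n):
        if i == reference_index:
            continue
        plane = planes[i]
        if plane.std() == 0 or ref.std() == 0:
            log.warning("plane %d is constant; averaging without registration", i)
            acc += plane
            cnt += 1.0
            continue
        res = ecc_register(
            ref, plane, motion_type=motion_type, max_iters=max_iters,
            eps=eps, n_pyramid_levels=n_pyramid_levels,
        )
        warped, mask = warp_image(plane, res.warp, ref.shape)
        acc[mask] += warped[mask]
        cnt[mask] += 1.0
    return np.clip(acc / cnt, 0.0, 1.0)
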