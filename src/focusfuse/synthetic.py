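"""Synthetic embryo-like focal stacks with known all-in-focus ground truth.

Each scene contains 1–8 translucent round "cells" at distinct optical
depths in [0, 1], rendered as anti-aliased discs with a bright membrane
ring, a darker band-limited interior texture, and a faint halo,
composited back-to-front over a vignetted background. A stack is the
scene imaged at 7 equispaced focus depths: a cell at depth d, imaged at
focus f, is defocused by a Gaussian PSF with

    sigma(d, f) = sigma_max * |d - f|

(so sigma = 0 in its own focal plane), and additive Gaussian sensor
noise is applied after compositing. The zero-blur, pre-noise render is
retained as ground truth, which no real embryo recording can provide —
that is what makes every fusion engine testable end to end.

All randomness flows from explicit seeds; a dataset is byte-identical
across runs with the same arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .pyramid import FusionRule, fuse_lp_stack, max_levels
from .stackio import N_PLANES, FocalStack

__all__ = [
    "SceneSpec",
    "Scene",
    "SyntheticStack",
    "random_scene",
    "make_scene",
    "render_stack",
    "make_dataset",
    "default_sigma_max",
]

ALLOWED_CELL_COUNTS = (1, 2, 4, 8)

#: radius range as a fraction of the frame side, per cell count
_RADIUS_FRACTIONS = {1: (0.26, 0.32), 2: (0.19, 0.24), 4: (0.14, 0.18), 8: (0.10, 0.13)}


def default_sigma_max(size: int) -> float:
    """Defocus blur at unit depth offset, scaled to resolution (size/16)."""
    return size / 16.0


@dataclass
class SceneSpec:
    """Geometry and imaging parameters of one synthetic scene."""

    size: int
    n_cells: int
    centers: np.ndarray  # (n, 2) as (x, y)
    radii: np.ndarray  # (n,)
    depths: np.ndarray  # (n,) in [0, 1]
    texture_seed: int = 0
    noise_sigma: float = 0.01
    vignette_strength: float = 0.15
    transparency: float = 0.6

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        if self.n_cells not in ALLOWED_CELL_COUNTS:
            raise ValueError(f"n_cells must be one of {ALLOWED_CELL_COUNTS}")
        if not (len(self.centers) == len(self.radii) == len(self.depths) == self.n_cells):
            raise ValueError("centers, radii, depths must each have n_cells entries")
        if np.any(self.depths < 0) or np.any(self.depths > 1):
            raise ValueError("depths must lie in [0, 1]")
        if self.n_cells >= 2 and np.ptp(self.depths) < 1e-9:
            raise ValueError("scenes with >= 2 cells need at least two distinct depths")
        margin = 2.0
        for (cx, cy), r in zip(self.centers, self.radii):
            if not (r + margin <= cx <= self.size - r - margin
                    and r + margin <= cy <= self.size - r - margin):
                raise ValueError(
                    f"cell at ({cx:.1f}, {cy:.1f}) r={r:.1f} violates the "
                    f"{margin:.0f}-px frame margin"
                )
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must be in [0, 1)")


def random_scene(
    n_cells: int,
    size: int = 64,
    seed: int | np.random.Generator = 0,
    noise_sigma: float = 0.01,
) -> SceneSpec:
    """Draw a valid random scene: overlapping discs, spread-out depths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = _RADIUS_FRACTIONS[n_cells]
    radii = rng.uniform(lo * size, hi * size, size=n_cells)
    centers = np.empty((n_cells, 2))
    # cluster centers loosely around the frame middle, like blastomeres in
    # a well; rejection-free draw inside the margin box
    for i, r in enumerate(radii):
        span = size - 2 * (r + 2.0)
        mid = size / 2.0
        sd = max(size * 0.13, 1.0)
        cx = np.clip(mid + sd * rng.standard_normal(), r + 2.0, r + 2.0 + span)
        cy = np.clip(mid + sd * rng.standard_normal(), r + 2.0, r + 2.0 + span)
        centers[i] = (cx, cy)
    if n_cells == 1:
        depths = rng.uniform(0.0, 1.0, size=1)
    else:
        # stratified depths guarantee distinctness and spread
        edges = np.linspace(0.0, 1.0, n_cells + 1)
        depths = edges[:-1] + rng.uniform(0.05, 0.95, size=n_cells) * np.diff(edges)
        rng.shuffle(depths)
    return SceneSpec(
        size=size, n_cells=n_cells, centers=centers, radii=radii, depths=depths,
        texture_seed=int(rng.integers(0, 2**31 - 1)), noise_sigma=noise_sigma,
    )


@dataclass
class Scene:
    """Renderable scene: background plus per-cell intensity/alpha layers."""

    spec: SceneSpec
    background: np.ndarray
    cell_layers: list[tuple[np.ndarray, np.ndarray]]  # (intensity, alpha) per cell
    order: np.ndarray  # composite order, back (far) to front (near)


def _render_cell(spec: SceneSpec, i: int, rng: np.random.Generator):
    size = spec.size
    (cx, cy), r = spec.centers[i], spec.radii[i]
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    dist = np.hypot(xs - cx, ys - cy)
    # anti-aliased disc with a faint halo just outside the membrane
    alpha = np.clip(r - dist + 0.5, 0.0, 1.0)
    halo = 0.35 * np.exp(-(((dist - r) / (0.08 * r + 1.0)) ** 2))
    alpha = np.maximum(alpha, np.where(dist > r, halo, 0.0))
    # bright membrane ring near the rim, darker textured interior
    ring = np.exp(-(((dist - 0.88 * r) / (0.07 * r + 0.5)) ** 2))
    texture = ndi.gaussian_filter(rng.standard_normal((size, size)), 1.5)
    texture = texture / (np.abs(texture).max() + 1e-12)
    radial = 1.0 - 0.25 * (dist / (r + 1e-9)) ** 2
    interior = np.clip(0.42 * radial + 0.10 * texture, 0.0, 1.0)
    intensity = np.clip(interior * (1.0 - ring) + 0.88 * ring, 0.0, 1.0)
    return intensity, alpha


def make_scene(spec: SceneSpec) -> Scene:
    """Deterministically render the scene layers (given texture_seed)."""
    rng = np.random.default_rng(spec.texture_seed)
    size = spec.size
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    rad2 = ((xs - size / 2) ** 2 + (ys - size / 2) ** 2) / (2 * (size / 2) ** 2)
    background = 0.55 * (1.0 - spec.vignette_strength * rad2)
    background += 0.02 * ndi.gaussian_filter(rng.standard_normal((size, size)), 3.0)
    background = np.clip(background, 0.0, 1.0)
    layers = [_render_cell(spec, i, rng) for i in range(spec.n_cells)]
    order = np.argsort(-spec.depths, kind="stable")  # far cells composited first
    return Scene(spec=spec, background=background, cell_layers=layers, order=order)


def _composite(scene: Scene, blur_sigmas: np.ndarray, bg_sigma: float) -> np.ndarray:
    spec = scene.spec
    img = (
        ndi.gaussian_filter(scene.background, bg_sigma)
        if bg_sigma > 0.05
        else scene.background.copy()
    )
    tau = spec.transparency
    for i in scene.order:
        intensity, alpha = scene.cell_layers[i]
        s = blur_sigmas[i]
        # blur premultiplied color, not the factors separately: over a
        # locally uniform backdrop the defocused composite then equals
        # the defocus of the sharp composite (light blurs additively)
        premult = intensity * alpha
        if s > 0.05:
            premult = ndi.gaussian_filter(premult, s)
            alpha = ndi.gaussian_filter(alpha, s)
        img = img * (1.0 - np.clip(alpha * tau, 0.0, 1.0)) + premult * tau
    return np.clip(img, 0.0, 1.0)


@dataclass
class SyntheticStack:
    """A rendered stack plus its privileged information."""

    stack: FocalStack
    ground_truth: np.ndarray
    depth_map: np.ndarray
    spec: SceneSpec


_BACKGROUND_DEPTH = 0.5


def render_stack(
    scene: Scene, sigma_max: float | None = None, n_planes: int = N_PLANES,
    stack_id: str = "synthetic",
) -> SyntheticStack:
    """Image the scene at ``n_planes`` equispaced focus depths in [0, 1].

    Per plane, each cell is blurred by sigma_max·|depth − focus| before
    compositing; sensor noise is added after. The ground truth is the
    zero-blur, noise-free composite of the same scene.
    """
    spec = scene.spec
    if sigma_max is None:
        sigma_max = default_sigma_max(spec.size)
    if sigma_max <= 0:
        raise ValueError("sigma_max must be positive")
    focus = np.linspace(0.0, 1.0, n_planes)
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.texture_seed, 7]))
    planes = []
    for f in focus:
        sigmas = sigma_max * np.abs(spec.depths - f)
        bg_sigma = sigma_max * abs(_BACKGROUND_DEPTH - f) * 0.5
        img = _composite(scene, sigmas, bg_sigma)
        if spec.noise_sigma > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sigma, img.shape)
        planes.append(np.clip(img, 0.0, 1.0))
    ground_truth = _composite(scene, np.zeros(spec.n_cells), 0.0)

    depth_map = np.full((spec.size, spec.size), _BACKGROUND_DEPTH)
    for i in scene.order:
        _, alpha = scene.cell_layers[i]
        depth_map[alpha > 0.5] = spec.depths[i]

    stack = FocalStack(
        planes=np.stack(planes), focal_distances=focus, stack_id=stack_id,
        cell_count=spec.n_cells if spec.n_cells in ALLOWED_CELL_COUNTS else None,
    )
    return SyntheticStack(stack=stack, ground_truth=ground_truth,
                          depth_map=depth_map, spec=spec)


def make_dataset(
    n_stacks: int,
    size: int = 64,
    seed: int = 0,
    split: float = 0.8,
    cell_counts: tuple[int, ...] = ALLOWED_CELL_COUNTS,
    sigma_max: float | None = None,
    noise_sigma: float = 0.01,
    lp_levels: int | None = None,
    lp_rule: FusionRule | None = None,
) -> tuple[list[tuple[SyntheticStack, np.ndarray]], list[tuple[SyntheticStack, np.ndarray]]]:
    """Generate (stack, LP-fused target) pairs and split train/test.

    Cell counts cycle through ``cell_counts`` in fixed proportion. Each
    stack's Laplacian-pyramid fusion (default configuration) is its
    training target, mirroring how focus-stacked references are produced
    when no ground truth exists. The random ``split`` (default 80/20) and
    all pixel data are fully determined by ``seed``.
    """
    if n_stacks < 5:
        raise ValueError("need at least 5 stacks for a meaningful split")
    if lp_levels is None:
        lp_levels = min(5, max_levels((size, size)))
    master = np.random.SeedSequence(seed)
    scene_seeds = master.spawn(n_stacks)
    pairs = []
    for i in range(n_stacks):
        n_cells = cell_counts[i % len(cell_counts)]
        rng = np.random.default_rng(scene_seeds[i])
        spec = random_scene(n_cells, size=size, seed=rng, noise_sigma=noise_sigma)
        sstack = render_stack(make_scene(spec), sigma_max=sigma_max,
                              stack_id=f"syn{i:04d}_c{n_cells}")
        target = fuse_lp_stack(sstack.stack, n_levels=lp_levels, rule=lp_rule)
        pairs.append((sstack, target))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    perm = rng.permutation(n_stacks)
    n_train = int(round(split * n_stacks))
    train = [pairs[i] for i in perm[:n_train]]
    test = [pairs[i] for i in perm[n_train:]]
    return train, test
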