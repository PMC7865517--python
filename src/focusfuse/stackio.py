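"""Image and focal-stack data model, readers/writers, and resizing.

Images are plain 2-D ``numpy`` arrays. On disk they are 8-bit unsigned
(PNG or TIFF); in memory every processing stage works on real values in
``[0, 1]``. A :class:`FocalStack` bundles the seven co-registered planes
captured at monotonically increasing focal distance that form the unit of
fusion input.

Plane indices are 0-based (``fp0`` .. ``fp6``); filenames using 1-based
labels (``fp1`` .. ``fp7``) are accepted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _skimage_resize

N_PLANES = 7

__all__ = [
    "N_PLANES",
    "FocalStack",
    "StackShapeError",
    "RangeError",
    "to_float",
    "to_uint8",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "resize_image",
    "resize_stack",
]


class StackShapeError(ValueError):
    """A focal stack does not have exactly 7 planes of identical shape."""


class RangeError(ValueError):
    """Pixel intensities fall outside the processed range [0, 1]."""


@dataclass
class FocalStack:
    """Seven single-channel planes ordered by increasing focal distance.

    Parameters
    ----------
    planes:
        Array of shape ``(7, H, W)`` with intensities in ``[0, 1]``.
    focal_distances:
        Monotonically increasing focus labels ``fd1 < ... < fd7``;
        defaults to 7 equispaced depths in ``[0, 1]``.
    stack_id:
        Free-form identifier used in filenames and report rows.
    cell_count:
        Optional annotation (1, 2, 4 or 8) used for evaluation grouping.
    """

    planes: np.ndarray
    focal_distances: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, N_PLANES)
    )
    stack_id: str = "stack"
    cell_count: int | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        self.focal_distances = np.asarray(self.focal_distances, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != N_PLANES:
            raise StackShapeError(
                f"a focal stack needs exactly {N_PLANES} planes, "
                f"got array of shape {self.planes.shape}"
            )
        if self.focal_distances.shape != (N_PLANES,):
            raise StackShapeError(
                f"need {N_PLANES} focal distances, got {self.focal_distances.shape}"
            )
        if np.any(np.diff(self.focal_distances) <= 0):
            raise StackShapeError("focal distances must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of every plane."""
        return self.planes.shape[1], self.planes.shape[2]

    def __iter__(self):
        return iter(self.planes)

    def __len__(self) -> int:
        return N_PLANES


def _check_range(img: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if lo < -tol or hi > 1.0 + tol:
        raise RangeError(
            f"intensities must lie in [0, 1]; found range [{lo:.6g}, {hi:.6g}]"
        )
    # forgive float round-off only
    return np.clip(img, 0.0, 1.0)


def to_float(img_u8: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities {0..255} to the processed scale [0, 1]."""
    return np.asarray(img_u8, dtype=float) / 255.0


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize [0, 1] intensities to {0..255} by round-half-up.

    Raises :class:`RangeError` on out-of-range input rather than clipping
    silently.
    """
    img = _check_range(img)
    # round-half-up: deterministic, independent of the banker's rounding
    # used by np.round
    return np.floor(img * 255.0 + 0.5).clip(0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read one 8-bit grayscale image into a [0, 1] float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) read of a gray file
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        arr = arr.astype(np.uint8)
    return to_float(arr)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 8-bit PNG or TIFF (chosen by extension)."""
    path = Path(path)
    u8 = to_uint8(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        iio.imwrite(path, u8)


_FP_RE = re.compile(r"fp(\d+)", re.IGNORECASE)


def _plane_files(directory: Path) -> list[Path]:
    files = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    # if every filename carries an fp<k> label, order by the label so that
    # both fp0..fp6 and fp1..fp7 conventions sort correctly
    labels = [_FP_RE.search(p.stem) for p in files]
    if files and all(m is not None for m in labels):
        files = [p for _, p in sorted(zip((int(m.group(1)) for m in labels), files))]
    return files


def read_stack(path: str | Path, stack_id: str | None = None) -> FocalStack:
    """Read a 7-plane focal stack.

    ``path`` is either a multi-page TIFF (7 pages, page order = focal
    order) or a directory of 7 PNG/TIFF planes ordered by their ``fp<k>``
    label (or lexicographically when unlabelled).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = _plane_files(path)
        if len(files) != N_PLANES:
            raise StackShapeError(
                f"expected {N_PLANES} plane files in {path}, found {len(files)}"
            )
        planes = [read_image(f) for f in files]
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise StackShapeError(f"mixed plane resolutions in {path}: {shapes}")
        arr = np.stack(planes)
        sid = stack_id or path.name
    else:
        pages = tifffile.imread(path)
        pages = np.asarray(pages)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != N_PLANES:
            raise StackShapeError(
                f"expected {N_PLANES} TIFF pages in {path}, found {pages.shape[0]}"
            )
        arr = to_float(pages.astype(np.uint8))
        sid = stack_id or path.stem
    return FocalStack(planes=arr, stack_id=sid)


def write_stack(
    stack: FocalStack, path: str | Path, layout: str = "multipage-tiff"
) -> None:
    """Write a stack as a 7-page TIFF or as a directory of PNG planes.

    Directory layout names planes ``<stack_id>_fp<k>.png`` with k in 0..6.
    """
    path = Path(path)
    u8 = np.stack([to_uint8(p) for p in stack.planes])
    if layout == "multipage-tiff":
        tifffile.imwrite(path, u8)
    elif layout == "plane-directory":
        path.mkdir(parents=True, exist_ok=True)
        for k, plane in enumerate(u8):
            iio.imwrite(path / f"{stack.stack_id}_fp{k}.png", plane)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def resize_image(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinearly resize a [0, 1] image to ``side``×``side``."""
    if side < 8:
        raise ValueError(f"side must be >= 8, got {side}")
    img = np.asarray(img, dtype=float)
    if img.shape == (side, side):
        return img.copy()
    out = _skimage_resize(
        img, (side, side), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def resize_stack(stack: FocalStack, side: int) -> FocalStack:
    """Resize every plane of a stack to ``side``×``side``."""
    planes = np.stack([resize_image(p, side) for p in stack.planes])
    return FocalStack(
        planes=planes,
        focal_distances=stack.focal_distances.copy(),
        stack_id=stack.stack_id,
        cell_count=stack.cell_count,
    )
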