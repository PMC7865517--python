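"""Desk-scale experimental comparison of the three fusion engines.

Runs LP, ECC, and (optionally) U-Net fusion on byte-identical synthetic
stacks over a grid of resolutions and cell counts, scores every output
with the six-metric suite against both the LP-fused reference (the
protocol usable on real data, where no ground truth exists) and the
synthetic ground truth (which only simulation affords), and writes
per-stack rows plus a mean ± 95% CI summary. Wall-clock timing is
available as an informational harness only — it is hardware-dependent
and never part of any quality claim.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _pkg_version
from .ecc import fuse_ecc
from .metrics import SimilarityReport, similarity_report
from .pyramid import FusionRule, fuse_lp_stack, max_levels
from .stackio import write_image
from .synthetic import make_scene, random_scene, render_stack
from .unet import UNet, fuse_unet

log = logging.getLogger(__name__)

__all__ = ["EvaluationGrid", "run_evaluation", "run_timing", "compare_report"]


@dataclass
class EvaluationGrid:
    """What to evaluate: the cross product of resolutions and cell counts."""

    resolutions: list[int] = field(default_factory=lambda: [64, 96, 128])
    cell_counts: list[int] = field(default_factory=lambda: [1, 2, 4, 8])
    n_stacks_per_cell: int = 5
    methods: list[str] = field(default_factory=lambda: ["lp", "ecc", "unet"])
    reference: str = "lp_target"
    seed: int = 0
    lp_levels: int | None = None
    ecc_motion: str = "euclidean"

    def __post_init__(self) -> None:
        if not self.resolutions or not self.cell_counts or not self.methods:
            raise ValueError("grid must be non-empty")
        bad = set(self.methods) - {"lp", "ecc", "unet"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.reference not in ("lp_target", "ground_truth"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @classmethod
    def from_yaml(cls, path) -> "EvaluationGrid":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _fuse(method: str, stack, grid: EvaluationGrid, net: UNet | None):
    if method == "lp":
        levels = grid.lp_levels or min(5, max_levels(stack.shape))
        return fuse_lp_stack(stack, n_levels=levels, rule=FusionRule())
    if method == "ecc":
        return fuse_ecc(stack, motion_type=grid.ecc_motion)
    return fuse_unet(net, stack)


def _iter_stacks(grid: EvaluationGrid, resolution: int, cell_count: int):
    base = np.random.SeedSequence([grid.seed, resolution, cell_count])
    for j, child in enumerate(base.spawn(grid.n_stacks_per_cell)):
        rng = np.random.default_rng(child)
        spec = random_scene(cell_count, size=resolution, seed=rng)
        yield j, render_stack(
            make_scene(spec), stack_id=f"r{resolution}_c{cell_count}_{j:03d}"
        )


def run_evaluation(
    grid: EvaluationGrid,
    run_dir,
    net: UNet | None = None,
    save_images: bool = True,
) -> pd.DataFrame:
    """Run the grid; returns the summary frame and writes CSV artifacts.

    Writes ``per_stack.csv`` (one row per stack × method × reference,
    the source of truth), ``summary.csv`` (mean, 95% t-CI half-width and
    n per method/resolution/cell-count/reference cell),
    ``resolved_config.yaml`` and ``run.log`` into ``run_dir``. When
    'unet' is requested without a network it is skipped with a warning
    and the remaining methods still run.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("focusfuse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        grid.to_yaml(run_dir / "resolved_config.yaml")
        methods = list(grid.methods)
        if "unet" in methods and net is None:
            log.warning("no U-Net weights supplied; skipping the 'unet' method")
            methods = [m for m in methods if m != "unet"]
        rows = []
        img_dir = run_dir / "images"
        if save_images:
            img_dir.mkdir(exist_ok=True)
        for resolution in grid.resolutions:
            for cell_count in grid.cell_counts:
                for j, ss in _iter_stacks(grid, resolution, cell_count):
                    lp_levels = grid.lp_levels or min(5, max_levels(ss.stack.shape))
                    lp_target = fuse_lp_stack(ss.stack, n_levels=lp_levels)
                    checksum = _checksum(ss.stack.planes)
                    references = {
                        "lp_target": lp_target,
                        "ground_truth": ss.ground_truth,
                    }
                    if save_images:
                        write_image(ss.ground_truth,
                                    img_dir / f"{ss.stack.stack_id}_gt.png")
                        for k, plane in enumerate(ss.stack.planes):
                            write_image(plane,
                                        img_dir / f"{ss.stack.stack_id}_fp{k}.png")
                    for method in methods:
                        fused = (lp_target if method == "lp"
                                 else _fuse(method, ss.stack, grid, net))
                        if save_images:
                            write_image(
                                fused, img_dir / f"{ss.stack.stack_id}_{method}.png"
                            )
                        for ref_name, ref_img in references.items():
                            rep = similarity_report(fused, ref_img)
                            rows.append({
                                "stack_id": ss.stack.stack_id,
                                "cell_count": cell_count,
                                "resolution": resolution,
                                "method": method,
                                "reference": ref_name,
                                "checksum": checksum,
                                **rep.to_dict(),
                            })
                    log.info("evaluated %s (%d methods)", ss.stack.stack_id,
                             len(methods))
        per_stack = pd.DataFrame(rows)
        per_stack.to_csv(run_dir / "per_stack.csv", index=False)
        summary = summarize(per_stack)
        summary.to_csv(run_dir / "summary.csv", index=False)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def summarize(per_stack: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Mean and t-based CI half-width per (method, resolution, cells, ref).

    Recomputable from per_stack.csv alone; infinite PSNR values (exact
    matches) are excluded from that metric's cell with a note in n.
    """
    keys = ["method", "resolution", "cell_count", "reference"]
    records = []
    for group_keys, g in per_stack.groupby(keys):
        rec = dict(zip(keys, group_keys))
        rec["n"] = len(g)
        for metric in SimilarityReport.FIELDS:
            vals = g[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                rec[f"{metric}_mean"] = np.nan
                rec[f"{metric}_ci"] = np.nan
                continue
            mean = float(np.mean(vals))
            if len(vals) > 1 and np.std(vals, ddof=1) > 0:
                half = float(
                    stats.t.ppf(0.5 + confidence / 2, len(vals) - 1)
                    * np.std(vals, ddof=1) / np.sqrt(len(vals))
                )
            else:
                half = 0.0
            rec[f"{metric}_mean"] = mean
            rec[f"{metric}_ci"] = half
        records.append(rec)
    return pd.DataFrame(records)


def run_timing(grid: EvaluationGrid, run_dir, net: UNet | None = None,
               repeats: int = 10) -> pd.DataFrame:
    """Median wall-clock per fusion call, per (method, resolution).

    Informational only: timings depend on the host and are never used as
    a quality gate. Machine metadata is recorded alongside.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    methods = [m for m in grid.methods if m != "unet" or net is not None]
    rows = []
    for resolution in grid.resolutions:
        _, ss = next(_iter_stacks(grid, resolution, grid.cell_counts[0]))
        for method in methods:
            times = []
            for _ in range(repeats):
                t0 = time.perf_counter()
                _fuse(method, ss.stack, grid, net)
                times.append(time.perf_counter() - t0)
            rows.append({
                "method": method,
                "resolution": resolution,
                "median_s": float(np.median(times)),
                "repeats": repeats,
            })
    df = pd.DataFrame(rows)
    meta = {
        "note": "informational only; wall-clock depends on the host machine",
        "platform": platform.platform(),
        "python": platform.python_version(),
        "focusfuse": _pkg_version,
    }
    df.to_csv(run_dir / "timing.csv", index=False)
    (run_dir / "timing_meta.json").write_text(json.dumps(meta, indent=2))
    return df


def compare_report(run_dir) -> list[Path]:
    """Panel images (7 planes + fused outputs + ground truth) per stack.

    Requires a completed :func:`run_evaluation` with ``save_images=True``.
    Also writes ``report.txt`` noting which method minimizes RMSE to
    ground truth per stack. Panels cover whichever methods completed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stackio import read_image

    run_dir = Path(run_dir)
    img_dir = run_dir / "images"
    per_stack = pd.read_csv(run_dir / "per_stack.csv")
    panels = []
    lines = []
    panel_dir = run_dir / "panels"
    panel_dir.mkdir(exist_ok=True)
    gt_rows = per_stack[per_stack["reference"] == "ground_truth"]
    for stack_id, g in gt_rows.groupby("stack_id"):
        best = g.loc[g["rmse"].idxmin()]
        lines.append(
            f"{stack_id}: best RMSE-to-ground-truth = {best['method']} "
            f"({best['rmse']:.3f})"
        )
        methods = sorted(g["method"].unique())
        tiles = [(f"fp{k}", img_dir / f"{stack_id}_fp{k}.png") for k in range(7)]
        tiles += [(m.upper(), img_dir / f"{stack_id}_{m}.png") for m in methods]
        tiles += [("truth", img_dir / f"{stack_id}_gt.png")]
        tiles = [(t, p) for t, p in tiles if p.exists()]
        if not tiles:
            continue
        ncols = 4
        nrows = -(-len(tiles) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.4 * nrows))
        for ax in np.ravel(axes):
            ax.axis("off")
        for ax, (title, p) in zip(np.ravel(axes), tiles):
            ax.imshow(read_image(p), cmap="gray", vmin=0, vmax=1)
            ax.set_title(title, fontsize=8)
            ax.axis("off")
        out = panel_dir / f"{stack_id}.png"
        fig.savefig(out, dpi=100, bbox_inches="tight")
        plt.close(fig)
        panels.append(out)
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return panels
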