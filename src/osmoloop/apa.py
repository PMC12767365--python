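"""Aggregate Hi-C analysis: loop pileups, enrichment scores, rescaled domains.

All statistics run on **raw** counts; balanced matrices are for display
only. The enrichment score is exactly

    median(foreground + 1) / median(background + 1)

with the foreground at the window center (single pixel or 3×3) and the
background either the top-left + bottom-right corner boxes — which sit at
approximately the same genomic distance as the loop pixel, controlling for
distance decay — or the ring of pixels at Chebyshev distance w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io import ContactMatrix, LoopSet, WindowOutOfBounds, snap_to_grid

__all__ = [
    "AggregateBlock",
    "ScaledAggregate",
    "EnrichmentScore",
    "apa",
    "enrichment",
    "background_normalize",
    "scaled_domain_aggregate",
    "diagonal_profile",
    "timecourse_enrichment",
    "standardize_loops",
]


@dataclass
class AggregateBlock:
    """Mean pileup matrix over included loop windows."""

    matrix: np.ndarray
    half_width: int
    n_used: int
    n_excluded: int
    resolution: int
    exclusions: dict[str, int] = field(default_factory=dict)


@dataclass
class ScaledAggregate:
    """Span-rescaled mean pileup: each window unit-normalized, then averaged."""

    matrix: np.ndarray
    n_used: int
    n_excluded: int
    buffer: float


@dataclass(frozen=True)
class EnrichmentScore:
    value: float
    fg_mode: str
    bg_mode: str

    def __float__(self) -> float:
        return self.value


def apa(
    matrices: Mapping[str, ContactMatrix],
    loops: LoopSet,
    half_width: int = 10,
    min_rowsum: float = 1.0,
) -> AggregateBlock:
    """Aggregate peak analysis: mean of raw-count windows centered on loop pixels.

    Exclusion rules (tallied in ``exclusions``): inter-chromosomal loops;
    loops whose window would overlap the matrix diagonal (span ≤ 2w+1
    bins); windows extending outside the bin grid; windows whose center row
    or center column sums below ``min_rowsum`` (dead anchor bins). The
    aggregate is the arithmetic mean over included windows (normalized by
    loop number).
    """
    if not matrices:
        raise ValueError("no contact matrices supplied")
    resolution = next(iter(matrices.values())).genome.resolution
    gridded = snap_to_grid(loops, resolution)
    b1, b2 = gridded.anchor_bins(resolution)
    w = half_width
    side = 2 * w + 1
    acc = np.zeros((side, side))
    tally = {"inter_chromosomal": 0, "near_diagonal": 0, "out_of_bounds": 0,
             "low_signal": 0}
    n_used = 0
    for (row, i, j) in zip(gridded.df.itertuples(index=False), b1, b2):
        if row.chrom1 != row.chrom2 or row.chrom1 not in matrices:
            tally["inter_chromosomal"] += 1
            continue
        if j - i <= side:
            tally["near_diagonal"] += 1
            continue
        try:
            block = matrices[row.chrom1].window(int(i), int(j), w)
        except WindowOutOfBounds:
            tally["out_of_bounds"] += 1
            continue
        if block[w, :].sum() < min_rowsum or block[:, w].sum() < min_rowsum:
            tally["low_signal"] += 1
            continue
        acc += block
        n_used += 1
    n_excluded = sum(tally.values())
    if n_used == 0:
        raise ValueError(f"no loops usable for APA; exclusions: {tally}")
    return AggregateBlock(acc / n_used, w, n_used, n_excluded, resolution, tally)


def _fg_bg(
    block: np.ndarray, fg_mode: str, bg_mode: str, corner_size: int
) -> tuple[np.ndarray, np.ndarray]:
    side = block.shape[0]
    if side != block.shape[1] or side % 2 == 0:
        raise ValueError("block must be square with odd side")
    if side < 2 * corner_size + 1:
        raise ValueError(f"block side {side} < 2*corner_size+1 = {2 * corner_size + 1}")
    w = side // 2
    if fg_mode == "center":
        fg = block[w : w + 1, w : w + 1]
    elif fg_mode == "center3x3":
        fg = block[w - 1 : w + 2, w - 1 : w + 2]
    else:
        raise ValueError(f"unknown fg_mode {fg_mode!r}")
    if bg_mode == "corners":
        cs = corner_size
        bg = np.concatenate([block[:cs, :cs].ravel(), block[-cs:, -cs:].ravel()])
    elif bg_mode == "ring":
        ii, jj = np.indices(block.shape)
        cheb = np.maximum(np.abs(ii - w), np.abs(jj - w))
        bg = block[cheb == w]
    else:
        raise ValueError(f"unknown bg_mode {bg_mode!r}")
    return fg.ravel(), bg


def enrichment(
    block: np.ndarray | AggregateBlock,
    fg_mode: str = "center",
    bg_mode: str = "corners",
    corner_size: int = 3,
) -> EnrichmentScore:
    """median(foreground + 1) / median(background + 1), exactly."""
    mat = block.matrix if isinstance(block, AggregateBlock) else np.asarray(block)
    fg, bg = _fg_bg(mat, fg_mode, bg_mode, corner_size)
    value = float((np.median(fg) + 1.0) / (np.median(bg) + 1.0))
    return EnrichmentScore(value, fg_mode, bg_mode)


def background_normalize(
    block: np.ndarray | AggregateBlock, corner_size: int = 3
) -> np.ndarray:
    """Scale a block so the corner-median background sits at 1.

    Uses the same +1 guard as the enrichment formula — (M+1)/(median+1) —
    so the normalized center equals enrichment(center, corners) exactly.
    """
    mat = block.matrix if isinstance(block, AggregateBlock) else np.asarray(block)
    _, bg = _fg_bg(mat, "center", "corners", corner_size)
    return (mat + 1.0) / (np.median(bg) + 1.0)


def scaled_domain_aggregate(
    matrices: Mapping[str, ContactMatrix],
    loops: LoopSet,
    buffer: float = 0.5,
    min_span_bp: int = 150_000,
    out_size: int = 100,
) -> ScaledAggregate:
    """Span-rescaled domain aggregate.

    Per loop: extract the square window spanning the loop plus a
    ``buffer``·span margin on both sides, bilinear-resize it to
    ``out_size``² with corner-aligned sampling, divide by its total, and
    average across loops. Loops below ``min_span_bp`` (default: medium to
    long range, ≥ 150 kb), out-of-bounds windows, and all-zero windows are
    excluded and tallied.
    """
    if not matrices:
        raise ValueError("no contact matrices supplied")
    resolution = next(iter(matrices.values())).genome.resolution
    gridded = snap_to_grid(loops, resolution)
    b1, b2 = gridded.anchor_bins(resolution)
    acc = np.zeros((out_size, out_size))
    n_used = 0
    n_excluded = 0
    for (row, i, j) in zip(gridded.df.itertuples(index=False), b1, b2):
        span = int(j - i)
        if (
            row.chrom1 != row.chrom2
            or row.chrom1 not in matrices
            or span * resolution < min_span_bp
            or span < 2
        ):
            n_excluded += 1
            continue
        pad = int(round(buffer * span))
        lo, hi = int(i) - pad, int(j) + pad
        mat = matrices[row.chrom1]
        if lo < 0 or hi >= mat.n_bins:
            n_excluded += 1
            continue
        # extract [lo, hi] x [lo, hi] via the symmetric sparse matrix
        sym = mat._symmetric()
        window = np.asarray(sym[lo : hi + 1, lo : hi + 1].todense(), dtype=float)
        resized = bilinear_resize(window, out_size)
        total = resized.sum()
        if total <= 0:
            n_excluded += 1
            continue
        acc += resized / total
        n_used += 1
    if n_used == 0:
        raise ValueError("no loops usable for domain aggregate")
    return ScaledAggregate(acc / n_used, n_used, n_excluded, buffer)


def bilinear_resize(window: np.ndarray, out_size: int) -> np.ndarray:
    """Corner-aligned bilinear resize; identity when sizes already match."""
    window = np.asarray(window, dtype=float)
    if window.shape == (out_size, out_size):
        return window.copy()
    src = window.shape[0]
    coords = np.linspace(0.0, src - 1.0, out_size)
    jj, ii = np.meshgrid(coords, coords)
    return map_coordinates(window, [ii, jj], order=1, mode="nearest")


def diagonal_profile(
    aggregate: np.ndarray | ScaledAggregate | AggregateBlock, corner_size: int = 3
) -> np.ndarray:
    """Main-diagonal trace normalized to the corner-median background (+1 guard)."""
    if isinstance(aggregate, (ScaledAggregate, AggregateBlock)):
        mat = aggregate.matrix
    else:
        mat = np.asarray(aggregate)
    cs = corner_size
    bg = np.concatenate([mat[:cs, :cs].ravel(), mat[-cs:, -cs:].ravel()])
    return (np.diagonal(mat) + 1.0) / (np.median(bg) + 1.0)


def timecourse_enrichment(
    matrices_by_time: Mapping[float, Mapping[str, ContactMatrix]],
    loops_by_class: Mapping[str, LoopSet],
    half_width: int = 10,
    fg_mode: str = "center",
    bg_mode: str = "corners",
) -> tuple[pd.DataFrame, float | None]:
    """Per-class APA enrichment at every time point.

    Returns a (class × time) table of enrichment values and the Pearson
    correlation between the ``gained`` and ``lost``/``preexisting`` curves
    (None when fewer than two time points or either class is absent).
    """
    times = sorted(matrices_by_time)
    curves = {}
    for klass, loops in loops_by_class.items():
        vals = []
        for t in times:
            block = apa(matrices_by_time[t], loops, half_width=half_width)
            vals.append(enrichment(block, fg_mode, bg_mode).value)
        curves[klass] = vals
    table = pd.DataFrame(curves, index=pd.Index(times, name="time")).T
    corr: float | None = None
    lost_key = "lost" if "lost" in curves else ("preexisting" if "preexisting" in curves else None)
    if "gained" in curves and lost_key and len(times) >= 2:
        g = np.asarray(curves["gained"])
        l = np.asarray(curves[lost_key])
        if np.std(g) > 0 and np.std(l) > 0:
            corr = float(np.corrcoef(g, l)[0, 1])
    return table, corr


def standardize_loops(
    loops: LoopSet, target_span: int = 150_000, resolution: int = 10_000
) -> LoopSet:
    """Replace each loop by one of exactly ``target_span`` centered on its midpoint.

    The output anchors are one bin wide on the grid; the loop-pixel midpoint
    is preserved to within one bin.
    """
    f = loops.df
    mid1 = (f.start1 + f.end1).to_numpy() // 2
    mid2 = (f.start2 + f.end2).to_numpy() // 2
    center = (mid1 + mid2) // 2
    new_m1 = center - target_span // 2
    new_m2 = center + target_span // 2
    b1 = new_m1 // resolution
    b2 = new_m2 // resolution
    df = f.copy()
    df["start1"] = b1 * resolution
    df["end1"] = (b1 + 1) * resolution
    df["start2"] = b2 * resolution
    df["end2"] = (b2 + 1) * resolution
    return LoopSet(df)
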