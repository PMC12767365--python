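"""Merging, classifying and overlapping loop anchors.

Loops are merged across replicates/conditions by DBSCAN on the 2-D points
(anchor1.start, anchor2.start) with Manhattan distance and min_samples = 1,
which makes clusters the transitive closure of the "within ε" relation —
no loop is ever discarded as noise. Classification of treated-condition
loops as de novo vs pre-existing, promoter/feature overlap fractions, and
at-anchor vs within-loop peak labels follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import DBSCAN

from .io import LoopSet

__all__ = [
    "OverlapReport",
    "merge_loops_dbscan",
    "classify_de_novo",
    "anchor_feature_overlap",
    "locate_peaks",
]


@dataclass
class OverlapReport:
    """Per-loop de novo / shared-anchor labels with summary fractions."""

    fraction_de_novo: float
    fraction_shared_anchor: float  # denominator: focal loops
    fraction_shared_anchor_anchors: float  # denominator: focal anchors
    labels: pd.DataFrame


def merge_loops_dbscan(
    loopsets: list[LoopSet] | LoopSet,
    eps_bp: int = 20_000,
    min_pts: int = 1,
    resolution: int = 10_000,
) -> pd.DataFrame:
    """Merge loop calls across sets by DBSCAN (Manhattan distance, ε inclusive).

    Returns a table with one row per input loop: ``source`` (index of the
    originating set), ``member`` (row within it), anchor starts, and
    ``cluster`` id, plus the representative anchors (member-wise median
    snapped to the bin grid). Clustering runs separately per chromosome
    pair; output ordering is deterministic by (chrom, rep1, rep2).
    """
    if isinstance(loopsets, LoopSet):
        loopsets = [loopsets]
    frames = []
    for si, ls in enumerate(loopsets):
        d = ls.df[["chrom1", "start1", "chrom2", "start2"]].copy()
        d["source"] = si
        d["member"] = np.arange(len(d))
        frames.append(d)
    allloops = pd.concat(frames, ignore_index=True)
    if allloops.empty:
        raise ValueError("no loops to merge")
    out_parts = []
    next_cluster = 0
    for (c1, c2), grp in allloops.groupby(["chrom1", "chrom2"], sort=True):
        pts = grp[["start1", "start2"]].to_numpy(dtype=float)
        labels = DBSCAN(eps=eps_bp, min_samples=min_pts, metric="manhattan").fit(pts).labels_
        # min_pts = 1 guarantees no noise label; guard anyway
        noise = labels == -1
        if noise.any():
            labels = labels.copy()
            labels[noise] = labels.max() + 1 + np.arange(noise.sum())
        g = grp.copy()
        reps = {}
        for lab in np.unique(labels):
            m = labels == lab
            r1 = int(np.median(pts[m, 0]) // resolution) * resolution
            r2 = int(np.median(pts[m, 1]) // resolution) * resolution
            reps[lab] = (r1, r2)
        g["rep1"] = [reps[l][0] for l in labels]
        g["rep2"] = [reps[l][1] for l in labels]
        g["_lab"] = labels
        out_parts.append(g)
    out = pd.concat(out_parts, ignore_index=True)
    out = out.sort_values(["chrom1", "rep1", "rep2", "source", "member"], ignore_index=True)
    # stable cluster ids in output order
    seen: dict[tuple, int] = {}
    cluster_ids = []
    for key in zip(out.chrom1, out.chrom2, out._lab, out.rep1, out.rep2):
        if key not in seen:
            seen[key] = next_cluster
            next_cluster += 1
        cluster_ids.append(seen[key])
    out["cluster"] = cluster_ids
    return out.drop(columns="_lab")


def classify_de_novo(
    focal: LoopSet, reference: LoopSet, slack_bp: int = 10_000
) -> OverlapReport:
    """Label focal loops as pre-existing vs de novo relative to a reference set.

    A focal loop is *pre-existing* when some reference loop on the same
    chromosome pair has both anchors within ``slack_bp`` of the focal
    anchors (order-respecting); it *shares an anchor* when at least one
    reference anchor lies within slack of either focal anchor. The
    anchor-denominator variant counts matched focal anchors over all focal
    anchors.
    """
    if len(focal) == 0:
        raise ValueError("empty focal loop set")
    f = focal.df
    r = reference.df
    pre = np.zeros(len(f), dtype=bool)
    a1_shared = np.zeros(len(f), dtype=bool)
    a2_shared = np.zeros(len(f), dtype=bool)
    ref_by_pair = dict(tuple(r.groupby(["chrom1", "chrom2"], sort=False)))
    ref_anchor_by_chrom: dict[str, np.ndarray] = {}
    for chrom, starts in pd.concat(
        [r[["chrom1", "start1"]].rename(columns={"chrom1": "c", "start1": "s"}),
         r[["chrom2", "start2"]].rename(columns={"chrom2": "c", "start2": "s"})]
    ).groupby("c"):
        ref_anchor_by_chrom[chrom] = np.sort(starts.s.to_numpy())
    def near(sorted_arr: np.ndarray, x: int) -> bool:
        k = np.searchsorted(sorted_arr, x)
        for t in (k - 1, k):
            if 0 <= t < len(sorted_arr) and abs(int(sorted_arr[t]) - x) <= slack_bp:
                return True
        return False
    for idx, row in enumerate(f.itertuples(index=False)):
        pair = ref_by_pair.get((row.chrom1, row.chrom2))
        if pair is not None:
            hit = (
                (np.abs(pair.start1.to_numpy() - row.start1) <= slack_bp)
                & (np.abs(pair.start2.to_numpy() - row.start2) <= slack_bp)
            )
            pre[idx] = bool(hit.any())
        arr1 = ref_anchor_by_chrom.get(row.chrom1)
        arr2 = ref_anchor_by_chrom.get(row.chrom2)
        a1_shared[idx] = arr1 is not None and near(arr1, int(row.start1))
        a2_shared[idx] = arr2 is not None and near(arr2, int(row.start2))
    shared_loop = a1_shared | a2_shared
    labels = pd.DataFrame(
        {
            "pre_existing": pre,
            "de_novo": ~pre,
            "anchor1_shared": a1_shared,
            "anchor2_shared": a2_shared,
            "shares_anchor": shared_loop,
        }
    )
    n = len(f)
    return OverlapReport(
        fraction_de_novo=float((~pre).mean()),
        fraction_shared_anchor=float(shared_loop.mean()),
        fraction_shared_anchor_anchors=float(
            (a1_shared.sum() + a2_shared.sum()) / (2 * n)
        ),
        labels=labels,
    )


def _feature_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp.start, grp.end) if e > s
        )
    return trees


def anchor_feature_overlap(
    loops: LoopSet,
    intervals: pd.DataFrame,
    labels: np.ndarray | pd.Series | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of loop anchors whose half-open interval hits any feature.

    When per-loop class ``labels`` are supplied the returned frame also
    carries per-class anchor-overlap fractions in ``.attrs['per_class']``.
    """
    trees = _feature_trees(intervals)
    f = loops.df
    hits1 = np.array(
        [bool(trees.get(c) and trees[c].overlap(int(s), int(e)))
         for c, s, e in zip(f.chrom1, f.start1, f.end1)]
    )
    hits2 = np.array(
        [bool(trees.get(c) and trees[c].overlap(int(s), int(e)))
         for c, s, e in zip(f.chrom2, f.start2, f.end2)]
    )
    flags = pd.DataFrame({"anchor1": hits1, "anchor2": hits2})
    fraction = float(np.concatenate([hits1, hits2]).mean()) if len(f) else 0.0
    if labels is not None:
        per_class = {}
        lab = np.asarray(labels)
        for k in pd.unique(lab):
            m = lab == k
            per_class[str(k)] = float(np.concatenate([hits1[m], hits2[m]]).mean())
        flags.attrs["per_class"] = per_class
    return fraction, flags


def locate_peaks(
    peaks: pd.DataFrame, loops: LoopSet, resolution: int = 10_000
) -> pd.Series:
    """Label each peak ``at_anchor`` / ``within_loop`` / ``outside``.

    A peak is at an anchor when its midpoint falls in either (gridded)
    anchor bin of any loop; within a loop when its midpoint bin lies
    strictly between the two anchor bins on the same chromosome. At-anchor
    takes precedence for peaks satisfying both via nested loops.
    """
    f = loops.df
    b1 = (f.start1 + f.end1).to_numpy() // 2 // resolution
    b2 = (f.start2 + f.end2).to_numpy() // 2 // resolution
    anchor_bins: dict[str, set[int]] = {}
    interior: dict[str, list[tuple[int, int]]] = {}
    for chrom, x, y in zip(f.chrom1, b1, b2):
        anchor_bins.setdefault(chrom, set()).update((int(x), int(y)))
        interior.setdefault(chrom, []).append((int(x), int(y)))
    out = []
    for row in peaks.itertuples(index=False):
        mid_bin = (int(row.start) + int(row.end)) // 2 // resolution
        if mid_bin in anchor_bins.get(row.chrom, ()):
            out.append("at_anchor")
        elif any(x < mid_bin < y for x, y in interior.get(row.chrom, ())):
            out.append("within_loop")
        else:
            out.append("outside")
    return pd.Series(out, index=peaks.index, name="location")
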