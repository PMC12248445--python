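"""Spatial segmentation by hierarchical divisive clustering of rank spectra.

Pixels are partitioned by a divisive scheme: each pixel's feature vector is
replaced by its within-pixel ranks (making the method invariant to per-pixel
intensity scaling and robust to outlier peaks); starting from a single
segment, the segment with the largest heterogeneity — the sum of squared
deviations of its member rank vectors from the segment mean — is repeatedly
bisected by 2-means until the requested number of segments is reached or no
segment remains splittable.  The 2-means is initialized by splitting on the
sign of the leading-principal-component projection (with a deterministic
eigenvector sign convention), so the procedure involves no randomness.

Segments are matched to histology tissue types by majority overlap with a
label mask, reporting per-segment purity and the adjusted Rand index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .msi_io import FeatureMatrix
from .synthetic_data import BACKGROUND, TissuePhantom

logger = logging.getLogger("lipidmsi")

__all__ = ["SegmentationResult", "divisive_rank_segment", "match_segments_to_mask", "merge_segments_by_tissue"]


@dataclass
class SegmentationResult:
    """Per-pixel segment labels plus per-segment mean spectra and split tree."""

    labels: np.ndarray  # segment id per pixel (row of the feature matrix)
    n_segments: int
    segment_means: dict[int, np.ndarray]  # mean *intensity* vector per segment
    split_tree: dict  # nested {segment, heterogeneity, children: [...]}
    pixel_index: list[tuple[int, int]] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None

    def label_grid(self) -> np.ndarray:
        """Segment ids painted on the raster; background = -1."""
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        grid = np.full(self.grid_shape, -1, dtype=np.int64)
        for (r, c), lab in zip(self.pixel_index, self.labels):
            grid[r, c] = lab
        return grid


def _heterogeneity(ranks: np.ndarray, idx: np.ndarray) -> float:
    sub = ranks[idx]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def _pc_split(sub: np.ndarray) -> np.ndarray | None:
    """Initial bipartition: sign of the projection on the leading principal
    component (deterministic; the eigenvector sign is fixed by making its
    largest-magnitude entry positive).  Returns None when degenerate."""
    centered = sub - sub.mean(axis=0)
    # leading right-singular vector of the centered matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return None
    pc = vt[0]
    pivot = int(np.argmax(np.abs(pc)))
    if pc[pivot] < 0:
        pc = -pc
    proj = centered @ pc
    side = proj > 0
    if side.all() or not side.any():
        return None
    return side


def _bisect(sub: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means on the rows of ``sub``; returns bool membership
    of the second cluster.  Initialized from the leading-principal-component
    sign split, then refined by Lloyd iterations."""
    side = _pc_split(sub)
    if side is None:  # no variance to split on
        return np.zeros(sub.shape[0], dtype=bool)
    centers = np.stack([sub[~side].mean(axis=0), sub[side].mean(axis=0)])
    assign = np.zeros(sub.shape[0], dtype=np.int64)
    for it in range(max_iter):
        d0 = ((sub - centers[0]) ** 2).sum(axis=1)
        d1 = ((sub - centers[1]) ** 2).sum(axis=1)
        new = (d1 < d0).astype(np.int64)  # ties -> cluster 0 (lower seed index)
        if it > 0 and np.array_equal(new, assign):
            break
        assign = new
        for k in (0, 1):
            members = assign == k
            if members.any():
                centers[k] = sub[members].mean(axis=0)
    return assign.astype(bool)


def divisive_rank_segment(matrix: FeatureMatrix, k: int, seed: int | None = None,
                  min_segment_size: int = 10, heterogeneity_eps: float = 1e-9
                  ) -> SegmentationResult:
    """Divisive rank-based segmentation into at most ``k`` segments.

    ``seed`` is accepted for interface stability; the principal-component
    initialization makes the procedure fully deterministic, so it is unused.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = matrix.n_pixels
    if k > n:
        raise ValueError("k exceeds the number of pixels")
    ranks = rankdata(matrix.dense_values(), axis=1, method="average")
    labels = np.zeros(n, dtype=np.int64)
    tree: dict = {"segment": 0, "heterogeneity": _heterogeneity(ranks, np.arange(n)),
                  "children": []}
    nodes = {0: tree}
    het = {0: tree["heterogeneity"]}
    next_id = 1
    unsplittable: set[int] = set()
    while len(het) < k:
        candidates = {s: h for s, h in het.items() if s not in unsplittable
                      and h > heterogeneity_eps
                      and int((labels == s).sum()) > min_segment_size}
        if not candidates:
            warnings.warn(
                f"requested {k} segments, produced {len(het)}: no segment "
                "remains splittable", stacklevel=2)
            break
        target = max(sorted(candidates), key=lambda s: candidates[s])
        idx = np.flatnonzero(labels == target)
        side = _bisect(ranks[idx])
        if side.all() or not side.any():  # degenerate split
            unsplittable.add(target)
            continue
        a, b = next_id, next_id + 1
        next_id += 2
        labels[idx[~side]] = a
        labels[idx[side]] = b
        het.pop(target)
        het[a] = _heterogeneity(ranks, idx[~side])
        het[b] = _heterogeneity(ranks, idx[side])
        children = [{"segment": a, "heterogeneity": het[a], "children": []},
                    {"segment": b, "heterogeneity": het[b], "children": []}]
        nodes[target]["children"] = children
        nodes[a], nodes[b] = children
    # relabel to compact 0..m-1 in order of first pixel occurrence
    order = {old: new for new, old in enumerate(dict.fromkeys(labels.tolist()))}
    labels = np.array([order[v] for v in labels])

    def _relabel(node):
        node["segment"] = order.get(node["segment"], node["segment"])
        for ch in node["children"]:
            _relabel(ch)

    _relabel(tree)
    dense = matrix.dense_values()
    means = {s: dense[labels == s].mean(axis=0) for s in np.unique(labels)}
    return SegmentationResult(labels, int(labels.max()) + 1, means, tree,
                              list(matrix.pixel_index), matrix.grid_shape)


def match_segments_to_mask(result: SegmentationResult, phantom: TissuePhantom
                           ) -> dict:
    """Assign each segment to a tissue label by majority overlap.

    Returns ``{"assignment": segment -> tissue label, "purity": segment ->
    fraction, "ari": adjusted Rand index}`` over non-background pixels.
    """
    if result.grid_shape != phantom.grid_shape:
        raise ValueError("segmentation grid does not match phantom grid")
    truth = np.array([phantom.label_grid[r, c] for r, c in result.pixel_index])
    keep = truth != BACKGROUND
    seg = result.labels[keep]
    tis = truth[keep]
    assignment: dict[int, int] = {}
    purity: dict[int, float] = {}
    for s in np.unique(seg):
        members = tis[seg == s]
        vals, counts = np.unique(members, return_counts=True)
        best = int(vals[np.argmax(counts)])
        assignment[int(s)] = best
        purity[int(s)] = float(counts.max() / counts.sum())
    ari = float(adjusted_rand_score(tis, seg))
    return {"assignment": assignment, "purity": purity, "ari": ari}


def merge_segments_by_tissue(result: SegmentationResult, phantom: TissuePhantom
                             ) -> tuple[np.ndarray, dict]:
    """Collapse segments onto their majority tissue label.

    Used when k exceeds the number of tissue types: profiling then proceeds
    per tissue type rather than per raw segment.  Returns the per-pixel tissue
    labels and the match report.
    """
    report = match_segments_to_mask(result, phantom)
    tissue = np.array([report["assignment"][int(s)] for s in result.labels])
    return tissue, report
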