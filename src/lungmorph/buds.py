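"""Skeleton analysis of the epithelium and peripheral bud counting.

The epithelial mask is thinned to a one-pixel-wide, 8-connected skeleton.
Degree-1 skeleton pixels are the branched ends; walking inward from a
branched end through degree-2 pixels reaches its parent, the first junction
pixel (degree >= 3).  A branched end counts toward the bud total only when
it lies near the outer contour — closer than 25% of the vertical extent of
the explant — and by default the number of buds is the number of DISTINCT
parents over those qualifying ends (sibling tips sharing a junction count
once); endpoints on a junction-free path count as their own bud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import InvalidInputError

log = logging.getLogger(__name__)

__all__ = ["SkeletonGraph", "BudCount", "skeletonize", "parent_of", "count_buds"]

SENTINEL: tuple[int, int] = (-1, -1)  # parent of an endpoint on a junction-free path

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _degree_image(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant", cval=0) * skel


@dataclass
class SkeletonGraph:
    """Skeleton pixels with classified endpoints and junctions."""

    skeleton_mask: np.ndarray
    endpoints: list[tuple[int, int]] = field(default_factory=list)
    branch_nodes: list[tuple[int, int]] = field(default_factory=list)
    endpoint_parent: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)


def _walk_to_junction(
    skel: np.ndarray, degree: np.ndarray, endpoint: tuple[int, int]
) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """Walk from an endpoint through degree-2 pixels; return (parent, path)."""
    h, w = skel.shape
    path = [endpoint]
    prev = None
    cur = endpoint
    visited = {endpoint}
    while True:
        if degree[cur] >= 3 and cur != endpoint:
            return cur, path[:-1]
        nxt = None
        for dr, dc in _NEIGH:
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and skel[r, c] and (r, c) != prev and (r, c) not in visited:
                nxt = (r, c)
                break
        if nxt is None:
            return SENTINEL, path
        prev = cur
        cur = nxt
        visited.add(cur)
        path.append(cur)


def _prune_spurs(skel: np.ndarray, min_length: int) -> np.ndarray:
    """Remove skeleton branches shorter than ``min_length`` pixels.

    Only spurs attached to a junction are removed; a junction-free skeleton
    (a simple path) is left intact regardless of length.
    """
    skel = skel.copy()
    for _ in range(8):  # pruning can expose new short spurs; few passes suffice
        degree = _degree_image(skel)
        eps = list(zip(*np.nonzero(degree == 1)))
        removed = False
        for ep in eps:
            if not skel[ep]:
                continue
            parent, path = _walk_to_junction(skel, degree, ep)
            if parent != SENTINEL and len(path) < min_length:
                for p in path:
                    skel[p] = False
                removed = True
        if not removed:
            break
    return skel


def skeletonize(mask: np.ndarray, min_spur: int = 3) -> SkeletonGraph:
    """Thin a mask to its skeleton and classify endpoints and junctions.

    Topology-preserving morphological thinning (iterative boundary/corner
    removal) down to a 1-px, 8-connected skeleton; branches shorter than
    ``min_spur`` pixels are pruned as boundary-noise artifacts before
    classification.  Endpoints have exactly one skeleton neighbor, branch
    nodes three or more; each endpoint maps to its parent junction (or the
    sentinel ``(-1, -1)`` when the skeleton has no junction).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    skel = _sk_skeletonize(mask)
    if min_spur > 0:
        skel = _prune_spurs(skel, min_spur)
    degree = _degree_image(skel)
    endpoints = [tuple(p) for p in np.argwhere(degree == 1)]
    branch_nodes = [tuple(p) for p in np.argwhere(degree >= 3)]
    graph = SkeletonGraph(skeleton_mask=skel, endpoints=endpoints, branch_nodes=branch_nodes)
    for ep in endpoints:
        parent, _ = _walk_to_junction(skel, degree, ep)
        graph.endpoint_parent[ep] = parent
    return graph


def parent_of(endpoint: tuple[int, int], graph: SkeletonGraph) -> tuple[int, int]:
    """Parent junction of a branched end (sentinel if the path has none)."""
    ep = tuple(endpoint)
    if ep not in graph.endpoint_parent:
        raise InvalidInputError(f"{ep} is not an endpoint of the skeleton")
    return graph.endpoint_parent[ep]


@dataclass
class BudCount:
    """Peripheral bud count with the filter that produced it."""

    n_buds: int
    qualifying_endpoints: list[tuple[int, int]]
    vertical_extent: int
    distance_cutoff: float


def count_buds(
    graph: SkeletonGraph,
    outer: np.ndarray,
    count_mode: str = "parents",
    periphery_fraction: float = 0.25,
) -> BudCount:
    """Count peripheral airway buds from the skeleton and outer mask.

    An endpoint qualifies when its Euclidean distance to the nearest
    outer-contour pixel is below ``periphery_fraction`` times the vertical
    extent (bounding-box height) of the outer mask.  ``count_mode`` selects
    the reading: ``"parents"`` counts distinct parent junctions over
    qualifying endpoints (sentinel-parent endpoints each count themselves),
    ``"endpoints"`` counts the qualifying endpoints directly.
    """
    if count_mode not in ("parents", "endpoints"):
        raise InvalidInputError(f"unknown count_mode {count_mode!r}")
    outer = np.asarray(outer, dtype=bool)
    rows = np.nonzero(outer.any(axis=1))[0]
    if rows.size == 0:
        raise InvalidInputError("empty outer mask")
    vertical_extent = int(rows[-1] - rows[0] + 1)
    cutoff = periphery_fraction * vertical_extent
    contour = outer & ~ndimage.binary_erosion(outer)
    dist_to_contour = ndimage.distance_transform_edt(~contour)
    if not graph.endpoints:
        log.warning("skeleton has no endpoints; bud count is 0")
        return BudCount(0, [], vertical_extent, cutoff)
    qualifying = [ep for ep in graph.endpoints if dist_to_contour[ep] < cutoff]
    if count_mode == "endpoints":
        n = len(qualifying)
    else:
        # a junction is a connected clump of branch pixels; two endpoints whose
        # parent pixels touch share one junction and count once
        branch_mask = _degree_image(graph.skeleton_mask) >= 3
        junction_lab, _ = ndimage.label(branch_mask, structure=np.ones((3, 3)))
        parents = set()
        n_sentinel = 0
        for ep in qualifying:
            par = graph.endpoint_parent[ep]
            if par == SENTINEL:
                n_sentinel += 1  # junction-free path: the tip is its own bud
            else:
                parents.add(int(junction_lab[par]))
        n = len(parents) + n_sentinel
    return BudCount(n, qualifying, vertical_extent, cutoff)
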