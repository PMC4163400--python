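"""Seeded clustering of primitive regions under minimum description length.

The epithelium is darker than the surrounding mesenchyme, so seeds are found
by sliding a circular kernel outward along the eight centroid rays and
keeping, per ray, the position of minimum kernel mean intensity.  Clusters
grow greedily from the seed regions: a neighboring primitive region R_n is
merged into cluster C_i when the description-length gain

    G = nR_n H(R_n) + nC_i H(C_i) - nC_new H(C_new) + b1 + nb * b2

is positive — the extra bits needed to code the pooled intensities are repaid
by no longer coding the shared boundary (b1 bits for its starting point, b2
per chain-code element, nb shared elements).  At every step the candidate
with the largest positive gain anywhere is merged (greedy, deterministic
ties), and clusters that become adjacent union when their mutual gain is
positive.  Candidates are restricted to a local circular window of at most
``window_max_regions`` primitive regions around the query region, which keeps
the statistics local and avoids merging distant outlier regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial import cKDTree

from ._util import disk_offsets as _disk_offsets
from ._util import shannon_entropy_bits
from .errors import InvalidMergeError, SegmentationFailureError
from .outer_contour import RayFan
from .partition import PrimitiveRegion, adjacency_boundary_counts

log = logging.getLogger(__name__)

__all__ = [
    "Seed",
    "Cluster",
    "BitCosts",
    "LocalWindow",
    "select_seeds",
    "region_bits",
    "merge_gain",
    "build_local_window",
    "grow_clusters",
]


@dataclass(frozen=True)
class Seed:
    """A cluster starting point on one of the eight rays."""

    ray_index: int  # 1..8
    location: tuple[int, int]
    region_id: int
    kernel_mean: float


@dataclass
class Cluster:
    """A growing union of primitive regions with pooled statistics."""

    id: int
    region_ids: set[int]
    pixel_count: int
    histogram: np.ndarray
    entropy: float  # recomputed from the pooled histogram, never averaged
    boundary: int  # external boundary length (4-adjacent chain elements)

    @classmethod
    def from_region(cls, cid: int, r: PrimitiveRegion) -> "Cluster":
        return cls(
            id=cid,
            region_ids={r.id},
            pixel_count=r.pixel_count,
            histogram=r.histogram.astype(np.int64).copy(),
            entropy=r.entropy,
            boundary=r.boundary_length,
        )

    @property
    def bits(self) -> float:
        return self.pixel_count * self.entropy


@dataclass(frozen=True)
class BitCosts:
    """Bit costs of the boundary code: b1 per starting point, b2 per element."""

    b1: float
    b2: float = 3.0  # 8-direction chain code

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("bit costs must be positive")

    @classmethod
    def for_image(cls, shape: tuple[int, int]) -> "BitCosts":
        return cls(b1=float(math.ceil(math.log2(shape[0] * shape[1]))))


@dataclass(frozen=True)
class LocalWindow:
    """Circular query window of at most ``max_regions`` regions."""

    center_region: int
    member_ids: frozenset[int]
    max_regions: int = 100


def _kernel_mean_image(img: np.ndarray, radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    k = (dr * dr + dc * dc <= radius * radius).astype(float)
    num = convolve(np.asarray(img, dtype=float), k, mode="constant", cval=0.0)
    den = convolve(np.ones_like(img, dtype=float), k, mode="constant", cval=0.0)
    return num / den


def select_seeds(
    img: np.ndarray,
    fan: RayFan,
    outer: np.ndarray,
    labels: np.ndarray,
    kernel_radius: float = 8.0,
) -> list[Seed]:
    """One seed per ray: the kernel position of minimum mean intensity.

    A circular kernel of ``kernel_radius`` slides from the centroid outward
    along each ray while its center stays inside the outer mask; the winning
    position is the one minimizing the kernel mean (ties resolve to the
    position nearest the centroid).  The seed itself is anchored to the
    darkest pixel inside the winning kernel, which pins it to epithelial
    tissue even when the kernel is wider than the branch it straddles.
    Seeds landing in an already-seeded primitive region are deduplicated.
    Fewer than 2 seeds from distinct rays is a failure; deduplication alone
    may leave a single seed (the epithelium already forms one region).
    """
    outer = np.asarray(outer, dtype=bool)
    img = np.asarray(img, dtype=float)
    h, w = outer.shape
    means = _kernel_mean_image(img, kernel_radius)
    offsets = np.array(sorted((int(dr), int(dc)) for dr, dc in map(tuple, _disk_offsets(kernel_radius))))
    cr, cc = fan.centroid
    seeds: list[Seed] = []
    n_rays_hit = 0
    taken_regions: set[int] = set()
    for i, (drow, dcol) in enumerate(fan.directions(), start=1):
        best: tuple[float, tuple[int, int]] | None = None
        t = 0.0
        while True:
            r = int(round(cr + t * drow))
            c = int(round(cc + t * dcol))
            if not (0 <= r < h and 0 <= c < w) or not outer[r, c]:
                break
            m = float(means[r, c])
            if best is None or m < best[0]:
                best = (m, (r, c))
            t += 1.0
        if best is None:
            log.warning("ray %d has no position inside the outer mask; skipped", i)
            continue
        n_rays_hit += 1
        kernel_mean, center = best
        rows = np.clip(center[0] + offsets[:, 0], 0, h - 1)
        cols = np.clip(center[1] + offsets[:, 1], 0, w - 1)
        inside = outer[rows, cols]
        if inside.any():
            rows, cols = rows[inside], cols[inside]
        k = int(np.argmin(img[rows, cols]))
        loc = (int(rows[k]), int(cols[k]))
        rid = int(labels[loc])
        if rid in taken_regions:
            log.info("seed on ray %d falls in already-seeded region %d; deduplicated", i, rid)
            continue
        taken_regions.add(rid)
        seeds.append(Seed(ray_index=i, location=loc, region_id=rid, kernel_mean=kernel_mean))
    if n_rays_hit < 2:
        raise SegmentationFailureError(f"only {n_rays_hit} rays produced candidates; need at least 2")
    if len(seeds) < 2:
        log.warning("deduplication left %d seed(s); epithelium already coherent", len(seeds))
    if not seeds:
        raise SegmentationFailureError("no seeds found")
    return seeds


def region_bits(r: PrimitiveRegion | Cluster) -> float:
    """Bits to code a region's intensities: pixel count times entropy."""
    return r.pixel_count * r.entropy


def merge_gain(
    rn: PrimitiveRegion | Cluster,
    ci: Cluster,
    nb: int,
    costs: BitCosts,
) -> float:
    """Description-length gain of merging region ``rn`` into cluster ``ci``.

    ``nb`` is the number of shared boundary chain elements.  Positive gain
    means the pooled intensity code grows by less than the b1 + nb*b2 bits
    saved on the vanished common boundary.
    """
    if nb < 1:
        raise InvalidMergeError("regions share no boundary; merge undefined")
    pooled = np.asarray(rn.histogram, dtype=np.int64) + np.asarray(ci.histogram, dtype=np.int64)
    n_new = rn.pixel_count + ci.pixel_count
    h_new = shannon_entropy_bits(pooled)
    return region_bits(rn) + region_bits(ci) - n_new * h_new + costs.b1 + nb * costs.b2


def build_local_window(
    rn: PrimitiveRegion,
    all_regions: list[PrimitiveRegion],
    outer: np.ndarray,
    max_regions: int = 100,
) -> LocalWindow:
    """Grow a circle at ``rn``'s centroid until it holds ``max_regions`` regions.

    Membership is by centroid inclusion and only regions whose centroids lie
    inside the outer mask participate, so the window never extends past the
    outer contour.
    """
    outer = np.asarray(outer, dtype=bool)
    inside = [
        r
        for r in all_regions
        if outer[int(round(r.centroid[0])), int(round(r.centroid[1]))] or r.id == rn.id
    ]
    d = [math.dist(r.centroid, rn.centroid) for r in inside]
    order = np.argsort(d, kind="stable")
    members = frozenset(inside[j].id for j in order[:max_regions])
    return LocalWindow(center_region=rn.id, member_ids=members, max_regions=max_regions)


class _GrowState:
    """Mutable bookkeeping for the greedy growth loop."""

    def __init__(
        self,
        regions: list[PrimitiveRegion],
        seeds: list[Seed],
        outer: np.ndarray,
        costs: BitCosts,
        pair_counts: dict[tuple[int, int], int],
        window_max_regions: int,
    ) -> None:
        self.rmap = {r.id: r for r in regions}
        self.costs = costs
        self.pair_counts = pair_counts
        outer = np.asarray(outer, dtype=bool)
        self.inside = {
            r.id
            for r in regions
            if outer[int(round(r.centroid[0])), int(round(r.centroid[1]))]
        }
        inside_list = sorted(self.inside)
        self._inside_ids = np.array(inside_list)
        pts = np.array([self.rmap[i].centroid for i in inside_list]) if inside_list else np.empty((0, 2))
        self._tree = cKDTree(pts) if len(inside_list) else None
        self.k_window = min(window_max_regions, len(inside_list))
        self._window_cache: dict[int, frozenset[int]] = {}
        self.nH = {r.id: r.pixel_count * r.entropy for r in regions}

        self.clusters: dict[int, Cluster] = {}
        self.assigned: dict[int, int] = {}
        for s in seeds:
            c = Cluster.from_region(s.ray_index, self.rmap[s.region_id])
            self.clusters[c.id] = c
            self.assigned[s.region_id] = c.id
        # frontier[cid][rid] = shared boundary elements with the cluster
        self.frontier: dict[int, dict[int, int]] = {cid: {} for cid in self.clusters}
        self.cpair_nb: dict[tuple[int, int], int] = {}
        for cid, c in self.clusters.items():
            (seed_rid,) = c.region_ids
            for m in self.rmap[seed_rid].neighbors:
                nb = self.pc(seed_rid, m)
                if m in self.assigned:
                    other = self.assigned[m]
                    if other != cid:
                        key = tuple(sorted((cid, other)))
                        # counted once per ordered scan; guard against double add
                        if key not in self.cpair_nb:
                            self.cpair_nb[key] = 0
                        if cid < other:
                            self.cpair_nb[key] += nb
                elif m in self.inside:
                    self.frontier[cid][m] = self.frontier[cid].get(m, 0) + nb
        self.gains: dict[int, dict[int, float]] = {}
        self._win_ok: dict[int, set[int]] = {cid: set() for cid in self.clusters}
        for cid in self.clusters:
            self.recompute_gains(cid)

    def pc(self, a: int, b: int) -> int:
        return self.pair_counts.get((a, b) if a < b else (b, a), 0)

    def window(self, rid: int) -> frozenset[int]:
        if rid not in self._window_cache:
            if self._tree is None:
                self._window_cache[rid] = frozenset()
            else:
                _, idx = self._tree.query(self.rmap[rid].centroid, k=self.k_window)
                idx = np.atleast_1d(idx)
                self._window_cache[rid] = frozenset(int(self._inside_ids[j]) for j in idx)
        return self._window_cache[rid]

    def _window_allows(self, cid: int, rid: int) -> bool:
        # the query window around rid must reach the cluster; once true it
        # stays true because clusters only grow
        if rid in self._win_ok[cid]:
            return True
        if self.clusters[cid].region_ids & self.window(rid):
            self._win_ok[cid].add(rid)
            return True
        return False

    def recompute_gains(self, cid: int) -> None:
        c = self.clusters[cid]
        cand = [
            rid
            for rid, nb in sorted(self.frontier[cid].items())
            if nb >= 1 and self._window_allows(cid, rid)
        ]
        if not cand:
            self.gains[cid] = {}
            return
        hists = np.stack([self.rmap[r].histogram for r in cand]).astype(np.int64)
        pooled = hists + c.histogram[None, :]
        totals = pooled.sum(axis=1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = pooled / totals[:, None]
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        h_new = -plogp.sum(axis=1)
        n_new = np.array([self.rmap[r].pixel_count for r in cand]) + c.pixel_count
        g = (
            np.array([self.nH[r] for r in cand])
            + c.pixel_count * c.entropy
            - n_new * h_new
            + self.costs.b1
            + np.array([self.frontier[cid][r] for r in cand]) * self.costs.b2
        )
        self.gains[cid] = dict(zip(cand, g))

    def best_candidate(self) -> tuple[float, int, int] | None:
        best: tuple[float, int, int] | None = None
        for cid in sorted(self.clusters):
            for rid, g in self.gains[cid].items():
                if g <= 0:
                    continue
                if best is None or g > best[0] or (g == best[0] and (rid, cid) < (best[1], best[2])):
                    best = (g, rid, cid)
        return best

    def merge_region(self, rid: int, cid: int) -> None:
        c = self.clusters[cid]
        r = self.rmap[rid]
        nb_shared = self.frontier[cid].pop(rid)
        c.region_ids.add(rid)
        c.histogram = c.histogram + r.histogram
        c.pixel_count += r.pixel_count
        c.entropy = shannon_entropy_bits(c.histogram)
        c.boundary += r.boundary_length - 2 * nb_shared
        self.assigned[rid] = cid
        # rid leaves every other cluster's frontier; its shared boundary with
        # that cluster becomes cluster-cluster adjacency
        for other, fr in self.frontier.items():
            if other == cid or rid not in fr:
                continue
            nb = fr.pop(rid)
            key = tuple(sorted((cid, other)))
            self.cpair_nb[key] = self.cpair_nb.get(key, 0) + nb
            self.gains[other].pop(rid, None)
        # new frontier contributions from rid's unassigned neighbors (boundary
        # shared with other clusters was already accounted by the pops above)
        for m in r.neighbors:
            if m not in self.assigned and m in self.inside:
                self.frontier[cid][m] = self.frontier[cid].get(m, 0) + self.pc(rid, m)
        self.recompute_gains(cid)

    def union_positive_cluster_pairs(self, merge_log: list | None, step: int) -> int:
        """Union adjacent cluster pairs while their mutual gain is positive."""
        changed = True
        while changed:
            changed = False
            for key in sorted(self.cpair_nb):
                c1, c2 = key
                if c1 not in self.clusters or c2 not in self.clusters:
                    continue
                nb = self.cpair_nb[key]
                if nb < 1:
                    continue
                a, b = self.clusters[c1], self.clusters[c2]
                query, host = (a, b) if a.pixel_count <= b.pixel_count else (b, a)
                g = merge_gain(query, host, nb, self.costs)
                if g > 0:
                    self._union(host.id, query.id)
                    if merge_log is not None:
                        merge_log.append((step, host.id, -query.id, g))
                    step += 1
                    changed = True
                    break
        return step

    def _union(self, keep: int, drop: int) -> None:
        ck, cd = self.clusters[keep], self.clusters.pop(drop)
        key = tuple(sorted((keep, drop)))
        nb = self.cpair_nb.pop(key, 0)
        ck.region_ids |= cd.region_ids
        ck.histogram = ck.histogram + cd.histogram
        ck.pixel_count += cd.pixel_count
        ck.entropy = shannon_entropy_bits(ck.histogram)
        ck.boundary += cd.boundary - 2 * nb
        for rid in cd.region_ids:
            self.assigned[rid] = keep
        for rid, v in self.frontier.pop(drop).items():
            self.frontier[keep][rid] = self.frontier[keep].get(rid, 0) + v
        self._win_ok[keep] |= self._win_ok.pop(drop)
        for other_key in list(self.cpair_nb):
            if drop in other_key:
                other = other_key[0] if other_key[1] == drop else other_key[1]
                v = self.cpair_nb.pop(other_key)
                nk = tuple(sorted((keep, other)))
                self.cpair_nb[nk] = self.cpair_nb.get(nk, 0) + v
        self.gains.pop(drop, None)
        self.recompute_gains(keep)


def grow_clusters(
    regions: list[PrimitiveRegion],
    seeds: list[Seed],
    outer: np.ndarray,
    costs: BitCosts,
    labels: np.ndarray,
    pair_counts: dict[tuple[int, int], int] | None = None,
    window_max_regions: int = 100,
    merge_log: list | None = None,
) -> np.ndarray:
    """Greedy MDL growth from the seeds; returns the epithelial mask.

    At each step the single (cluster, adjacent-region) candidate with the
    largest positive gain anywhere is merged (ties: smaller region id, then
    smaller cluster id); adjacent clusters with positive mutual gain are
    unioned as they meet.  Growth stops when no candidate gain is positive.
    The returned mask is the union of all cluster pixels, restricted to the
    outer mask.  ``merge_log`` (if given) receives ``(step, cluster_id,
    region_id, gain)`` rows; cluster unions log the absorbed cluster as a
    negative id.
    """
    if not seeds:
        raise SegmentationFailureError("need at least 1 seed")
    if pair_counts is None:
        pair_counts = adjacency_boundary_counts(labels)
    state = _GrowState(regions, seeds, outer, costs, pair_counts, window_max_regions)
    step = 0
    step = state.union_positive_cluster_pairs(merge_log, step)
    merged_any = False
    while True:
        best = state.best_candidate()
        if best is None:
            break
        g, rid, cid = best
        state.merge_region(rid, cid)
        if merge_log is not None:
            merge_log.append((step, cid, rid, g))
        step += 1
        merged_any = True
        step = state.union_positive_cluster_pairs(merge_log, step)
    if not merged_any:
        log.warning("no positive merge gain at start; returning seed regions alone")
    member_ids = sorted(set().union(*(c.region_ids for c in state.clusters.values())))
    mask = np.isin(labels, member_ids)
    return mask & np.asarray(outer, dtype=bool)
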