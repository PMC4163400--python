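"""Gradient flow-line partitioning into primitive regions.

The gradient-magnitude surface of the diffused image is treated as a
topographic relief.  From every pixel a steepest-descent path is followed to
a local minimum (or flat plateau); all pixels draining to the same minimum
form one primitive region, so region boundaries coincide with the ridges of
the gradient surface.  Descent steps to the strictly smaller 8-neighbor of
minimum value; among tied minima the LAST neighbor in a fixed row-major scan
of the 3x3 window is taken.  Adjacent terminating pixels of equal height are
unioned, so flat plateaus do not fragment.

The recursive definition is evaluated iteratively by pointer doubling, which
yields identical labels with bounded depth on large images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._util import quantize_u8, shannon_entropy_bits
from .errors import InvalidInputError

__all__ = [
    "NEIGHBOR_OFFSETS",
    "PrimitiveRegion",
    "gradient_magnitude",
    "trace_flow_labels",
    "compute_region_stats",
    "adjacency_boundary_counts",
    "export_debug",
]

# Fixed neighbor scan order: row-major over the 3x3 window, center excluded.
# The tie rule "take the last pixel found" refers to this order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude, border handled by edge replication."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("expected a nonempty 2-D image")
    pad = np.pad(img, 1, mode="edge")
    gy = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    gx = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    return np.hypot(gy, gx)


def _descent_targets(gradmag: np.ndarray) -> np.ndarray:
    """Flat index of each pixel's descent step (itself if no strictly smaller neighbor)."""
    h, w = gradmag.shape
    big = np.inf
    padded = np.pad(gradmag, 1, mode="constant", constant_values=big)
    nvals = np.stack(
        [padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in NEIGHBOR_OFFSETS]
    )  # (8, h, w)
    nmin = nvals.min(axis=0)
    descending = nmin < gradmag
    # last neighbor (in scan order) attaining the minimum
    eq_rev = (nvals[::-1] == nmin)
    last_idx = 7 - np.argmax(eq_rev, axis=0)
    offs = np.array(NEIGHBOR_OFFSETS)
    rows, cols = np.indices((h, w))
    tr = rows + offs[last_idx, 0]
    tc = cols + offs[last_idx, 1]
    targets = tr * w + tc
    self_idx = rows * w + cols
    return np.where(descending, targets, self_idx).ravel()


def trace_flow_labels(gradmag: np.ndarray) -> np.ndarray:
    """Label every pixel by the flow-line minimum it drains to.

    Returns an int label image with consecutive labels 1..n_regions,
    numbered in row-major order of first appearance (deterministic).
    """
    gradmag = np.asarray(gradmag, dtype=float)
    if gradmag.ndim != 2 or gradmag.size == 0:
        raise InvalidInputError("expected a nonempty 2-D gradient image")
    if (gradmag < 0).any():
        raise InvalidInputError("gradient magnitude must be non-negative")
    h, w = gradmag.shape
    n = h * w
    nxt = _descent_targets(gradmag)
    # pointer doubling to the terminal of each path
    while True:
        nxt2 = nxt[nxt]
        if np.array_equal(nxt2, nxt):
            break
        nxt = nxt2
    roots = nxt  # terminal flat index per pixel

    # union adjacent equal-valued terminals (plateau handling)
    is_term = nxt == np.arange(n)
    term_img = is_term.reshape(h, w)
    pairs_a: list[np.ndarray] = []
    pairs_b: list[np.ndarray] = []
    for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # each undirected pair once
        sl_a = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
        sl_b = (slice(max(0, dr), h + min(0, dr)), slice(max(0, dc), w + min(0, dc)))
        a_term = term_img[sl_a]
        b_term = term_img[sl_b]
        equal = gradmag[sl_a] == gradmag[sl_b]
        hit = a_term & b_term & equal
        if hit.any():
            ar, ac = np.nonzero(hit)
            ar_a = ar + sl_a[0].start
            ac_a = ac + sl_a[1].start
            pairs_a.append(ar_a * w + ac_a)
            pairs_b.append((ar_a + dr) * w + (ac_a + dc))
    term_idx = np.nonzero(is_term)[0]
    remap = -np.ones(n, dtype=np.int64)
    remap[term_idx] = np.arange(term_idx.size)
    if pairs_a:
        ia = remap[np.concatenate(pairs_a)]
        ib = remap[np.concatenate(pairs_b)]
        g = coo_matrix((np.ones(ia.size), (ia, ib)), shape=(term_idx.size, term_idx.size))
        _, comp = connected_components(g, directed=False)
    else:
        comp = np.arange(term_idx.size)
    group_of_pixel = comp[remap[roots]]

    # consecutive labels in row-major order of first appearance
    _, first_idx, inverse = np.unique(group_of_pixel, return_index=True, return_inverse=True)
    label_of_group = np.empty(first_idx.size, dtype=np.int32)
    label_of_group[np.argsort(first_idx, kind="stable")] = np.arange(1, first_idx.size + 1)
    return label_of_group[inverse].reshape(h, w)


@dataclass
class PrimitiveRegion:
    """One primitive region with the statistics used for MDL clustering."""

    id: int
    pixel_count: int
    histogram: np.ndarray  # 256-bin intensity counts
    entropy: float  # Shannon entropy of the normalized histogram, bits
    min_int: int
    max_int: int
    centroid: tuple[float, float]
    boundary_length: int  # 4-adjacent pixel pairs with a different label
    neighbors: set[int] = field(default_factory=set)


def adjacency_boundary_counts(labels: np.ndarray) -> dict[tuple[int, int], int]:
    """Shared 4-adjacent boundary-element counts per region pair (a < b)."""
    labels = np.asarray(labels)
    out: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = labels[:-1, :] if axis == 0 else labels[:, :-1]
        b = labels[1:, :] if axis == 0 else labels[:, 1:]
        diff = a != b
        if not diff.any():
            continue
        lo = np.minimum(a[diff], b[diff]).astype(np.int64)
        hi = np.maximum(a[diff], b[diff]).astype(np.int64)
        codes, counts = np.unique(lo * (labels.max() + 1) + hi, return_counts=True)
        for code, cnt in zip(codes, counts):
            key = (int(code // (labels.max() + 1)), int(code % (labels.max() + 1)))
            out[key] = out.get(key, 0) + int(cnt)
    return out


def compute_region_stats(labels: np.ndarray, img: np.ndarray) -> list[PrimitiveRegion]:
    """Per-region intensity statistics, boundary lengths and adjacency.

    ``boundary_length`` counts the 4-adjacent pixel pairs whose labels
    differ, attributed to both touching regions; the frame border does not
    contribute.  Adjacency derives from the same pairs.
    """
    labels = np.asarray(labels)
    img = np.asarray(img)
    if labels.shape != img.shape:
        raise InvalidInputError("label and intensity images must share a shape")
    n = int(labels.max())
    flat_lab = labels.ravel().astype(np.int64) - 1
    inten = quantize_u8(img).ravel().astype(np.int64)
    hists = np.bincount(flat_lab * 256 + inten, minlength=n * 256).reshape(n, 256)
    counts = hists.sum(axis=1)
    rows, cols = np.indices(labels.shape)
    sum_r = np.bincount(flat_lab, weights=rows.ravel(), minlength=n)
    sum_c = np.bincount(flat_lab, weights=cols.ravel(), minlength=n)
    pair_counts = adjacency_boundary_counts(labels)
    boundary = np.zeros(n, dtype=np.int64)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for (a, b), cnt in pair_counts.items():
        boundary[a - 1] += cnt
        boundary[b - 1] += cnt
        neighbors[a - 1].add(b)
        neighbors[b - 1].add(a)
    regions = []
    for i in range(n):
        hist = hists[i]
        nz = np.nonzero(hist)[0]
        regions.append(
            PrimitiveRegion(
                id=i + 1,
                pixel_count=int(counts[i]),
                histogram=hist.astype(np.int64),
                entropy=shannon_entropy_bits(hist),
                min_int=int(nz[0]),
                max_int=int(nz[-1]),
                centroid=(float(sum_r[i] / counts[i]), float(sum_c[i] / counts[i])),
                boundary_length=int(boundary[i]),
                neighbors=neighbors[i],
            )
        )
    return regions


def export_debug(labels: np.ndarray, regions: list[PrimitiveRegion], out_dir) -> None:
    """Write the label image (16-bit PNG) and per-region stats CSV for inspection."""
    from pathlib import Path

    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "labels.png", np.asarray(labels, dtype=np.uint16))
    rows = [
        {
            "id": r.id,
            "n_pixels": r.pixel_count,
            "entropy_bits": r.entropy,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "boundary_len": r.boundary_length,
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(out / "regions.csv", index=False)
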