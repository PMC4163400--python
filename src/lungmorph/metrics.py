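"""Segmentation overlap scoring and per-explant morphometry.

The Dice similarity coefficient DSC(A, B) = 2|A∩B| / (|A| + |B|) is reported
in percent, 0% for disjoint masks to 100% for identical ones.  Morphometry
reports areas as foreground pixel counts and perimeters as the length of the
traced 8-connected boundary polygon (diagonal steps count sqrt(2)), both in
pixels and in physical units via the pixel size (40 um/px by default for the
stereo-microscope setup).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np

from ._util import largest_component
from .errors import InvalidInputError, UndefinedScoreError

log = logging.getLogger(__name__)

__all__ = ["OverlapCounts", "MorphometryReport", "dsc", "perimeter_8connected", "morphometry"]


@dataclass(frozen=True)
class OverlapCounts:
    """True/false positive and false negative pixel counts of masks (A, B)."""

    tp: int
    fp: int
    fn: int

    @classmethod
    def from_masks(cls, a: np.ndarray, b: np.ndarray) -> "OverlapCounts":
        a = np.asarray(a, dtype=bool)
        b = np.asarray(b, dtype=bool)
        if a.shape != b.shape:
            raise InvalidInputError("masks must share a shape")
        return cls(
            tp=int((a & b).sum()),
            fp=int((a & ~b).sum()),
            fn=int((~a & b).sum()),
        )


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks, in percent."""
    counts = OverlapCounts.from_masks(a, b)
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise UndefinedScoreError("DSC undefined for two empty masks")
    return 100.0 * 2 * counts.tp / denom


_CW = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _next_boundary_pixel(mask: np.ndarray, cur: tuple[int, int], ref_off: tuple[int, int]):
    """First foreground neighbor of ``cur`` scanning clockwise after ``ref_off``."""
    h, w = mask.shape
    i = _CW.index(ref_off)
    for k in range(1, 9):
        off = _CW[(i + k) % 8]
        q = (cur[0] + off[0], cur[1] + off[1])
        if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
            return q, off
    return None


def perimeter_8connected(mask: np.ndarray) -> float:
    """Length of the traced outer boundary polygon of the largest component.

    Radial-sweep (Moore neighbor) tracing through boundary pixel centers;
    axial steps count 1, diagonal steps sqrt(2).  Interior holes do not
    contribute.  A single pixel has perimeter 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    mask = largest_component(mask)
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))  # topmost, then leftmost
    first = _next_boundary_pixel(mask, start, (0, -1))  # its west neighbor is background
    if first is None:
        return 0.0
    second, off0 = first
    cycle = []
    cur, off = second, off0
    limit = 8 * mask.sum() + 8
    while len(cycle) < limit:
        cycle.append(cur)
        back = (-off[0], -off[1])
        cur, off = _next_boundary_pixel(mask, cur, back)
        if (cur, off) == (second, off0):
            break
    total = 0.0
    for p, q in zip(cycle, cycle[1:] + cycle[:1]):
        total += math.hypot(p[0] - q[0], p[1] - q[1])
    return total


@dataclass(frozen=True)
class MorphometryReport:
    """Morphometric quantities of one explant image."""

    epithelial_area_px: float
    epithelial_area_um2: float
    epithelial_perimeter_px: float
    epithelial_perimeter_um: float
    outer_area_px: float
    outer_area_um2: float
    outer_perimeter_px: float
    outer_perimeter_um: float
    n_buds: int
    culture_day: int | None = None
    image_type: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def morphometry(
    epi: np.ndarray,
    outer: np.ndarray,
    buds,
    px_um: float = 40.0,
    culture_day: int | None = None,
    image_type: str | None = None,
) -> MorphometryReport:
    """Areas, perimeters and bud count for one explant.

    ``buds`` is a :class:`~lungmorph.buds.BudCount` (or None for 0).  The
    epithelial mask is clipped to the outer mask (logged when pixels were
    dropped), which enforces the containment invariant.
    """
    epi = np.asarray(epi, dtype=bool)
    outer = np.asarray(outer, dtype=bool)
    if epi.shape != outer.shape:
        raise InvalidInputError("masks must share a shape")
    clipped = epi & outer
    dropped = int(epi.sum() - clipped.sum())
    if dropped:
        log.warning("clipped %d epithelial pixels outside the outer mask", dropped)
    epi = clipped
    if not epi.any() or not outer.any():
        log.warning("empty mask(s); morphometry report is zero-valued")
    n_buds = int(getattr(buds, "n_buds", 0) if buds is not None else 0)
    epi_area = float(epi.sum())
    out_area = float(outer.sum())
    epi_per = perimeter_8connected(epi) if epi.any() else 0.0
    out_per = perimeter_8connected(outer) if outer.any() else 0.0
    return MorphometryReport(
        epithelial_area_px=epi_area,
        epithelial_area_um2=epi_area * px_um**2,
        epithelial_perimeter_px=epi_per,
        epithelial_perimeter_um=epi_per * px_um,
        outer_area_px=out_area,
        outer_area_um2=out_area * px_um**2,
        outer_perimeter_px=out_per,
        outer_perimeter_um=out_per * px_um,
        n_buds=n_buds,
        culture_day=culture_day,
        image_type=image_type,
    )
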