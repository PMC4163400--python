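"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["shannon_entropy_bits", "quantize_u8", "largest_component", "disk_offsets"]


def shannon_entropy_bits(hist: np.ndarray) -> float:
    """Shannon entropy (base 2) of a count histogram.

    Empty histograms have zero entropy by convention.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        return 0.0
    p = hist[hist > 0] / total
    return float(-(p * np.log2(p)).sum())


def quantize_u8(img: np.ndarray) -> np.ndarray:
    """Round a float image in [0, 255] to integer gray levels 0..255."""
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Keep only the largest connected foreground component (8-connected by default)."""
    from skimage import measure

    lab = measure.label(mask, connectivity=connectivity)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def disk_offsets(radius: float) -> np.ndarray:
    """(row, col) integer offsets covering a filled disc of the given radius."""
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr * dr + dc * dc <= radius * radius
    return np.stack([dr[keep], dc[keep]], axis=1)
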