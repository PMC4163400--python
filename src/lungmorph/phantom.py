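"""Synthetic lung-explant phantoms with known ground truth.

Each phantom is a rendered explant image plus its true outer mask, true
epithelial mask, and true peripheral-bud count, so every pipeline stage can
be validated without microscope data.

Geometry.  The epithelium is drawn as dark branched tubing: an annular body
(the looped airway network seen in cultured explants) carrying
``n_buds_target`` finger-like terminal buds that protrude toward the rim,
plus interior spokes whose number grows with ``n_generations`` (a proxy for
culture day).  Attaching each bud at its own, well-separated point of the
annulus makes the ground truth unambiguous: the skeleton's qualifying
endpoints are exactly the bud tips and each tip has a distinct parent
junction, so both bud-counting conventions agree with ``true_buds``.  With
``n_generations = 1`` the epithelium degenerates to a single unbranched tube
with one bud at its distal end.

Rendering.  The explant hull (a smooth lobed blob obtained by dilating the
epithelium) is filled with bright mesenchyme on a dark background; the
epithelium is darker than the mesenchyme.  Gaussian noise, a linear
illumination ramp and a radially decaying rim shadow emulate the two
microscope lighting regimes: high-contrast "type A" (no ramp/shadow) and
low-contrast, shadowed "type B".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._util import largest_component
from .errors import ConstraintError, InvalidParameterError

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_suite", "DAY_PROFILES"]

# culture day -> (n_generations, n_buds_target): branching depth and bud
# number increase over the 5-day culture period
DAY_PROFILES: dict[int, tuple[int, int]] = {1: (2, 2), 2: (3, 3), 3: (3, 4), 4: (4, 6), 5: (4, 8)}


def max_buds(n_generations: int) -> int:
    """Largest feasible bud count for a branching depth (angular packing cap)."""
    return 1 if n_generations <= 1 else min(2**n_generations, 10)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic explant; same spec + seed is bit-identical."""

    rng_seed: int = 0
    image_size: tuple[int, int] = (576, 768)
    n_generations: int = 3
    n_buds_target: int = 4
    epithelium_intensity: float = 60.0
    mesenchyme_intensity: float = 180.0
    background_intensity: float = 30.0
    noise_sd: float = 6.0
    illumination_gradient: float = 0.0  # intensity units across the frame width
    shadow_strength: float = 0.0  # intensity units of rim darkening

    def __post_init__(self) -> None:
        if not (1 <= self.n_generations <= 4):
            raise InvalidParameterError("n_generations must be in 1..4")
        if min(self.image_size) < 64:
            raise InvalidParameterError("image_size must be at least 64 px per side")
        if not (0 <= self.background_intensity < self.mesenchyme_intensity <= 255):
            raise InvalidParameterError("need background < mesenchyme intensity in [0, 255]")
        if not (0 <= self.epithelium_intensity < self.mesenchyme_intensity):
            raise InvalidParameterError("need epithelium < mesenchyme intensity")
        if self.n_buds_target < 1 or self.n_buds_target > max_buds(self.n_generations):
            raise ConstraintError(
                f"{self.n_buds_target} buds infeasible for {self.n_generations} generations"
            )


@dataclass
class PhantomTruth:
    """Rendered phantom with its ground-truth masks and bud count."""

    rgb: np.ndarray  # (H, W, 3) uint8
    outer_truth: np.ndarray  # bool
    epi_truth: np.ndarray  # bool
    true_buds: int
    bud_tip_locations: list[tuple[int, int]]
    spec: PhantomSpec
    culture_day: int | None = None
    image_type: str = "A"


def _capsule_sdf(dist_grid: tuple[np.ndarray, np.ndarray], p0, p1, width: float) -> np.ndarray:
    """Signed distance to a thick line segment (capsule): negative inside."""
    rr, cc = dist_grid
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.hypot(rr - p0[0], cc - p0[1]) - width / 2
    t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2, 0.0, 1.0)
    pr = p0[0] + t * d[0]
    pc = p0[1] + t * d[1]
    return np.hypot(rr - pr, cc - pc) - width / 2


def _soft_union(fields: list[np.ndarray], fillet: float) -> np.ndarray:
    """Soft minimum of signed distance fields; ``fillet`` rounds junctions.

    Junction cusps of a hard union skeletonize into spurious short branches,
    so tissue junctions are blended smoothly instead.
    """
    stack = np.stack(fields)
    m = stack.min(axis=0)
    acc = np.exp(-(stack - m[None]) / fillet).sum(axis=0)
    return m - fillet * np.log(acc)


def _draw_epithelium(spec: PhantomSpec, rng: np.random.Generator):
    """Rasterize the epithelial tubing; returns (mask, tip pixels, basal point)."""
    h, w = spec.image_size
    s = float(min(h, w))
    cr, cc = h / 2.0, w / 2.0
    rr, cc_grid = np.mgrid[0:h, 0:w].astype(float)
    grid = (rr, cc_grid)
    tips: list[tuple[int, int]] = []
    fillet = 0.012 * s

    tube_w = 0.055 * s
    if spec.n_generations == 1:
        # single unbranched tube, roughly vertical, bud at the distal (upper) end
        ang = math.radians(90.0 + rng.uniform(-15.0, 15.0))
        L = 0.34 * s
        base = (cr + 0.12 * s, cc)
        tip = (base[0] - L * math.sin(ang), base[1] + L * math.cos(ang))
        epi = _capsule_sdf(grid, base, tip, tube_w) <= 0
        tips.append((int(round(tip[0])), int(round(tip[1]))))
        return epi, tips, base

    fields: list[np.ndarray] = []
    # annular airway loop: a closed tube has no skeleton endpoints, so every
    # endpoint of the final skeleton is a bud tip by construction; branching
    # depth modulates the loop's radius and wall thickness
    g = spec.n_generations
    ring_r = (0.15 + 0.02 * g) * s
    ring_w = (0.038 + 0.004 * g) * s
    d_center = np.hypot(rr - cr, cc_grid - cc)
    # mild lobing so the loop is not a perfect circle
    theta = np.arctan2(-(rr - cr), cc_grid - cc)
    lobe_phase = rng.uniform(0, 2 * math.pi)
    lobing = 1.0 + 0.05 * np.sin(g * theta + lobe_phase)
    fields.append(np.abs(d_center - ring_r * lobing) - ring_w / 2)
    # bud fingers: one T-junction each on the annulus, tips toward the rim
    n = spec.n_buds_target
    finger_len = (0.17 - 0.008 * g) * s
    finger_w = 0.045 * s
    base_off = rng.uniform(0.0, 360.0)
    spacing = 360.0 / n
    for i in range(n):
        a = math.radians(base_off + i * spacing + rng.uniform(-0.2, 0.2) * spacing)
        drow, dcol = -math.sin(a), math.cos(a)
        # the finger is rooted on the local (lobed) ring centerline so it
        # leaves no stub poking through the inner wall
        r_base = ring_r * (1.0 + 0.05 * math.sin(g * a + lobe_phase))
        p0 = (cr + r_base * drow, cc + r_base * dcol)
        p1 = (cr + (ring_r + finger_len) * drow, cc + (ring_r + finger_len) * dcol)
        fields.append(_capsule_sdf(grid, p0, p1, finger_w))
        tips.append((int(round(p1[0])), int(round(p1[1]))))
    epi = _soft_union(fields, fillet) <= 0
    return epi, tips, None


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    s = float(min(h, w))
    epi, tips, base = _draw_epithelium(spec, rng)

    # hull: dilate the tubing, add a basal body for the single-tube case so
    # the tube's proximal end is not peripheral, then smooth into a lobed blob
    dil = 0.06 * s
    hull = ndimage.distance_transform_edt(~epi) <= dil
    if base is not None:
        rr, cc_grid = np.mgrid[0:h, 0:w].astype(float)
        hull |= np.hypot(rr - base[0], cc_grid - base[1]) <= 0.20 * s
    hull = ndimage.gaussian_filter(hull.astype(float), 0.01 * s) > 0.5
    hull = ndimage.binary_fill_holes(largest_component(hull))
    epi &= hull

    # sanity of the bud geometry: every tip peripheral, nothing else close
    contour = hull & ~ndimage.binary_erosion(hull)
    dist = ndimage.distance_transform_edt(~contour)
    rows = np.nonzero(hull.any(axis=1))[0]
    cutoff = 0.25 * (rows[-1] - rows[0] + 1)
    for t in tips:
        if dist[t] >= 0.8 * cutoff:
            raise ConstraintError("generated bud tip is not peripheral; spec too crowded")

    gray = np.full((h, w), spec.background_intensity, dtype=float)
    gray[hull] = spec.mesenchyme_intensity
    gray[epi] = spec.epithelium_intensity
    # soft tissue boundaries as seen through the stereo microscope
    gray = ndimage.gaussian_filter(gray, 1.2)
    if spec.illumination_gradient:
        ramp = (np.arange(w) / max(w - 1, 1) - 0.5) * spec.illumination_gradient
        gray = gray + ramp[None, :]
    if spec.shadow_strength:
        inner = ndimage.distance_transform_edt(hull)
        shade = spec.shadow_strength * np.exp(-inner / (0.5 * dil + 1e-9))
        gray = gray - shade * hull
    gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)
    # optical/sensor blur acts after the noise sources, so the captured
    # noise is spatially correlated rather than pixel-white
    gray = ndimage.gaussian_filter(gray, 0.8)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)

    image_type = "B" if (spec.illumination_gradient or spec.shadow_strength) else "A"
    return PhantomTruth(
        rgb=rgb,
        outer_truth=hull,
        epi_truth=epi,
        true_buds=spec.n_buds_target,
        bud_tip_locations=tips,
        spec=spec,
        image_type=image_type,
    )


def generate_suite(
    n_per_day: int,
    days: list[int],
    type_b: bool = False,
    rng_seed: int = 0,
    image_size: tuple[int, int] = (576, 768),
    noise_sd: float = 6.0,
) -> list[PhantomTruth]:
    """Phantoms emulating a multi-day culture study.

    Branching depth and bud count follow :data:`DAY_PROFILES`, so true bud
    medians are non-decreasing over days.  ``type_b`` switches on the
    illumination ramp and rim shadow of the low-contrast regime.
    Deterministic: per-phantom seeds derive from ``rng_seed``.
    """
    if n_per_day < 1:
        raise InvalidParameterError("n_per_day must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(days) * n_per_day)
    out: list[PhantomTruth] = []
    k = 0
    for day in days:
        gens, buds = DAY_PROFILES.get(int(day), DAY_PROFILES[min(max(int(day), 1), 5)])
        for _ in range(n_per_day):
            seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            spec = PhantomSpec(
                rng_seed=seed,
                image_size=image_size,
                n_generations=gens,
                n_buds_target=buds,
                noise_sd=noise_sd,
                illumination_gradient=40.0 if type_b else 0.0,
                shadow_strength=35.0 if type_b else 0.0,
            )
            truth = generate_phantom(spec)
            truth.culture_day = int(day)
            out.append(truth)
    return out
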