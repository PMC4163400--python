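"""End-to-end explant analysis: preprocessing through morphometry.

``analyze_image`` runs the full chain on an in-memory image; ``run_pipeline``
wraps it with file I/O and writes every artifact (masks, overlay, merge log,
report, resolved config); ``run_batch`` evaluates a manifest of image/truth
pairs and aggregates per culture day.  The pipeline is fully deterministic
for a given image and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import buds as buds_mod
from . import cluster as cluster_mod
from . import metrics as metrics_mod
from . import outer_contour as outer_mod
from . import partition as partition_mod
from . import preprocess
from ._util import quantize_u8
from .config import PipelineConfig
from .errors import PipelineError
from .metrics import MorphometryReport

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze_image", "run_pipeline", "run_batch", "evaluate_suite"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    gray: np.ndarray
    diffused: np.ndarray
    outer_mask: np.ndarray
    epi_mask: np.ndarray
    skeleton: buds_mod.SkeletonGraph
    bud_count: buds_mod.BudCount
    report: MorphometryReport
    refined: bool
    n_regions: int
    seeds: list[cluster_mod.Seed]
    merge_log: list[tuple] = field(default_factory=list)


def _needs_refinement(diffused: np.ndarray, global_mask: np.ndarray, cfg: PipelineConfig) -> bool:
    """Type-B images get the locally adaptive threshold; auto mode triggers on
    a high coefficient of variation of the boundary intensity."""
    mode = cfg.outer.image_type
    if mode == "A":
        return False
    if mode == "B":
        return True
    from scipy import ndimage

    # sample object tissue just inside the contour: the edge ramp itself would
    # dominate the statistic and make the trigger meaningless
    depth = max(3, round(0.02 * min(global_mask.shape)))
    eroded = ndimage.binary_erosion(global_mask, iterations=depth)
    contour = eroded & ~ndimage.binary_erosion(eroded)
    if not contour.any():
        contour = global_mask & ~ndimage.binary_erosion(global_mask)
    vals = diffused[contour]
    if vals.size == 0 or vals.mean() == 0:
        return False
    cv = float(vals.std() / abs(vals.mean()))
    return cv > cfg.outer.cv_trigger


def _regularize_epithelium(
    mask: np.ndarray, outer: np.ndarray, close_radius: float, sigma: float, keep_frac: float = 0.05
) -> np.ndarray:
    """Regularize the raw cluster union into a coherent epithelial object.

    Closing at the seed-kernel radius (the method's epithelial tube scale)
    bridges slivers the greedy merge left unassigned, the same Gaussian
    smoothing used on the outer contour removes boundary raggedness, and
    components below ``keep_frac`` of the foreground are discarded as merge
    debris.  The result stays inside the outer mask.
    """
    from scipy import ndimage
    from skimage.morphology import disk

    m = ndimage.binary_closing(mask, structure=disk(int(round(close_radius))))
    m = ndimage.gaussian_filter(m.astype(float), sigma) > 0.5
    m &= np.asarray(outer, dtype=bool)
    lab, _ = ndimage.label(m, structure=np.ones((3, 3)))
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if sizes.sum() == 0:
        return mask & np.asarray(outer, dtype=bool)
    keep = np.nonzero(sizes >= keep_frac * sizes.sum())[0]
    return np.isin(lab, keep)


def analyze_image(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    culture_day: int | None = None,
) -> PipelineResult:
    """Run the full morphometric analysis on an RGB or grayscale array."""
    cfg = config or PipelineConfig()

    gray = preprocess.rgb_to_gray(img)
    diffused = preprocess.anisotropic_diffusion(
        gray,
        preprocess.DiffusionParams(
            iterations=cfg.diffusion.iterations,
            sigma=cfg.diffusion.sigma,
            time_step=cfg.diffusion.time_step,
        ),
    )

    global_mask = outer_mod.segment_global(diffused)
    refined = _needs_refinement(diffused, global_mask, cfg)
    pre_smooth = (
        outer_mod.refine_outer_mask(diffused, global_mask, control_grid=cfg.outer.control_grid)
        if refined
        else global_mask
    )
    outer_mask = outer_mod.smooth_contour(pre_smooth, cfg.outer.smooth_sigma)

    # the gradient surface is an 8-bit intensity image in this pipeline's
    # data model; integer quantization lets flat areas form plateaus so the
    # partition yields large homogeneous primitive regions
    gradmag = quantize_u8(partition_mod.gradient_magnitude(diffused))
    labels = partition_mod.trace_flow_labels(gradmag)
    regions = partition_mod.compute_region_stats(labels, diffused)
    pair_counts = partition_mod.adjacency_boundary_counts(labels)

    fan = outer_mod.cast_rays(outer_mask)
    seeds = cluster_mod.select_seeds(
        diffused, fan, outer_mask, labels, kernel_radius=cfg.cluster.kernel_radius
    )
    costs = cluster_mod.BitCosts.for_image(diffused.shape)
    merge_log: list[tuple] = []
    epi_raw = cluster_mod.grow_clusters(
        regions,
        seeds,
        outer_mask,
        costs,
        labels,
        pair_counts=pair_counts,
        window_max_regions=cfg.cluster.window_max_regions,
        merge_log=merge_log,
    )
    epi_mask = _regularize_epithelium(
        epi_raw, outer_mask, cfg.cluster.kernel_radius, cfg.outer.smooth_sigma
    )

    skeleton = buds_mod.skeletonize(epi_mask, min_spur=cfg.buds.min_spur)
    bud_count = buds_mod.count_buds(
        skeleton,
        outer_mask,
        count_mode=cfg.buds.count_mode,
        periphery_fraction=cfg.buds.periphery_fraction,
    )
    report = metrics_mod.morphometry(
        epi_mask,
        outer_mask,
        bud_count,
        px_um=cfg.pixel_size_um,
        culture_day=culture_day,
        image_type=cfg.outer.image_type,
    )
    return PipelineResult(
        gray=gray,
        diffused=diffused,
        outer_mask=outer_mask,
        epi_mask=epi_mask,
        skeleton=skeleton,
        bud_count=bud_count,
        report=report,
        refined=refined,
        n_regions=len(regions),
        seeds=seeds,
        merge_log=merge_log,
    )


def _write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def _overlay(result: PipelineResult) -> np.ndarray:
    """Render the Fig-style overlay: outer contour yellow, epithelium red,
    skeleton white, branched ends red dots and parents blue dots."""
    from scipy import ndimage

    base = np.clip(result.diffused, 0, 255).astype(np.uint8)
    rgb = np.repeat(base[:, :, None], 3, axis=2)
    epi = result.epi_mask
    rgb[epi] = (0.5 * rgb[epi] + 0.5 * np.array([200, 40, 40])).astype(np.uint8)
    contour = result.outer_mask & ~ndimage.binary_erosion(result.outer_mask)
    contour = ndimage.binary_dilation(contour)
    rgb[contour] = [255, 230, 0]
    rgb[result.skeleton.skeleton_mask] = [255, 255, 255]
    for ep in result.skeleton.endpoints:
        rr = slice(max(ep[0] - 2, 0), ep[0] + 3)
        cc = slice(max(ep[1] - 2, 0), ep[1] + 3)
        rgb[rr, cc] = [255, 0, 0]
    for bn in set(result.skeleton.endpoint_parent.values()) - {buds_mod.SENTINEL}:
        rr = slice(max(bn[0] - 2, 0), bn[0] + 3)
        cc = slice(max(bn[1] - 2, 0), bn[1] + 3)
        rgb[rr, cc] = [0, 80, 255]
    return rgb


def _contour_polyline(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    contour = mask & ~ndimage.binary_erosion(mask)
    rows, cols = np.nonzero(contour)
    return np.stack([cols, rows], axis=1)  # x, y columns


def run_pipeline(
    image_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "lungmorph_out",
    culture_day: int | None = None,
) -> PipelineResult:
    """Analyze one image file and write all artifacts under ``out_dir``.

    Artifacts: ``outer_mask.png``, ``epi_mask.png``, ``skeleton.png``,
    ``overlay.png``, ``outer_contour.csv`` (x,y in 0-based pixel
    coordinates, origin top-left), ``buds.csv``, ``merge_log.csv``,
    ``report.json``/``report.csv`` and the resolved ``config.json``.
    """
    cfg = config or PipelineConfig()
    img = iio.imread(image_path)
    result = analyze_image(img, cfg, culture_day=culture_day)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_mask(out / "outer_mask.png", result.outer_mask)
    _write_mask(out / "epi_mask.png", result.epi_mask)
    _write_mask(out / "skeleton.png", result.skeleton.skeleton_mask)
    iio.imwrite(out / "overlay.png", _overlay(result))
    poly = _contour_polyline(result.outer_mask)
    pd.DataFrame(poly, columns=["x", "y"]).to_csv(out / "outer_contour.csv", index=False)
    from scipy import ndimage

    oc = result.outer_mask & ~ndimage.binary_erosion(result.outer_mask)
    dist = ndimage.distance_transform_edt(~oc)
    bud_rows = []
    for ep in result.bud_count.qualifying_endpoints:
        par = result.skeleton.endpoint_parent[ep]
        bud_rows.append(
            {
                "endpoint_x": ep[1],
                "endpoint_y": ep[0],
                "parent_x": par[1],
                "parent_y": par[0],
                "dist_to_contour": float(dist[ep]),
            }
        )
    pd.DataFrame(bud_rows, columns=["endpoint_x", "endpoint_y", "parent_x", "parent_y", "dist_to_contour"]).to_csv(
        out / "buds.csv", index=False
    )
    pd.DataFrame(result.merge_log, columns=["step", "cluster_id", "region_id", "gain_bits"]).to_csv(
        out / "merge_log.csv", index=False
    )
    report_dict = result.report.to_dict()
    (out / "report.json").write_text(json.dumps(report_dict, indent=2, sort_keys=True) + "\n")
    pd.DataFrame([report_dict]).to_csv(out / "report.csv", index=False)
    cfg.save_json(out / "config.json")
    return result


def _score_one(result: PipelineResult, outer_truth, epi_truth, true_buds) -> dict:
    return {
        "outer_dsc": metrics_mod.dsc(result.outer_mask, outer_truth),
        "epi_dsc": metrics_mod.dsc(result.epi_mask, epi_truth),
        "bud_error": abs(result.bud_count.n_buds - int(true_buds)),
        "n_buds": result.bud_count.n_buds,
        "true_buds": int(true_buds),
    }


def evaluate_suite(truths, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the pipeline on in-memory phantoms and score against their truths.

    Returns one row per phantom: culture day, image type, outer and
    epithelial DSC (percent) and absolute bud-count error.
    """
    rows = []
    for i, truth in enumerate(truths):
        result = analyze_image(truth.rgb, config, culture_day=truth.culture_day)
        row = {"index": i, "day": truth.culture_day, "image_type": truth.image_type}
        row.update(_score_one(result, truth.outer_truth, truth.epi_truth, truth.true_buds))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_day(per_image: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean ± SD of the evaluation metrics (one row per culture day)."""
    if per_image.empty:
        return pd.DataFrame(
            columns=["day", "outer_dsc_mean", "outer_dsc_sd", "epi_dsc_mean", "epi_dsc_sd",
                     "bud_error_mean", "bud_error_sd", "n_images"]
        )
    g = per_image.groupby("day")
    agg = pd.DataFrame(
        {
            "outer_dsc_mean": g["outer_dsc"].mean(),
            "outer_dsc_sd": g["outer_dsc"].std(ddof=1),
            "epi_dsc_mean": g["epi_dsc"].mean(),
            "epi_dsc_sd": g["epi_dsc"].std(ddof=1),
            "bud_error_mean": g["bud_error"].mean(),
            "bud_error_sd": g["bud_error"].std(ddof=1),
            "n_images": g["epi_dsc"].size(),
        }
    ).reset_index()
    return agg


def run_batch(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "lungmorph_eval",
) -> pd.DataFrame:
    """Evaluate a manifest of image/truth file pairs; write per-image and
    per-day aggregate CSVs.  Entries with missing truths are skipped with a
    warning."""
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in entries:
        img_p = manifest_path.parent / entry["image"]
        try:
            outer_t = iio.imread(manifest_path.parent / entry["outer_truth"]) > 127
            epi_t = iio.imread(manifest_path.parent / entry["epi_truth"]) > 127
        except (FileNotFoundError, KeyError) as exc:
            log.warning("skipping %s: missing truth (%s)", entry.get("image"), exc)
            continue
        try:
            result = analyze_image(iio.imread(img_p), config, culture_day=entry.get("day"))
        except PipelineError as exc:
            log.warning("skipping %s: pipeline failed (%s)", entry.get("image"), exc)
            continue
        row = {"image": str(entry["image"]), "day": entry.get("day")}
        row.update(_score_one(result, outer_t, epi_t, entry.get("true_buds", 0)))
        rows.append(row)
    if not rows:
        log.warning("empty evaluation: no scorable manifest entries")
    per_image = pd.DataFrame(rows)
    per_image.to_csv(out / "per_image.csv", index=False)
    agg = aggregate_by_day(per_image if rows else per_image.reindex(columns=["day", "outer_dsc", "epi_dsc", "bud_error"]))
    agg.to_csv(out / "per_day.csv", index=False)
    return per_image
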