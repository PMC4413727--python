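"""End-to-end pipeline: simulate → voxelize → measure → fit → compare.

A configured run generates (or loads) labeled voxel scenes, measures every
individual root system, fits the tip-distance model per species ×
treatment group, runs the nonparametric group comparisons, and validates
voxel-based measurements against the generator's analytic ground truth
with zero-intercept regressions. All outputs are plain CSV/JSON written to
the run directory; a fixed seed reproduces every file byte for byte.

Outputs
-------
metrics.csv          one row per individual (volume, surface area, tips,
                     ellipse, depths; mm and cm² columns for areas)
tips.csv             one row per detected tip (x, y, z, nearest-neighbor)
depth_profiles.csv   per-individual depth histogram of root volume
distance_fits.json   per-group (c1, c2, SS_reg/SS_tot, n) of the
                     tip-distance model
comparisons.csv      Kruskal–Wallis + pairwise Wilcoxon results
validation.json      zero-intercept slopes of measured vs. ground truth
run_log.txt          timestamped stage log (the only non-deterministic file)
"""

from __future__ import annotations

import json
import logging
import platform
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .voxel_core import LabelVolume, extract_individual
from .synthetic_roots import (
    DEFAULT_CONTAINER,
    Scene,
    make_experiment,
    voxelize_scene,
)
from .morphometry import (
    depth_profile,
    root_surface_area,
    root_volume,
    volume_weighted_mean_depth,
)
from .tip_spatial import (
    detect_tips,
    fit_tip_ellipse,
    min_tip_distances,
    skeletonize,
)
from .distance_model import DistanceFit, fit_distance_pdf
from .group_stats import (
    ALPHA_FAMILY,
    ALPHA_PAIRWISE,
    GroupComparison,
    compare_groups,
    regression_through_origin,
)

__all__ = [
    "RunConfig",
    "MetricsRecord",
    "RunReport",
    "PAPER_LIKE_DESIGN",
    "run_pipeline",
    "measure_individual",
    "validate_against_truth",
]

#: Study-style 13-container roster: 3 solitary aspen, 1 intra-specific
#: aspen pair, 3 inter-specific pairs, 3 intra-specific spruce pairs,
#: 3 solitary spruce (20 individuals in total).
PAPER_LIKE_DESIGN: list[tuple[str, tuple[str, ...] | str, int]] = [
    ("control", "aspen", 3),
    ("intra", "aspen", 1),
    ("inter", ("aspen", "spruce"), 3),
    ("intra", "spruce", 3),
    ("control", "spruce", 3),
]

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Serializable configuration; config + seed reproduce a run exactly."""

    seed: int = 0
    resolution_mm: float = 0.5
    bin_width_depth_mm: float = 10.0
    bin_width_distance_mm: float = 1.0
    design: list = field(default_factory=lambda: [list(r) for r in PAPER_LIKE_DESIGN])
    collar_rule: str = "shallowest"
    wall_exclusion: bool = True
    alpha_family: float = ALPHA_FAMILY
    alpha_pairwise: float = ALPHA_PAIRWISE
    container: tuple[float, float] = DEFAULT_CONTAINER
    output_dir: str = "rootspace_run"

    def to_json(self) -> str:
        d = asdict(self)
        d["container"] = list(d["container"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "container" in d:
            d["container"] = tuple(d["container"])
        return cls(**d)


@dataclass
class MetricsRecord:
    """Per-individual summary feeding the group-statistics layer."""

    scene_id: str
    individual_id: int
    species_tag: str
    treatment: str
    volume_mm3: float
    surface_area_mm2: float
    tip_count: int
    mean_tip_depth_mm: float
    volume_weighted_mean_depth_mm: float
    ellipse_semi_major_mm: float
    ellipse_semi_minor_mm: float
    axis_ratio: float
    radial_area_mm2: float
    median_min_tip_distance_mm: float


@dataclass
class RunReport:
    config: RunConfig
    records: list[MetricsRecord]
    metrics: pd.DataFrame
    comparisons: list[GroupComparison]
    distance_fits: dict[str, DistanceFit | None]
    validation: dict
    output_dir: Path


def _setup_logger(path: Path) -> logging.Logger:
    logger = logging.getLogger(f"rootspace.run.{path}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(path)):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    logger.propagate = False
    return logger


def measure_individual(
    grid, collar_rule: str = "shallowest", individual_id: int = 0
) -> dict:
    """All per-individual metrics from one binary grid.

    Returns a dict of scalars plus the raw tip coordinates and
    nearest-neighbor distances. Metrics that need a minimum number of tips
    (distances: 2, ellipse: 3 non-collinear) are NaN when undefined.
    """
    vol = root_volume(grid)
    area = root_surface_area(grid)
    skel = skeletonize(grid)
    tips = detect_tips(skel, grid, collar_rule=collar_rule,
                       source_individual=individual_id)
    out: dict = {
        "volume_mm3": vol,
        "surface_area_mm2": area,
        "tip_count": tips.n_tips,
        "tips_mm": tips.tips_mm,
    }
    out["volume_weighted_mean_depth_mm"] = (
        volume_weighted_mean_depth(grid) if vol > 0 else float("nan")
    )
    out["mean_tip_depth_mm"] = (
        float(tips.depths_mm.mean()) if tips.n_tips else float("nan")
    )
    if tips.n_tips >= 2:
        nn = min_tip_distances(tips)
    else:
        nn = np.empty(0)
    out["min_tip_distances_mm"] = nn
    out["median_min_tip_distance_mm"] = (
        float(np.median(nn)) if nn.size else float("nan")
    )
    try:
        fit = fit_tip_ellipse(tips)
        out["ellipse_semi_major_mm"] = fit.semi_major_mm
        out["ellipse_semi_minor_mm"] = fit.semi_minor_mm
        out["axis_ratio"] = fit.axis_ratio
        out["radial_area_mm2"] = fit.area_mm2
    except ValueError:
        out["ellipse_semi_major_mm"] = float("nan")
        out["ellipse_semi_minor_mm"] = float("nan")
        out["axis_ratio"] = float("nan")
        out["radial_area_mm2"] = float("nan")
    return out


def validate_against_truth(
    measured: Sequence[tuple[str, float, float]],
    truth: Sequence[tuple[str, float, float]],
) -> dict:
    """Zero-intercept regressions of 3D-measured on ground-truth values.

    ``measured`` and ``truth`` rows are ``(key, surface_area_mm2,
    tip_count)`` matched by key. Slopes are capture fractions: the part of
    the reference root system actually rendered in the voxel measurement.
    """
    m = {k: (a, t) for k, a, t in measured}
    g = {k: (a, t) for k, a, t in truth}
    missing = sorted(set(m) ^ set(g))
    if missing:
        raise ValueError(f"unmatched individuals in validation join: {missing}")
    keys = sorted(m)
    truth_area = [g[k][0] for k in keys]
    meas_area = [m[k][0] for k in keys]
    truth_tips = [g[k][1] for k in keys]
    meas_tips = [m[k][1] for k in keys]
    slope_area, r2_area = regression_through_origin(truth_area, meas_area)
    slope_tips, r2_tips = regression_through_origin(truth_tips, meas_tips)
    return {
        "surface_area": {"slope": slope_area, "r_squared": r2_area,
                         "n": len(keys)},
        "tip_count": {"slope": slope_tips, "r_squared": r2_tips,
                      "n": len(keys)},
    }


def _comparison_rows(comp: GroupComparison) -> list[dict]:
    base = {
        "parameter": comp.parameter_name,
        "observation_unit": comp.observation_unit,
        "H": comp.H_statistic,
        "p": comp.p_value,
    }
    if not comp.posthoc:
        return [dict(base, pair="", p_pair=float("nan"), significant=False)]
    return [
        dict(base, pair=f"{pr.pair[0]} vs {pr.pair[1]}", p_pair=pr.p_value,
             significant=pr.significant)
        for pr in comp.posthoc
    ]


def run_pipeline(config: RunConfig, scenes: list[Scene] | None = None) -> RunReport:
    """Execute the full pipeline under one configuration.

    ``scenes`` may be supplied (e.g., loaded from annotated stacks);
    otherwise they are generated from ``config.design``. A stage failure
    raises with the stage named; outputs of completed stages remain on
    disk.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(out_dir / "run_log.txt")
    t0 = time.time()
    from . import __version__ as pkg_version

    logger.info(
        "run start: rootspace %s, python %s, seed %d, resolution %g mm",
        pkg_version, platform.python_version(), config.seed,
        config.resolution_mm,
    )
    (out_dir / "config.json").write_text(config.to_json())

    stage = "simulate"
    try:
        if scenes is None:
            design = [
                (row[0], tuple(row[1]) if isinstance(row[1], (list, tuple)) else row[1], row[2])
                for row in config.design
            ]
            scenes = make_experiment(design, base_seed=config.seed,
                                     container=config.container)
        logger.info("simulate: %d scenes", len(scenes))

        stage = "measure"
        records: list[MetricsRecord] = []
        tip_rows: list[dict] = []
        profile_rows: list[dict] = []
        measured_val: list[tuple[str, float, float]] = []
        truth_val: list[tuple[str, float, float]] = []
        pooled_dist: dict[tuple[str, str], list[float]] = {}
        pooled_depth: dict[tuple[str, str], list[float]] = {}

        for scene in scenes:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                volume = voxelize_scene(
                    scene, config.resolution_mm,
                    wall_exclusion=config.wall_exclusion,
                )
            for idx, (tag, truth) in enumerate(scene.individuals, start=1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    grid = extract_individual(volume, idx)
                m = measure_individual(grid, collar_rule=config.collar_rule,
                                       individual_id=idx)
                key = f"{scene.scene_id}/{idx}"
                records.append(MetricsRecord(
                    scene_id=scene.scene_id,
                    individual_id=idx,
                    species_tag=tag,
                    treatment=scene.treatment,
                    volume_mm3=m["volume_mm3"],
                    surface_area_mm2=m["surface_area_mm2"],
                    tip_count=m["tip_count"],
                    mean_tip_depth_mm=m["mean_tip_depth_mm"],
                    volume_weighted_mean_depth_mm=m["volume_weighted_mean_depth_mm"],
                    ellipse_semi_major_mm=m["ellipse_semi_major_mm"],
                    ellipse_semi_minor_mm=m["ellipse_semi_minor_mm"],
                    axis_ratio=m["axis_ratio"],
                    radial_area_mm2=m["radial_area_mm2"],
                    median_min_tip_distance_mm=m["median_min_tip_distance_mm"],
                ))
                measured_val.append((key, m["surface_area_mm2"], m["tip_count"]))
                truth_val.append((key, truth.analytic_surface_area_mm2,
                                  truth.tip_count))
                group = (tag, scene.treatment)
                pooled_dist.setdefault(group, []).extend(
                    float(v) for v in m["min_tip_distances_mm"]
                )
                pooled_depth.setdefault(group, []).extend(
                    float(v) for v in (m["tips_mm"][:, 2] if m["tip_count"] else [])
                )
                nn = m["min_tip_distances_mm"]
                for j, tip in enumerate(m["tips_mm"]):
                    tip_rows.append({
                        "scene_id": scene.scene_id, "individual_id": idx,
                        "species": tag, "treatment": scene.treatment,
                        "x_mm": tip[0], "y_mm": tip[1], "z_mm": tip[2],
                        "nearest_neighbor_dist_mm":
                            nn[j] if nn.size else float("nan"),
                    })
                if m["volume_mm3"] > 0:
                    prof = depth_profile(grid, config.bin_width_depth_mm)
                    for lo, hi, v in zip(prof.bin_edges_mm[:-1],
                                         prof.bin_edges_mm[1:],
                                         prof.volume_per_bin_mm3):
                        profile_rows.append({
                            "scene_id": scene.scene_id, "individual_id": idx,
                            "species": tag, "treatment": scene.treatment,
                            "bin_low_mm": lo, "bin_high_mm": hi,
                            "volume_mm3": v,
                        })
            logger.info("measured scene %s (%d individuals)",
                        scene.scene_id, len(scene.individuals))

        metrics = pd.DataFrame([asdict(r) for r in records])
        if not metrics.empty:
            metrics["surface_area_cm2"] = metrics["surface_area_mm2"] / 100.0
        metrics.to_csv(out_dir / "metrics.csv", index=False,
                       float_format=_FLOAT_FMT)
        pd.DataFrame(tip_rows).to_csv(out_dir / "tips.csv", index=False,
                                      float_format=_FLOAT_FMT)
        pd.DataFrame(profile_rows).to_csv(out_dir / "depth_profiles.csv",
                                          index=False, float_format=_FLOAT_FMT)

        stage = "fit"
        fits: dict[str, DistanceFit | None] = {}
        for (tag, treatment), dists in sorted(pooled_dist.items()):
            name = f"{tag}/{treatment}"
            if len(dists) >= 10:
                fits[name] = fit_distance_pdf(
                    dists, bin_width_mm=config.bin_width_distance_mm,
                    normalize=True,
                )
            else:
                fits[name] = None
        fit_json = {
            name: (fit.to_dict() if fit is not None
                   else {"skipped": "fewer than 10 pooled distances"})
            for name, fit in fits.items()
        }
        (out_dir / "distance_fits.json").write_text(
            json.dumps(fit_json, indent=2, sort_keys=True)
        )
        logger.info("fit: %d groups", len(fits))

        stage = "compare"
        comparisons: list[GroupComparison] = []
        scalar_params = [
            "volume_mm3", "surface_area_mm2", "tip_count", "axis_ratio",
            "radial_area_mm2", "volume_weighted_mean_depth_mm",
            "mean_tip_depth_mm", "median_min_tip_distance_mm",
        ]
        if not metrics.empty:
            for species in sorted(metrics["species_tag"].unique()):
                sub = metrics[metrics["species_tag"] == species]
                for param in scalar_params:
                    groups = {
                        tr: sub.loc[sub["treatment"] == tr, param]
                        .dropna().tolist()
                        for tr in ("control", "intra", "inter")
                    }
                    groups = {k: v for k, v in groups.items() if v}
                    if len(groups) < 2:
                        continue
                    comparisons.append(compare_groups(
                        f"{species}:{param}", groups,
                        alpha_family=config.alpha_family,
                        alpha_pairwise=config.alpha_pairwise,
                        observation_unit="individual",
                    ))
                for param, pooled in (
                    ("min_tip_distance_mm", pooled_dist),
                    ("tip_depth_mm", pooled_depth),
                ):
                    groups = {
                        tr: pooled.get((species, tr), [])
                        for tr in ("control", "intra", "inter")
                    }
                    groups = {k: v for k, v in groups.items() if v}
                    if len(groups) < 2:
                        continue
                    comparisons.append(compare_groups(
                        f"{species}:{param}", groups,
                        alpha_family=config.alpha_family,
                        alpha_pairwise=config.alpha_pairwise,
                        observation_unit="tip",
                    ))
        comp_rows = [row for c in comparisons for row in _comparison_rows(c)]
        pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv",
                                       index=False, float_format=_FLOAT_FMT)
        logger.info("compare: %d comparisons", len(comparisons))

        stage = "validate"
        validation = (
            validate_against_truth(measured_val, truth_val)
            if measured_val else {}
        )
        (out_dir / "validation.json").write_text(
            json.dumps(validation, indent=2, sort_keys=True)
        )
        logger.info("validate: %s", json.dumps(
            {k: round(v["slope"], 3) for k, v in validation.items()})
        )
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info("run complete in %.1f s", time.time() - t0)
    for h in logger.handlers:
        h.close()
    return RunReport(
        config=config,
        records=records,
        metrics=metrics,
        comparisons=comparisons,
        distance_fits=fits,
        validation=validation,
        output_dir=out_dir,
    )
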