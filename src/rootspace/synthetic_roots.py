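"""Stochastic two-species root-scene generator with analytic ground truth.

Real seedling root systems in the study design fall into two architectural
archetypes: a taproot-dominant, sparsely branched conifer form
("spruce-like") and a densely laterally branched broadleaf form
("aspen-like"). This module grows such systems as discrete 1 mm segment
chains — laterals arise as a Poisson process along their parent, growth
direction blends toward the gravity vector and jitters at each step — and
voxelizes one- or two-individual scenes inside a cylindrical container into
a :class:`~rootspace.voxel_core.LabelVolume`.

Because each system is a vector model first (centerline segments with
radii), every scene carries closed-form ground truth: total length
``Σ ℓ``, lateral surface area ``Σ 2π r ℓ``, volume ``Σ π r² ℓ`` and exact
tip coordinates. The ground truth plays the role a destructive harvest
plays for imaged plants: the reference against which voxel-based
measurements are validated.

Coordinates are mm; the container axis is ``x = y = 0`` and z is depth
(positive downward, 0 at the medium surface).

The archetype presets are illustrative geometric stand-ins chosen to match
the two morphologies at the order of magnitude reported for 2-month-old
seedlings (hundreds of tips and metres of root for the aspen-like form,
~a dozen tips and ~20 cm for the spruce-like form); they are not estimates
of any measured plant's parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .voxel_core import LabelVolume

__all__ = [
    "ArchetypeParams",
    "RootSystemTruth",
    "Scene",
    "ASPEN_LIKE",
    "SPRUCE_LIKE",
    "ARCHETYPES",
    "DEFAULT_CONTAINER",
    "generate_root_system",
    "voxelize_scene",
    "truncate_at_wall",
    "wall_truncated_scene",
    "make_scene",
    "make_experiment",
]

STEP_MM = 1.0  # growth step = segment length

TREATMENTS = ("control", "intra", "inter")


@dataclass(frozen=True)
class ArchetypeParams:
    """Growth parameters for one architectural archetype.

    Lengths and radii in mm; ``lateral_rate_per_mm`` is the expected number
    of laterals per mm of parent axis; ``branching_depth`` is the maximum
    lateral order (0 = bare taproot, 1 = first-order laterals, ...);
    ``gravitropism_weight`` in [0, 1] blends each step's direction toward
    straight down; ``tortuosity_sd_deg`` is the per-step angular jitter.
    """

    taproot_length_mm: float
    taproot_radius_mm: float
    lateral_rate_per_mm: float
    lateral_length_distribution: tuple[float, float]  # (mean_mm, sd_mm)
    lateral_radius_mm: float
    branching_depth: int
    insertion_angle_deg: tuple[float, float]  # (mean, sd)
    gravitropism_weight: float
    tortuosity_sd_deg: float

    def __post_init__(self) -> None:
        if self.taproot_length_mm <= 0 or self.taproot_radius_mm <= 0:
            raise ValueError("taproot length and radius must be positive")
        if self.lateral_radius_mm <= 0:
            raise ValueError("lateral_radius_mm must be positive")
        if self.lateral_rate_per_mm < 0:
            raise ValueError("lateral_rate_per_mm must be >= 0")
        if self.branching_depth < 0:
            raise ValueError("branching_depth must be >= 0")
        if not 0.0 <= self.gravitropism_weight <= 1.0:
            raise ValueError("gravitropism_weight must be in [0, 1]")
        if self.tortuosity_sd_deg < 0:
            raise ValueError("tortuosity_sd_deg must be >= 0")


#: Densely branched broadleaf archetype (two lateral orders).
ASPEN_LIKE = ArchetypeParams(
    taproot_length_mm=140.0,
    taproot_radius_mm=0.9,
    lateral_rate_per_mm=0.28,
    lateral_length_distribution=(20.0, 8.0),
    lateral_radius_mm=0.35,
    branching_depth=2,
    insertion_angle_deg=(60.0, 15.0),
    gravitropism_weight=0.12,
    tortuosity_sd_deg=10.0,
)

#: Taproot-dominant conifer archetype (sparse first-order laterals).
SPRUCE_LIKE = ArchetypeParams(
    taproot_length_mm=110.0,
    taproot_radius_mm=0.8,
    lateral_rate_per_mm=0.11,
    lateral_length_distribution=(9.0, 4.0),
    lateral_radius_mm=0.35,
    branching_depth=1,
    insertion_angle_deg=(70.0, 15.0),
    gravitropism_weight=0.30,
    tortuosity_sd_deg=8.0,
)

ARCHETYPES: dict[str, ArchetypeParams] = {
    "aspen": ASPEN_LIKE,
    "spruce": SPRUCE_LIKE,
}

#: (inner_diameter_mm, imaged_depth_mm)
DEFAULT_CONTAINER: tuple[float, float] = (64.0, 150.0)


@dataclass
class RootSystemTruth:
    """Vector-model ground truth for one root system.

    ``segments`` is a list of ``(start_xyz, end_xyz, radius_mm,
    parent_index)`` tuples (xyz are length-3 float arrays, mm;
    ``parent_index`` is -1 for the collar segment). The segment graph is a
    tree: children attach at their parent's distal end, and every axis
    (taproot or lateral) ends in a terminal segment whose distal end is a
    root tip.
    """

    segments: list[tuple[np.ndarray, np.ndarray, float, int]]
    tip_coordinates: list[np.ndarray]
    origin_xyz_mm: np.ndarray
    analytic_length_mm: float
    analytic_surface_area_mm2: float
    analytic_volume_mm3: float
    seed: int

    @property
    def tip_count(self) -> int:
        return len(self.tip_coordinates)

    @property
    def tip_depths_mm(self) -> np.ndarray:
        if not self.tip_coordinates:
            return np.empty(0)
        return np.asarray([t[2] for t in self.tip_coordinates])


@dataclass
class Scene:
    """One container: treatment, individuals, and geometry.

    ``treatment``: "control" (1 individual) or "intra"/"inter" (2
    individuals of the same / different species). ``container`` is
    ``(inner_diameter_mm, depth_mm)``; ``planting_offsets_xy_mm`` gives
    each collar's x-y offset from the container axis.
    """

    treatment: str
    individuals: list[tuple[str, RootSystemTruth]]
    container: tuple[float, float] = DEFAULT_CONTAINER
    planting_offsets_xy_mm: list[tuple[float, float]] = field(default_factory=list)
    scene_id: str = ""

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        n = len(self.individuals)
        if self.treatment == "control" and n != 1:
            raise ValueError("control scenes hold exactly 1 individual")
        if self.treatment in ("intra", "inter") and n != 2:
            raise ValueError(f"{self.treatment} scenes hold exactly 2 individuals")
        if self.treatment == "intra":
            tags = {tag for tag, _ in self.individuals}
            if len(tags) != 1:
                raise ValueError("intra-specific pair must share a species tag")
        if self.treatment == "inter":
            tags = [tag for tag, _ in self.individuals]
            if tags[0] == tags[1]:
                raise ValueError("inter-specific pair must differ in species")
        radius = self.container[0] / 2.0
        for tag, truth in self.individuals:
            x, y = truth.origin_xyz_mm[0], truth.origin_xyz_mm[1]
            if x * x + y * y > radius * radius:
                raise ValueError(
                    f"collar of {tag} at ({x}, {y}) lies outside the container"
                )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector perpendicular to v with random azimuth about v."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, v)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(v, helper))
    e2 = np.cross(v, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2


def _rotate_toward(v: np.ndarray, angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vector v by angle_rad around a random perpendicular azimuth."""
    if angle_rad == 0.0:
        return v
    p = _perpendicular(v, rng)
    return _unit(np.cos(angle_rad) * v + np.sin(angle_rad) * p)


_DOWN = np.array([0.0, 0.0, 1.0])  # z is depth: "down" increases z


def _grow_axis(
    start: np.ndarray,
    direction: np.ndarray,
    length_mm: float,
    radius: float,
    parent_index: int,
    params: ArchetypeParams,
    rng: np.random.Generator,
    segments: list,
    axis_last_segment: list[int],
    branch_sites: list[tuple[int, int]],
    order: int,
) -> None:
    """Grow one axis of 1 mm steps, recording segments and branch sites.

    Direction per step blends toward +z (depth) by gravitropism_weight and
    is jittered by a normal angle of sd tortuosity_sd_deg. Lateral
    initiation sites are drawn as Poisson(rate·step) per step and recorded
    for later growth (breadth-first over orders keeps segment indices
    parent-before-child).
    """
    n_steps = max(1, int(round(length_mm / STEP_MM)))
    pos = start.astype(float)
    d = _unit(direction)
    prev_index = parent_index
    for step in range(n_steps):
        d = _unit((1.0 - params.gravitropism_weight) * d + params.gravitropism_weight * _DOWN)
        jitter = rng.normal(0.0, np.deg2rad(params.tortuosity_sd_deg))
        d = _rotate_toward(d, jitter, rng)
        end = pos + d * STEP_MM
        segments.append((pos.copy(), end.copy(), radius, prev_index))
        prev_index = len(segments) - 1
        # the apical (final) step never branches, so a terminal segment is
        # exactly one with no same-radius child at its distal end
        if order < params.branching_depth and step < n_steps - 1:
            n_lat = rng.poisson(params.lateral_rate_per_mm * STEP_MM)
            for _ in range(int(n_lat)):
                branch_sites.append((prev_index, order + 1))
        pos = end
    axis_last_segment.append(prev_index)


def generate_root_system(
    params: ArchetypeParams,
    origin_xyz: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> RootSystemTruth:
    """Grow one stochastic root system; reproducible given (params, seed).

    The taproot starts at ``origin_xyz`` heading straight down; laterals
    insert at their parent's distal step ends at a normal insertion angle
    with uniform random azimuth. Degenerate parameters (zero lateral rate)
    yield a bare taproot with a single apex tip.
    """
    rng = np.random.default_rng(seed)
    origin = np.asarray(origin_xyz, dtype=float)
    segments: list[tuple[np.ndarray, np.ndarray, float, int]] = []
    axis_last: list[int] = []
    sites: list[tuple[int, int]] = []

    _grow_axis(
        origin, _DOWN, params.taproot_length_mm, params.taproot_radius_mm,
        -1, params, rng, segments, axis_last, sites, order=0,
    )
    # breadth-first over lateral orders so parents always precede children
    mean_len, sd_len = params.lateral_length_distribution
    mean_ang, sd_ang = params.insertion_angle_deg
    while sites:
        next_sites: list[tuple[int, int]] = []
        for parent_idx, order in sites:
            p_start, p_end, _, _ = segments[parent_idx]
            parent_dir = _unit(p_end - p_start)
            angle = np.deg2rad(rng.normal(mean_ang, sd_ang))
            d0 = _rotate_toward(parent_dir, angle, rng)
            lat_len = max(STEP_MM, rng.normal(mean_len, sd_len))
            _grow_axis(
                p_end, d0, lat_len, params.lateral_radius_mm,
                parent_idx, params, rng, segments, axis_last, next_sites, order,
            )
        sites = next_sites

    return _finalize_truth(segments, axis_last, origin, seed)


def _finalize_truth(
    segments: list,
    axis_last: list[int],
    origin: np.ndarray,
    seed: int,
) -> RootSystemTruth:
    lengths = np.asarray([np.linalg.norm(e - s) for s, e, _, _ in segments])
    radii = np.asarray([r for _, _, r, _ in segments])
    tips = [segments[i][1].copy() for i in sorted(axis_last)]
    return RootSystemTruth(
        segments=segments,
        tip_coordinates=tips,
        origin_xyz_mm=origin,
        analytic_length_mm=float(lengths.sum()),
        analytic_surface_area_mm2=float((2.0 * np.pi * radii * lengths).sum()),
        analytic_volume_mm3=float((np.pi * radii**2 * lengths).sum()),
        seed=seed,
    )


def truncate_at_wall(
    truth: RootSystemTruth, container: tuple[float, float]
) -> RootSystemTruth:
    """Cut the vector model where roots meet the container wall.

    Tracing of a real root ceases once it contacts the wall; here a point
    contacts the wall when its radial distance from the container axis
    reaches ``inner_radius - segment_radius``. The first contact truncates
    its segment there and drops all distal material (including laterals
    attached beyond the cut). Cut ends become terminal, so they count as
    tips of the truncated model.
    """
    wall_r = container[0] / 2.0
    kept: list[tuple[np.ndarray, np.ndarray, float, int]] = []
    index_map: dict[int, int] = {}  # old index -> new index
    truncated: set[int] = set()  # old indices whose distal end was cut/killed
    has_child_at_end: dict[int, bool] = {}

    for old_idx, (s, e, r, parent) in enumerate(truth.segments):
        if parent >= 0 and (parent in truncated or parent not in index_map):
            truncated.add(old_idx)  # detached: parent gone or cut
            continue
        limit = wall_r - r
        rs = float(np.hypot(s[0], s[1]))
        re_ = float(np.hypot(e[0], e[1]))
        if rs >= limit:
            truncated.add(old_idx)
            continue
        if re_ >= limit:
            # first crossing of |xy| = limit along the segment
            t = _radial_crossing(s, e, limit)
            e = s + t * (e - s)
            truncated.add(old_idx)
            if np.linalg.norm(e - s) < 1e-9:
                continue
        new_parent = index_map[parent] if parent >= 0 else -1
        index_map[old_idx] = len(kept)
        kept.append((s.copy(), e.copy(), r, new_parent))
        if new_parent >= 0:
            has_child_at_end.setdefault(new_parent, False)

    # terminal iff no child continues the axis: a continuation child starts
    # at the distal end with the same radius (laterals differ in radius or,
    # for same-radius orders, still start at the parent's end — radius +
    # position test is the generator's structural signature)
    axis_last = []
    children: dict[int, list[int]] = {}
    for i, (_, _, _, p) in enumerate(kept):
        if p >= 0:
            children.setdefault(p, []).append(i)
    for i, (s, e, r, _) in enumerate(kept):
        cont = any(kept[c][2] == r and np.allclose(kept[c][0], e) for c in children.get(i, []))
        if not cont:
            axis_last.append(i)

    if not kept:
        return RootSystemTruth(
            segments=[], tip_coordinates=[], origin_xyz_mm=truth.origin_xyz_mm,
            analytic_length_mm=0.0, analytic_surface_area_mm2=0.0,
            analytic_volume_mm3=0.0, seed=truth.seed,
        )
    return _finalize_truth(kept, axis_last, truth.origin_xyz_mm, truth.seed)


def _radial_crossing(s: np.ndarray, e: np.ndarray, limit: float) -> float:
    """Smallest t in [0,1] with |xy(s + t(e-s))| = limit (exists by caller)."""
    d = e - s
    a = d[0] ** 2 + d[1] ** 2
    b = 2.0 * (s[0] * d[0] + s[1] * d[1])
    c = s[0] ** 2 + s[1] ** 2 - limit**2
    if a < 1e-15:
        return 1.0
    disc = max(b * b - 4 * a * c, 0.0)
    t = (-b + np.sqrt(disc)) / (2 * a)
    return float(np.clip(t, 0.0, 1.0))


def wall_truncated_scene(scene: Scene) -> Scene:
    """Scene with every individual's vector model cut at the wall."""
    individuals = [
        (tag, truncate_at_wall(truth, scene.container))
        for tag, truth in scene.individuals
    ]
    return replace(scene, individuals=individuals)


def voxelize_scene(
    scene: Scene,
    resolution_mm: float,
    wall_exclusion: bool = False,
) -> LabelVolume:
    """Rasterize a scene into a labeled voxel volume.

    A voxel belongs to individual ``i`` when its center lies inside some
    segment's finite cylinder: axial projection within the segment, radial
    distance ≤ the segment radius. Where two individuals claim a voxel the
    nearer centerline wins (ties go to the lower id). With
    ``wall_exclusion`` the vector models are first cut at the container
    wall (see :func:`truncate_at_wall`), mirroring annotation protocols
    that stop tracing at wall contact.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution_mm must be positive")
    diameter, depth = scene.container
    n_xy = int(np.ceil(diameter / resolution_mm))
    n_z = int(np.ceil(depth / resolution_mm))
    shape = (n_xy, n_xy, n_z)
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float64)
    # voxel-center coordinates: x_i = -D/2 + (i + 0.5) h, z_k = (k + 0.5) h
    x0 = -diameter / 2.0
    h = resolution_mm

    work = wall_truncated_scene(scene) if wall_exclusion else scene
    thin = [
        tag
        for tag, truth in work.individuals
        if any(r < resolution_mm / 2.0 for _, _, r, _ in truth.segments)
    ]
    if thin:
        warnings.warn(
            f"segment radius below resolution/2 for {sorted(set(thin))}; "
            "thin structures may be undersampled",
            stacklevel=2,
        )

    for ind_id, (_tag, truth) in enumerate(work.individuals, start=1):
        for s, e, r, _ in truth.segments:
            _stamp_segment(labels, best, ind_id, s, e, r, x0, h, shape)
    color_map = {
        i: _default_color(i) for i in range(1, len(work.individuals) + 1)
    }
    return LabelVolume(
        labels=labels, resolution_mm=resolution_mm, z_origin=0.0,
        color_map=color_map,
    )


def _default_color(i: int) -> tuple[int, int, int]:
    palette = [(230, 120, 20), (40, 90, 200), (30, 160, 60), (180, 40, 150)]
    return palette[(i - 1) % len(palette)]


def _stamp_segment(
    labels: np.ndarray,
    best: np.ndarray,
    ind_id: int,
    s: np.ndarray,
    e: np.ndarray,
    r: float,
    x0: float,
    h: float,
    shape: tuple[int, int, int],
) -> None:
    """Mark voxels inside one segment's finite cylinder, nearest-wins."""
    d = e - s
    length = np.linalg.norm(d)
    if length < 1e-12:
        return
    u = d / length
    lo = np.minimum(s, e) - r
    hi = np.maximum(s, e) + r
    origin = np.array([x0, x0, 0.0])
    i0 = np.maximum(np.floor((lo - origin) / h - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / h + 0.5).astype(int), np.asarray(shape) - 1)
    if np.any(i0 > i1):
        return
    ax = origin[0] + (np.arange(i0[0], i1[0] + 1) + 0.5) * h
    ay = origin[1] + (np.arange(i0[1], i1[1] + 1) + 0.5) * h
    az = origin[2] + (np.arange(i0[2], i1[2] + 1) + 0.5) * h
    px = ax[:, None, None] - s[0]
    py = ay[None, :, None] - s[1]
    pz = az[None, None, :] - s[2]
    t = px * u[0] + py * u[1] + pz * u[2]
    norm2 = px * px + py * py + pz * pz
    rad2 = norm2 - t * t
    inside = (t >= 0.0) & (t <= length) & (rad2 <= r * r)
    if not inside.any():
        return
    rad = np.sqrt(np.maximum(rad2, 0.0))
    sl = (slice(i0[0], i1[0] + 1), slice(i0[1], i1[1] + 1), slice(i0[2], i1[2] + 1))
    sub_best = best[sl]
    sub_labels = labels[sl]
    win = inside & (
        (rad < sub_best) | ((rad == sub_best) & (ind_id < sub_labels))
    )
    sub_best[win] = rad[win]
    sub_labels[win] = ind_id


def make_scene(
    treatment: str,
    species: tuple[str, ...] | str,
    seed: int,
    container: tuple[float, float] = DEFAULT_CONTAINER,
    archetypes: dict[str, ArchetypeParams] | None = None,
    pair_offset_mm: float | None = None,
    scene_id: str = "",
) -> Scene:
    """Build one scene: grow each individual at its planting position.

    Paired individuals are planted at symmetric offsets from the container
    axis (default: half the container radius). Per-individual seeds derive
    from ``seed`` as ``seed * 2 + position``.
    """
    arch = archetypes if archetypes is not None else ARCHETYPES
    if isinstance(species, str):
        species = (species,)
    if treatment == "control":
        tags = (species[0],)
    elif treatment == "intra":
        tags = (species[0], species[0])
    elif treatment == "inter":
        if len(species) < 2:
            raise ValueError("inter-specific scenes need two species tags")
        tags = (species[0], species[1])
    else:
        raise ValueError(f"unknown treatment {treatment!r}")

    radius = container[0] / 2.0
    if len(tags) == 1:
        offsets = [(0.0, 0.0)]
    else:
        off = pair_offset_mm if pair_offset_mm is not None else radius / 2.0
        offsets = [(-off, 0.0), (off, 0.0)]

    individuals = []
    for pos, tag in enumerate(tags):
        if tag not in arch:
            raise ValueError(f"no archetype preset for species {tag!r}")
        truth = generate_root_system(
            arch[tag],
            origin_xyz=(offsets[pos][0], offsets[pos][1], 0.0),
            seed=seed * 2 + pos,
        )
        individuals.append((tag, truth))
    return Scene(
        treatment=treatment,
        individuals=individuals,
        container=container,
        planting_offsets_xy_mm=offsets,
        scene_id=scene_id or f"{treatment}-{'-'.join(tags)}-{seed}",
    )


def make_experiment(
    design: Sequence[tuple[str, tuple[str, ...] | str, int]],
    base_seed: int,
    container: tuple[float, float] = DEFAULT_CONTAINER,
    archetypes: dict[str, ArchetypeParams] | None = None,
) -> list[Scene]:
    """Instantiate a replicated design as a list of scenes.

    ``design`` rows are ``(treatment, species or species pair,
    n_replicates)``. Scene seeds are ``base_seed + running replicate
    index``, so two runs with the same base seed produce identical scenes.
    """
    scenes: list[Scene] = []
    idx = 0
    for treatment, species, n_rep in design:
        if n_rep < 1:
            raise ValueError("n_replicates must be >= 1")
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        for rep in range(n_rep):
            tag = species if isinstance(species, str) else "-".join(species)
            scenes.append(
                make_scene(
                    treatment,
                    species,
                    seed=base_seed + idx,
                    container=container,
                    archetypes=archetypes,
                    scene_id=f"{treatment}_{tag}_r{rep}",
                )
            )
            idx += 1
    return scenes
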