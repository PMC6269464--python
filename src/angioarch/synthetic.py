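"""Seeded generation of 3D binary vascular phantoms and signal depletion.

Phantoms are unions of rasterized tubes: each vessel is a jittered polyline
centerline thickened to a radius; radii are chosen so the cross-section
areas span the caliber classes.  A hierarchy probability controls how often
a smaller vessel is seeded on an existing larger vessel, emulating
microvessels deployed adjacent to vessels of larger caliber.  The random
depletion routine deletes an exact count of uniformly chosen signal voxels,
emulating artefactual signal loss (imperfect staining, bleaching,
segmentation) for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .caliber import OVER_LABEL, CaliberClassScheme, ClassifiedStack
from .grid import DEFAULT_VOXEL_SIZE_UM, BinaryStack, GridMeta


@dataclass(frozen=True)
class VesselPopulation:
    """A population of vessels sharing one target radius.

    ``radius_um`` is the tube radius; the intended cross-section area is
    π·r², so radii below ~4.9 µm keep vessels inside the analyzable
    (< 75 µm²) range.  ``max_length_um`` optionally caps the centerline
    length (otherwise vessels run until they exit the grid).
    ``hierarchy`` overrides the spec-level hierarchical-seeding probability
    for this population (None = use the spec value).
    """

    radius_um: float
    count: int
    max_length_um: float | None = None
    hierarchy: float | None = None

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic vascular stack.

    ``hierarchy`` is the probability that a vessel is seeded on the surface
    of an already-drawn (larger) vessel rather than independently.
    ``placement`` controls where independently seeded ("infiltrating")
    vessels start: ``"uniform"`` draws positions uniformly at random;
    ``"stratified"`` consumes the cells of a shuffled ``cells_per_axis``³
    partition of the grid so successive vessels spread into fresh
    territory; ``"hypoxic"`` seeds each infiltrating vessel in the least
    vascularized tissue (jittered farthest-point sampling on the distance
    map to existing signal), emulating hypoxia-driven angiogenic sprouting.
    ``tortuosity_deg`` is the maximal angular jitter per unit step of the
    centerline walk.  Identical spec + seed produce identical stacks.
    """

    grid: GridMeta = GridMeta(DEFAULT_VOXEL_SIZE_UM, (256, 256, 256))
    populations: tuple[VesselPopulation, ...] = ()
    orientation_model: str = "uniform"  # "uniform" | "axis"
    placement: str = "uniform"  # "uniform" | "stratified" | "hypoxic"
    cells_per_axis: int = 4
    hierarchy: float = 0.0
    tortuosity_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation_model not in ("uniform", "axis"):
            raise ValueError(f"unknown orientation model {self.orientation_model!r}")
        if self.placement not in ("uniform", "stratified", "hypoxic"):
            raise ValueError(f"unknown placement model {self.placement!r}")
        if self.cells_per_axis < 1:
            raise ValueError("cells_per_axis must be >= 1")
        if not 0 <= self.hierarchy <= 1:
            raise ValueError("hierarchy must be in [0, 1]")


@dataclass(frozen=True)
class DepletionSpec:
    """Exact-count random deletion of a fraction of the signal."""

    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


def _random_direction(rng: np.random.Generator, model: str) -> np.ndarray:
    if model == "axis":
        axis = rng.integers(3)
        d = np.zeros(3)
        d[axis] = 1.0
        return d
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _jitter_direction(
    rng: np.random.Generator, direction: np.ndarray, max_angle_rad: float
) -> np.ndarray:
    """Rotate ``direction`` by a random angle <= max_angle_rad."""
    if max_angle_rad <= 0:
        return direction
    perturbed = direction + np.tan(max_angle_rad) * rng.uniform(-1, 1, size=3)
    n = np.linalg.norm(perturbed)
    return direction if n < 1e-9 else perturbed / n


def _walk_centerline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    shape: tuple[int, int, int],
    max_angle_rad: float,
    max_steps: int | None,
) -> list[np.ndarray]:
    """Polyline through ``start``, walked in both directions until it exits
    the grid (or exhausts ``max_steps`` total), jittered per unit step."""
    lo = -0.5
    hi = np.array(shape) - 0.5
    points = [start.copy()]
    budget = np.inf if max_steps is None else max_steps
    for sign in (1.0, -1.0):
        pos = start.copy()
        d = sign * direction
        half = budget / 2
        steps = 0
        while steps < half:
            d = _jitter_direction(rng, d, max_angle_rad)
            pos = pos + d
            if np.any(pos < lo) or np.any(pos >= hi):
                break
            points.append(pos.copy())
            steps += 1
    return points


def generate_phantom(
    spec: PhantomSpec, scheme: CaliberClassScheme | None = None
) -> tuple[BinaryStack, dict]:
    """Rasterize a phantom and report its ground truth.

    Populations are drawn from largest to smallest radius so hierarchical
    seeding always finds larger parents.  A vessel's voxels are those whose
    centers lie within the population radius of its centerline.  The ground
    truth lists, per population, the vessel count, its own voxel count
    (before union with other populations) and the intended caliber class of
    a straight axis-aligned tube of that radius.

    Overlapping vessels are counted once (binary union).  If hierarchical
    seeding is requested but no parent exists yet, seeding falls back to a
    uniform random position (recorded in the report).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid.shape
    voxel = spec.grid.voxel_size_um
    if scheme is None:
        scheme = (
            CaliberClassScheme()
            if np.isclose(voxel, DEFAULT_VOXEL_SIZE_UM)
            else CaliberClassScheme.from_voxel_size(voxel)
        )
    union = np.zeros(shape, dtype=bool)
    report: dict = {"seed": spec.seed, "populations": [], "hierarchy_fallbacks": 0}
    pops = sorted(spec.populations, key=lambda p: -p.radius_um)
    max_angle = np.deg2rad(spec.tortuosity_deg)

    cell_queue: list[tuple[int, int, int]] = []
    # working distance-to-signal map for hypoxic placement; refreshed per
    # population wave and updated by farthest-point suppression in between
    hypoxia_state: dict = {"dist": None}
    coord_grids = None

    def _independent_start() -> np.ndarray:
        nonlocal coord_grids
        if spec.placement == "uniform":
            return rng.uniform(0, 1, size=3) * (np.array(shape) - 1)
        if spec.placement == "stratified":
            if not cell_queue:
                k = spec.cells_per_axis
                cells = [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]
                cell_queue.extend(cells[i] for i in rng.permutation(len(cells)))
            cell = np.array(cell_queue.pop())
            size = np.array(shape) / spec.cells_per_axis
            return (cell + rng.uniform(0, 1, size=3)) * size - 0.5
        # hypoxic: jittered farthest-point sampling on the distance map
        dist = hypoxia_state["dist"]
        if dist is None or not np.isfinite(dist).any():
            return rng.uniform(0, 1, size=3) * (np.array(shape) - 1)
        candidates = np.flatnonzero(dist >= 0.8 * dist.max())
        start = np.array(np.unravel_index(rng.choice(candidates), shape), dtype=float)
        if coord_grids is None:
            coord_grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        d_to_start = np.sqrt(sum((g - c) ** 2 for g, c in zip(coord_grids, start)))
        hypoxia_state["dist"] = np.minimum(dist, d_to_start)
        return start
    for pop in pops:
        r_vox = pop.radius_um / voxel
        if r_vox < 0.5:
            report.setdefault("warnings", []).append(
                f"radius {pop.radius_um} µm is below half a voxel; vessels may rasterize empty"
            )
        centerline = np.zeros(shape, dtype=bool)
        parent_voxels = np.argwhere(union)
        dist_to_signal = (
            ndimage.distance_transform_edt(~union) if union.any() else None
        )
        if spec.placement == "hypoxic":
            hypoxia_state["dist"] = None if dist_to_signal is None else dist_to_signal.copy()
        max_steps = None if pop.max_length_um is None else int(pop.max_length_um / voxel)
        hierarchy = spec.hierarchy if pop.hierarchy is None else pop.hierarchy
        # deterministic split: the hierarchical fraction of the population is
        # seeded on parents, the rest infiltrates; infiltrating vessels go
        # first so hierarchical ones may also attach to them
        n_hier = int(round(hierarchy * pop.count))
        for j in range(pop.count):
            use_parent = j >= pop.count - n_hier
            if use_parent and len(parent_voxels) > 0:
                start = parent_voxels[rng.integers(len(parent_voxels))].astype(float)
                # climb the distance-to-signal gradient until the daughter
                # lumen clears the parent wall: the vessel stays adjacent
                # (~1 voxel gap) but the projected cross-sections of parent
                # and daughter no longer merge into one section
                if dist_to_signal is not None:
                    pos = tuple(start.astype(int))
                    for _ in range(int(3 * r_vox) + 4):
                        if dist_to_signal[pos] > r_vox + 0.6:
                            break
                        lo = np.maximum(np.array(pos) - 1, 0)
                        hi = np.minimum(np.array(pos) + 2, shape)
                        nb = dist_to_signal[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                        step = np.unravel_index(np.argmax(nb), nb.shape)
                        new_pos = tuple(lo + np.array(step))
                        if new_pos == pos:
                            break
                        pos = new_pos
                    start = np.array(pos, dtype=float)
            else:
                if use_parent:
                    report["hierarchy_fallbacks"] += 1
                start = np.clip(_independent_start(), 0, np.array(shape) - 1)
            direction = _random_direction(rng, spec.orientation_model)
            for p in _walk_centerline(rng, start, direction, shape, max_angle, max_steps):
                centerline[tuple(np.round(p).astype(int))] = True
        if centerline.any():
            dist = ndimage.distance_transform_edt(~centerline)
            mask = dist <= r_vox
        else:
            mask = centerline
        union |= mask
        intended_area = np.pi * pop.radius_um ** 2
        report["populations"].append(
            {
                "radius_um": pop.radius_um,
                "count": pop.count,
                "voxels": int(mask.sum()),
                "intended_area_um2": intended_area,
                "intended_class": int(scheme.classify_areas(np.array([intended_area]))[0]),
            }
        )
    report["total_signal_voxels"] = int(union.sum())
    return BinaryStack(spec.grid, union), report


def deplete_random(stack: BinaryStack, spec: DepletionSpec) -> BinaryStack:
    """Delete exactly ``round(fraction × N)`` signal voxels, chosen uniformly
    without replacement; background is untouched."""
    rng = np.random.default_rng(spec.seed)
    flat = np.flatnonzero(stack.voxels)
    n_delete = int(round(spec.fraction * flat.size))
    out = stack.voxels.copy()
    if n_delete > 0:
        kill = rng.choice(flat, size=n_delete, replace=False)
        out.flat[kill] = False
    return stack.with_voxels(out)


def deplete_classes(
    stack: BinaryStack,
    classified: ClassifiedStack,
    classes: tuple[int, ...],
    fraction: float,
    seed: int = 0,
    mode: str = "components",
) -> BinaryStack:
    """Delete a fraction of the signal of selected caliber classes.

    Used to emulate a vascular-targeted treatment: removing part of the
    largest- and smallest-caliber signal mimics the pruning of large
    vessels and the loss of microvessels seen under anti-angiogenic drugs.

    ``mode="components"`` (default) removes whole vessels: 26-connected
    components of the full signal whose dominant caliber label is the
    targeted class, drawn in random order until at least ``fraction`` of
    the class volume is gone.  Scattering holes into a large vessel would
    merely fragment it into smaller calibers, and deleting only the voxels
    carrying the class label would leave the vessel's end caps (whose
    sections read smaller) behind as debris; a pruned vessel disappears
    entirely.  ``mode="voxels"`` deletes individual class-labeled voxels
    uniformly (exact count), like :func:`deplete_random` restricted to the
    class.
    """
    if mode not in ("components", "voxels"):
        raise ValueError(f"unknown depletion mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = stack.voxels.copy()
    if mode == "voxels":
        for k in classes:
            flat = np.flatnonzero(classified.labels == k)
            n_delete = int(round(fraction * flat.size))
            if n_delete > 0:
                kill = rng.choice(flat, size=n_delete, replace=False)
                out.flat[kill] = False
        return stack.with_voxels(out)
    comp_labels, n = ndimage.label(stack.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    # dominant caliber class per component: most frequent nonzero label
    dominant = np.zeros(n + 1, dtype=np.int64)
    class_volume = {k: 0 for k in classes}
    comp_class_volume: dict[int, dict[int, int]] = {}
    for comp in range(1, n + 1):
        lab = classified.labels[comp_labels == comp]
        lab = lab[(lab > 0) & (lab != OVER_LABEL)] if (lab > 0).any() else lab
        if lab.size:
            vals, counts = np.unique(lab, return_counts=True)
            dominant[comp] = vals[np.argmax(counts)]
            comp_class_volume[comp] = dict(zip(vals.tolist(), counts.tolist()))
    for k in classes:
        class_volume[k] = int((classified.labels == k).sum())
    for k in classes:
        total = class_volume[k]
        if total == 0 or fraction == 0:
            continue
        members = [c for c in range(1, n + 1) if dominant[c] == k]
        target = fraction * total
        removed = 0.0
        skipped: list[int] = []
        for comp in rng.permutation(members):
            if removed >= target:
                break
            share = comp_class_volume.get(int(comp), {}).get(k, 0)
            # cap the overshoot so pruning one giant vascular tree cannot
            # silently wipe out the whole class
            if removed + share <= 1.3 * target:
                out[comp_labels == comp] = False
                removed += share
            else:
                skipped.append(int(comp))
        # components overshooting the cap stay; under-target removal is
        # preferred over wiping out a class entirely
    return stack.with_voxels(out)


#: Template of the packaged cohort: (radius µm, vessel count, max length µm,
#: hierarchical fraction); one population per caliber class at 0.54 µm
#: voxels.  Radii sit just above each class's lower area boundary so the
#: up-to-√3 obliquity factor of the projected-section measurement keeps a
#: straight vessel inside its octave-wide class.  Counts grow toward small
#: calibers while the hierarchical (parent-attached) fraction leaves a
#: slowly growing number of infiltrating vessels per class, which under
#: hypoxia-guided seeding yields near-linear V/D curves in a realistic
#: V% ~0.5–2.5 range.  Tuning constants of the fixture.
COHORT_TEMPLATE = (
    (3.53, 5, 11.5, 0.0),
    (2.49, 6, 16.0, 0.5),
    (1.77, 7, 16.0, 0.57),
    (1.25, 10, 18.0, 0.5),
    (0.88, 12, 21.0, 0.58),
    (0.63, 16, 22.0, 0.63),
    (0.44, 24, 30.0, 0.67),
)


def default_cohort(
    n_samples: int = 8,
    shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    hierarchy: float = 0.7,
    tortuosity_deg: float = 6.0,
    base_seed: int = 2021,
) -> list[tuple[str, PhantomSpec]]:
    """Specs of the packaged hierarchical phantom cohort.

    Emulates the sampling design of two z-stacks per tumor and one tumor
    per animal: consecutive sample pairs share a per-tumor vessel-count
    multiplier, individual stacks differ by seed.  Sample ids are
    ``t{tumor}_s{stack}``.  Placement is hypoxia-guided; per-population
    hierarchical fractions come from :data:`COHORT_TEMPLATE` (``hierarchy``
    applies to populations without an explicit value).
    """
    rng = np.random.default_rng(base_seed)
    grid = GridMeta(voxel_size_um, shape)
    cohort = []
    for i in range(n_samples):
        tumor = i // 2
        if i % 2 == 0:
            tumor_scale = rng.uniform(0.85, 1.15)
        pops = tuple(
            VesselPopulation(
                radius_um=r,
                count=max(1, int(round(c * tumor_scale))),
                max_length_um=max_len,
                hierarchy=h,
            )
            for r, c, max_len, h in COHORT_TEMPLATE
        )
        cohort.append(
            (
                f"t{tumor + 1}_s{i % 2 + 1}",
                PhantomSpec(
                    grid=grid,
                    populations=pops,
                    orientation_model="uniform",
                    placement="hypoxic",
                    hierarchy=hierarchy,
                    tortuosity_deg=tortuosity_deg,
                    seed=int(rng.integers(2 ** 31)),
                ),
            )
        )
    return cohort
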