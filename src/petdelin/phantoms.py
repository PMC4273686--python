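"""Digital phantoms: analytic lesion geometry, activity maps, exact ground truth.

Four phantom families are supported:

* the NEMA IQ sphere set (six hot spheres, 10-37 mm, on a 57.2 mm radius ring);
* a cylindrical body (300 x 221 mm) with seven spheres (7-37 mm) placed
  radially around the central transaxial slice;
* the same cylinder with seven 42 mm spherical shells enclosing cold
  ("necrotic") cores of 7-37 mm at background activity;
* six procedurally generated irregular lesions (seeded unions of overlapping
  balls) whose volumes span roughly the sphere-volume range.

Voxelization rule: a voxel belongs to a lesion iff its *centre* lies inside
the analytic surface (boundary inclusive).  The same rule is used everywhere,
so masks can be checked against a brute-force per-voxel scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .core import BinaryMask, BoundingBox, GridSpec, VoxelVolume, standard_grid

__all__ = [
    "SphereLesion",
    "ShellLesion",
    "IrregularLesion",
    "CylinderBody",
    "PhantomSpec",
    "NEMA_SPHERE_DIAMETERS_MM",
    "SYNTHETIC_SPHERE_DIAMETERS_MM",
    "NEMA_BACKGROUND_KBQ_ML",
    "build_nema_iq_spec",
    "build_synthetic_spec",
    "voxelize",
    "core_mask",
    "fit_sphere_ground_truth",
    "sphere_volume_ml",
]

NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SYNTHETIC_SPHERE_DIAMETERS_MM = (7.0, 10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
NEMA_BACKGROUND_KBQ_ML = 5.2
#: ring radius for sphere centres in the 300 mm synthetic cylinder; clears the
#: body wall for the 42 mm shells (114.4 + 21 < 150)
SYNTHETIC_RING_RADIUS_MM = 114.4
#: standard NEMA IQ sphere-centre circle (114.4 mm diameter)
NEMA_RING_RADIUS_MM = 57.2


def sphere_volume_ml(diameter_mm: float) -> float:
    """Analytic sphere volume (4/3) pi (d/2)^3, in ml."""
    return (4.0 / 3.0) * math.pi * (diameter_mm / 2.0) ** 3 / 1000.0


@dataclass(frozen=True)
class SphereLesion:
    """Uniform hot sphere; ``activity_ratio`` is lesion:background."""

    center: tuple[float, float, float]
    diameter: float
    activity_ratio: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"sphere diameter must be positive, got {self.diameter}")
        if self.activity_ratio <= 0:
            raise ValueError(f"activity ratio must be positive, got {self.activity_ratio}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def bounding_radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return r2 <= (self.diameter / 2.0) ** 2

    def relative_activity(self, x, y, z, inside):
        return np.where(inside, self.activity_ratio, 0.0)


@dataclass(frozen=True)
class ShellLesion:
    """Hot spherical shell around a cold core (core at background by default)."""

    center: tuple[float, float, float]
    outer_diameter: float
    core_diameter: float
    shell_activity_ratio: float
    core_activity_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.core_diameter < self.outer_diameter):
            raise ValueError(
                "need 0 < core_diameter < outer_diameter, got "
                f"core={self.core_diameter}, outer={self.outer_diameter}"
            )
        if self.shell_activity_ratio <= 0 or self.core_activity_ratio <= 0:
            raise ValueError("activity ratios must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def bounding_radius(self) -> float:
        return self.outer_diameter / 2.0

    def _r2(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2

    def contains(self, x, y, z) -> np.ndarray:
        """Hot support = the shell (outer ball minus core)."""
        r2 = self._r2(x, y, z)
        return (r2 <= (self.outer_diameter / 2.0) ** 2) & (
            r2 > (self.core_diameter / 2.0) ** 2
        )

    def core_contains(self, x, y, z) -> np.ndarray:
        return self._r2(x, y, z) <= (self.core_diameter / 2.0) ** 2

    def relative_activity(self, x, y, z, inside):
        act = np.where(inside, self.shell_activity_ratio, 0.0)
        core = self.core_contains(x, y, z)
        return np.where(core, self.core_activity_ratio, act)


@dataclass(frozen=True)
class IrregularLesion:
    """Union of overlapping balls, uniform uptake inside the union."""

    balls: tuple[tuple[tuple[float, float, float], float], ...]  # ((cx,cy,cz), radius)
    activity_ratio: float

    def __post_init__(self) -> None:
        if not self.balls:
            raise ValueError("irregular lesion needs at least one ball")
        if self.activity_ratio <= 0:
            raise ValueError("activity ratio must be positive")
        if any(r <= 0 for _, r in self.balls):
            raise ValueError("ball radii must be positive")

    @property
    def center(self) -> tuple[float, float, float]:
        c = np.mean([b[0] for b in self.balls], axis=0)
        return tuple(float(v) for v in c)

    @property
    def bounding_radius(self) -> float:
        c = np.asarray(self.center)
        return max(
            float(np.linalg.norm(np.asarray(b) - c)) + r for b, r in self.balls
        )

    def contains(self, x, y, z) -> np.ndarray:
        inside = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        for (cx, cy, cz), r in self.balls:
            inside |= (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        return inside

    def relative_activity(self, x, y, z, inside):
        return np.where(inside, self.activity_ratio, 0.0)


Lesion = SphereLesion | ShellLesion | IrregularLesion


@dataclass(frozen=True)
class CylinderBody:
    """Axial cylinder centred at the world origin."""

    diameter: float
    length: float

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("cylinder dimensions must be positive")

    def contains(self, x, y, z) -> np.ndarray:
        return (x**2 + y**2 <= (self.diameter / 2.0) ** 2) & (
            np.abs(z) <= self.length / 2.0
        )

    def contains_ball(self, center: Sequence[float], radius: float) -> bool:
        cx, cy, cz = center
        return (
            math.hypot(cx, cy) + radius <= self.diameter / 2.0
            and abs(cz) + radius <= self.length / 2.0
        )


def nema_iq_body() -> CylinderBody:
    """Cylindrical stand-in for the NEMA IQ torso shell (230 x 180 mm interior)."""
    return CylinderBody(diameter=230.0, length=180.0)


@dataclass
class PhantomSpec:
    """Declarative phantom description: body, background activity, lesions, grid."""

    body: CylinderBody
    background_activity: float  # kBq/ml
    lesions: list[Lesion]
    grid: GridSpec
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.background_activity < 0:
            raise ValueError("background activity must be non-negative")
        for i, les in enumerate(self.lesions):
            if not self.body.contains_ball(les.center, les.bounding_radius):
                raise ValueError(f"lesion {i} extends outside the phantom body")
        # conservative pairwise-disjointness check via bounding spheres
        for i in range(len(self.lesions)):
            for j in range(i + 1, len(self.lesions)):
                a, b = self.lesions[i], self.lesions[j]
                d = float(np.linalg.norm(np.subtract(a.center, b.center)))
                if d <= a.bounding_radius + b.bounding_radius:
                    raise ValueError(f"lesions {i} and {j} overlap (bounding spheres intersect)")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def les_dict(les: Lesion) -> dict:
            if isinstance(les, SphereLesion):
                return {"kind": "sphere", "center": list(les.center),
                        "diameter": les.diameter, "activity_ratio": les.activity_ratio}
            if isinstance(les, ShellLesion):
                return {"kind": "shell", "center": list(les.center),
                        "outer_diameter": les.outer_diameter,
                        "core_diameter": les.core_diameter,
                        "shell_activity_ratio": les.shell_activity_ratio,
                        "core_activity_ratio": les.core_activity_ratio}
            return {"kind": "irregular",
                    "balls": [[list(c), r] for c, r in les.balls],
                    "activity_ratio": les.activity_ratio}

        return {
            "name": self.name,
            "body": {"diameter": self.body.diameter, "length": self.body.length},
            "background_activity": self.background_activity,
            "grid": {"matrix": list(self.grid.matrix),
                     "voxel_size": list(self.grid.voxel_size)},
            "lesions": [les_dict(l) for l in self.lesions],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        lesions: list[Lesion] = []
        for ld in d["lesions"]:
            kind = ld["kind"]
            if kind == "sphere":
                lesions.append(SphereLesion(tuple(ld["center"]), ld["diameter"],
                                            ld["activity_ratio"]))
            elif kind == "shell":
                lesions.append(ShellLesion(tuple(ld["center"]), ld["outer_diameter"],
                                           ld["core_diameter"], ld["shell_activity_ratio"],
                                           ld.get("core_activity_ratio", 1.0)))
            elif kind == "irregular":
                balls = tuple((tuple(c), float(r)) for c, r in ld["balls"])
                lesions.append(IrregularLesion(balls, ld["activity_ratio"]))
            else:
                raise ValueError(f"unknown lesion kind {kind!r}")
        return cls(
            body=CylinderBody(**d["body"]),
            background_activity=d["background_activity"],
            lesions=lesions,
            grid=GridSpec(tuple(d["grid"]["matrix"]), tuple(d["grid"]["voxel_size"])),
            name=d.get("name", "phantom"),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(text))


# -- builders ---------------------------------------------------------------

def build_nema_iq_spec(contrast: float, grid: GridSpec | None = None) -> PhantomSpec:
    """NEMA IQ sphere set at the given sphere:background contrast.

    Six spheres (10-37 mm) co-planar on the central transaxial slice, centres
    on the standard 57.2 mm radius circle, background 5.2 kBq/ml.
    """
    if contrast <= 0:
        raise ValueError(f"contrast must be positive, got {contrast}")
    if grid is None:
        grid = standard_grid(200, nz=75)
    lesions = []
    for k, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        ang = math.radians(60.0 * k)
        c = (NEMA_RING_RADIUS_MM * math.cos(ang), NEMA_RING_RADIUS_MM * math.sin(ang), 0.0)
        lesions.append(SphereLesion(c, d, float(contrast)))
    return PhantomSpec(nema_iq_body(), NEMA_BACKGROUND_KBQ_ML, lesions, grid,
                       name=f"nema_c{contrast:g}")


def _irregular_lesions(rng: np.random.Generator, contrast: float) -> list[IrregularLesion]:
    """Six seeded irregular lesions at radial anchors, sizes spanning ~0.2-27 ml."""
    lesions = []
    # base radii log-spaced so the union volumes roughly span the sphere range
    base_radii = np.geomspace(4.0, 17.0, 6)
    for k in range(6):
        ang = 2.0 * math.pi * k / 6.0 + 0.3
        anchor = np.array([
            SYNTHETIC_RING_RADIUS_MM * math.cos(ang),
            SYNTHETIC_RING_RADIUS_MM * math.sin(ang),
            0.0,
        ])
        rb = float(base_radii[k])
        n_balls = int(rng.integers(3, 8))
        balls = []
        for _ in range(n_balls):
            offset = rng.uniform(-0.8 * rb, 0.8 * rb, size=3)
            radius = float(rng.uniform(0.5 * rb, rb))
            balls.append((tuple((anchor + offset).tolist()), radius))
        lesions.append(IrregularLesion(tuple(balls), float(contrast)))
    return lesions


def build_synthetic_spec(
    family: str,
    contrast: float = 8.0,
    grid: GridSpec | None = None,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Cylinder-body phantom (300 x 221 mm) for one of the three synthetic families.

    ``family`` is one of ``"spheres"`` (seven spheres 7-37 mm), ``"necrotic"``
    (seven 42 mm shells with cold cores 7-37 mm) or ``"irregular"`` (six
    seeded procedural shapes).  Lesion centres sit on a 114.4 mm radius ring
    around the central transaxial slice.
    """
    if contrast <= 0:
        raise ValueError(f"contrast must be positive, got {contrast}")
    if grid is None:
        grid = standard_grid(200, nz=55)
    body = CylinderBody(diameter=300.0, length=221.0)
    bg = NEMA_BACKGROUND_KBQ_ML
    lesions: list[Lesion]
    if family == "spheres":
        lesions = []
        for k, d in enumerate(SYNTHETIC_SPHERE_DIAMETERS_MM):
            ang = 2.0 * math.pi * k / 7.0
            c = (SYNTHETIC_RING_RADIUS_MM * math.cos(ang),
                 SYNTHETIC_RING_RADIUS_MM * math.sin(ang), 0.0)
            lesions.append(SphereLesion(c, d, float(contrast)))
    elif family == "necrotic":
        lesions = []
        for k, d in enumerate(SYNTHETIC_SPHERE_DIAMETERS_MM):
            ang = 2.0 * math.pi * k / 7.0
            c = (SYNTHETIC_RING_RADIUS_MM * math.cos(ang),
                 SYNTHETIC_RING_RADIUS_MM * math.sin(ang), 0.0)
            lesions.append(ShellLesion(c, outer_diameter=42.0, core_diameter=d,
                                       shell_activity_ratio=float(contrast),
                                       core_activity_ratio=1.0))
    elif family == "irregular":
        rng = np.random.default_rng(rng_seed)
        lesions = _irregular_lesions(rng, contrast)
    else:
        raise ValueError(f"unknown phantom family {family!r}")
    return PhantomSpec(body, bg, lesions, grid, name=f"{family}_c{contrast:g}")


# -- voxelization ------------------------------------------------------------

def _lesion_index_box(les: Lesion, vol_axes, shape) -> BoundingBox | None:
    """Index box covering the lesion's bounding sphere; None if fully outside."""
    cx, cy, cz = les.center
    r = les.bounding_radius
    lo, hi = [], []
    for k, (c, ax) in enumerate(zip((cx, cy, cz), vol_axes)):
        i0 = int(np.searchsorted(ax, c - r - 1e-9))
        i1 = int(np.searchsorted(ax, c + r + 1e-9))
        lo.append(i0)
        hi.append(i1)
    if any(h <= l for l, h in zip(lo, hi)):
        return None
    return BoundingBox(tuple(lo), tuple(hi))


def _mask_in_box(les, axes, box: BoundingBox, member_fn) -> np.ndarray:
    xs = axes[0][box.slices[0]][:, None, None]
    ys = axes[1][box.slices[1]][None, :, None]
    zs = axes[2][box.slices[2]][None, None, :]
    return member_fn(xs, ys, zs)


def voxelize(spec: PhantomSpec) -> tuple[VoxelVolume, list[BinaryMask]]:
    """Rasterise a phantom: activity map plus one ground-truth mask per lesion.

    The activity map holds ``background_activity`` inside the body, lesion
    activity (= ratio x background) inside each lesion's hot support, and zero
    outside the body.  Each returned mask is the lesion's hot support
    (for shell lesions that is the shell; see :func:`core_mask` for the core).

    Raises if any lesion's analytic extent leaves the grid.
    """
    grid = spec.grid
    origin = grid.centered_origin()
    axes = tuple(origin[k] + np.arange(grid.matrix[k]) * grid.voxel_size[k] for k in range(3))

    # grid world extents (voxel centres)
    for i, les in enumerate(spec.lesions):
        for k in range(3):
            c, r = les.center[k], les.bounding_radius
            if c - r < axes[k][0] - grid.voxel_size[k] / 2 or c + r > axes[k][-1] + grid.voxel_size[k] / 2:
                raise ValueError(
                    f"lesion {i} of phantom {spec.name!r} extends outside the grid on axis {k}"
                )

    xs = axes[0][:, None, None]
    ys = axes[1][None, :, None]
    zs = axes[2][None, None, :]
    body = spec.body.contains(xs, ys, zs)
    values = np.where(body, spec.background_activity, 0.0)

    masks: list[BinaryMask] = []
    for les in spec.lesions:
        box = _lesion_index_box(les, axes, grid.matrix)
        m = np.zeros(grid.matrix, dtype=bool)
        if box is not None:
            sub_inside = _mask_in_box(les, axes, box, les.contains)
            m[box.slices] = sub_inside
            # write activity inside the lesion's full analytic support
            xsb = axes[0][box.slices[0]][:, None, None]
            ysb = axes[1][box.slices[1]][None, :, None]
            zsb = axes[2][box.slices[2]][None, None, :]
            rel = les.relative_activity(xsb, ysb, zsb, sub_inside)
            sub = values[box.slices]
            values[box.slices] = np.where(rel > 0, rel * spec.background_activity, sub)
        masks.append(BinaryMask(m, grid, origin))
    return VoxelVolume(values, grid, origin), masks


def core_mask(les: ShellLesion, grid: GridSpec, origin: np.ndarray | None = None) -> BinaryMask:
    """Voxelized cold-core mask of a shell lesion (same centre-inclusion rule)."""
    if origin is None:
        origin = grid.centered_origin()
    axes = tuple(origin[k] + np.arange(grid.matrix[k]) * grid.voxel_size[k] for k in range(3))
    xs = axes[0][:, None, None]
    ys = axes[1][None, :, None]
    zs = axes[2][None, None, :]
    return BinaryMask(les.core_contains(xs, ys, zs), grid, np.asarray(origin, float))


def voxelize_sphere(center: Sequence[float], diameter: float, grid: GridSpec,
                    origin: np.ndarray | None = None) -> BinaryMask:
    """Voxelize a single analytic sphere (centre-inclusion rule)."""
    if origin is None:
        origin = grid.centered_origin()
    axes = tuple(origin[k] + np.arange(grid.matrix[k]) * grid.voxel_size[k] for k in range(3))
    cx, cy, cz = (float(c) for c in center)
    xs = axes[0][:, None, None]
    ys = axes[1][None, :, None]
    zs = axes[2][None, None, :]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= (diameter / 2.0) ** 2
    return BinaryMask(inside, grid, np.asarray(origin, float))


def fit_sphere_ground_truth(image: VoxelVolume, voi: BoundingBox,
                            true_diameter: float) -> BinaryMask:
    """Fit a sphere of known diameter to a single hot object inside a VOI.

    The sphere centre is the intensity-weighted centroid of the above-mean
    voxels in the VOI; the returned mask is that sphere voxelized on the
    image grid.  Used to recreate ground truth on data where the analytic
    mask is unavailable (e.g. external scanner images).
    """
    sub = image.values[voi.slices]
    if sub.size == 0:
        raise ValueError("VOI is empty")
    if np.ptp(sub) <= 0:
        raise ValueError("VOI intensity is flat; no object to fit")
    thr = float(sub.mean())
    sel = sub > thr
    if not sel.any():
        raise ValueError("no above-mean voxels in VOI")
    idx = np.argwhere(sel).astype(float) + np.asarray(voi.lo, dtype=float)
    w = sub[sel]
    centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    center = image.origin + centroid_idx * np.asarray(image.grid.voxel_size)
    return voxelize_sphere(center, true_diameter, image.grid, image.origin)
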