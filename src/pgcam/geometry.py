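"""Scene description and ray/volume utilities.

The default scene is a 100x100x200 mm^3 water phantom with the proton beam
along its long axis (+Y of a right-handed lab frame, origin at the phantom
center) surrounded by four two-plane detector modules, one facing each
lateral surface at a 50 mm air gap.  Each module consists of a monolithic
50x50x15 mm^3 scatter (S) crystal and a 2x2 array of 50x50x25 mm^3 absorber
(A) crystals separated by an adjustable focal distance F_d (default 15 mm).

Depth along the beam is reported as Y + 100 mm so that the phantom entrance
face is at depth 0 and its center at depth 100 mm.

Module poses are axis-aligned: a module is described by its outward normal
(a signed lab axis), which fixes the orientation of both detection planes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrystalBox",
    "DetectorModule",
    "Scene",
    "build_scene",
    "build_default_scene",
    "build_single_module_scene",
    "ray_path_in_box",
]

SCATTER_HALF = np.array([25.0, 25.0, 7.5])  # half-extents along (u, v, normal)
ABSORBER_HALF = np.array([25.0, 25.0, 12.5])
DEFAULT_FOCAL_DISTANCE = 15.0
DEFAULT_PHANTOM_HALF = np.array([50.0, 100.0, 50.0])  # beam along +Y
DEFAULT_STANDOFF = 50.0  # air gap between phantom surface and S front face

_AXIS_VECTORS = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "+z": np.array([0.0, 0.0, 1.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class CrystalBox:
    """Axis-aligned crystal volume in the lab frame."""

    center: np.ndarray
    half_extents: np.ndarray
    role: str  # "scatter" | "absorber"
    module_id: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "half_extents", np.asarray(self.half_extents, float))
        if np.any(self.half_extents <= 0):
            raise ValueError("half-extents must be positive")
        if self.role not in ("scatter", "absorber"):
            raise ValueError(f"unknown crystal role {self.role!r}")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.half_extents

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.half_extents

    def contains(self, points) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)


@dataclass(frozen=True)
class DetectorModule:
    """One two-plane module: S crystal plus 2x2 absorber array.

    ``normal`` is the outward-pointing lab axis label (e.g. "+x" for a
    module on the +x side of the scene, facing toward -x); ``front_distance``
    is the distance from the lab origin (beam axis) to the S front face.
    """

    module_id: int
    normal: str
    front_distance: float
    focal_distance: float = DEFAULT_FOCAL_DISTANCE
    center_v: float = 0.0  # offset of the module center along the beam axis

    def __post_init__(self):
        if self.normal not in _AXIS_VECTORS:
            raise ValueError(f"normal must be one of {sorted(_AXIS_VECTORS)}")
        if self.focal_distance <= 0:
            raise ValueError("focal distance must be positive")

    @property
    def normal_vec(self) -> np.ndarray:
        return _AXIS_VECTORS[self.normal]

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Module frame (e_u, e_v, e_n): e_n outward normal, e_v the beam
        axis (+Y) unless the module faces along Y, e_u completes the
        right-handed triad."""
        e_n = self.normal_vec
        e_v = np.array([0.0, 1.0, 0.0])
        if abs(float(e_n @ e_v)) > 0.9:
            e_v = np.array([0.0, 0.0, 1.0])
        e_u = np.cross(e_v, e_n)
        return e_u, e_v, e_n

    def _plane_center(self, along_normal: float) -> np.ndarray:
        e_u, e_v, e_n = self.basis
        return e_n * along_normal + e_v * self.center_v

    @property
    def scatter(self) -> CrystalBox:
        c = self._plane_center(self.front_distance + SCATTER_HALF[2])
        e_u, e_v, e_n = self.basis
        half = np.abs(SCATTER_HALF[0] * e_u) + np.abs(SCATTER_HALF[1] * e_v) + np.abs(SCATTER_HALF[2] * e_n)
        return CrystalBox(c, half, "scatter", self.module_id)

    @property
    def absorbers(self) -> list[CrystalBox]:
        e_u, e_v, e_n = self.basis
        d = self.front_distance + 2 * SCATTER_HALF[2] + self.focal_distance + ABSORBER_HALF[2]
        half = np.abs(ABSORBER_HALF[0] * e_u) + np.abs(ABSORBER_HALF[1] * e_v) + np.abs(ABSORBER_HALF[2] * e_n)
        out = []
        for du in (-25.0, 25.0):
            for dv in (-25.0, 25.0):
                c = self._plane_center(d) + du * e_u + dv * e_v
                out.append(CrystalBox(c, half, "absorber", self.module_id))
        return out

    @property
    def crystals(self) -> list[CrystalBox]:
        return [self.scatter] + self.absorbers

    @property
    def center(self) -> np.ndarray:
        """Geometric center of the module bounding volume."""
        los = np.array([c.lo for c in self.crystals])
        his = np.array([c.hi for c in self.crystals])
        return 0.5 * (los.min(axis=0) + his.max(axis=0))

    @property
    def bounding_radius(self) -> float:
        ctr = self.center
        r = 0.0
        for c in self.crystals:
            corners = ctr - c.center
            r = max(r, float(np.linalg.norm(np.abs(corners) + c.half_extents)))
        return r

    def to_local(self, points) -> np.ndarray:
        """Lab -> module-local coordinates (origin at the S front-face
        center, axes (u, v, depth-into-module); depth grows from the S
        front face toward the absorber plane)."""
        e_u, e_v, e_n = self.basis
        origin = self._plane_center(self.front_distance)
        p = np.atleast_2d(np.asarray(points, float)) - origin
        return np.stack([p @ e_u, p @ e_v, p @ e_n], axis=-1)


@dataclass
class Scene:
    """Phantom plus detector modules (phantom optional for point-source
    and classifier-training setups)."""

    modules: list[DetectorModule]
    phantom_half_extents: np.ndarray | None = None
    phantom_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phantom_material: str = "water"
    detector_material: str = "lacl3"

    def __post_init__(self):
        self.phantom_center = np.asarray(self.phantom_center, float)
        if self.phantom_half_extents is not None:
            self.phantom_half_extents = np.asarray(self.phantom_half_extents, float)
        self._check_overlaps()

    def _check_overlaps(self):
        boxes = [(c.lo, c.hi) for c in self.crystals]
        if self.phantom_half_extents is not None:
            boxes.append(
                (
                    self.phantom_center - self.phantom_half_extents,
                    self.phantom_center + self.phantom_half_extents,
                )
            )
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                lo = np.maximum(boxes[i][0], boxes[j][0])
                hi = np.minimum(boxes[i][1], boxes[j][1])
                if np.all(hi - lo > 1e-9):
                    raise ValueError(f"overlapping volumes in scene (boxes {i} and {j})")

    @property
    def crystals(self) -> list[CrystalBox]:
        out = []
        for m in self.modules:
            out.extend(m.crystals)
        return out

    @property
    def has_phantom(self) -> bool:
        return self.phantom_half_extents is not None

    def module(self, module_id: int) -> DetectorModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    # -- config serialization -------------------------------------------
    def to_config(self) -> dict:
        cfg: dict = {
            "phantom": None
            if self.phantom_half_extents is None
            else {
                "half_extents": self.phantom_half_extents.tolist(),
                "center": self.phantom_center.tolist(),
                "material": self.phantom_material,
            },
            "detector_material": self.detector_material,
            "modules": [
                {
                    "module_id": m.module_id,
                    "normal": m.normal,
                    "front_distance": m.front_distance,
                    "focal_distance": m.focal_distance,
                    "center_v": m.center_v,
                }
                for m in self.modules
            ],
        }
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "Scene":
        ph = cfg.get("phantom")
        modules = [DetectorModule(**m) for m in cfg["modules"]]
        return cls(
            modules=modules,
            phantom_half_extents=None if ph is None else np.asarray(ph["half_extents"], float),
            phantom_center=np.zeros(3) if ph is None else np.asarray(ph.get("center", [0, 0, 0]), float),
            phantom_material="water" if ph is None else ph.get("material", "water"),
            detector_material=cfg.get("detector_material", "lacl3"),
        )

    def scene_hash(self) -> str:
        payload = json.dumps(self.to_config(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_default_scene(
    focal_distance: float = DEFAULT_FOCAL_DISTANCE,
    n_modules: int = 4,
    standoff: float = DEFAULT_STANDOFF,
    phantom: bool = True,
) -> Scene:
    """Four modules facing the four beam-parallel lateral phantom faces.

    Each S front face sits ``standoff`` mm from the lateral phantom surface,
    i.e. standoff + 50 mm from the beam axis with the default phantom.
    """
    if not 1 <= n_modules <= 4:
        raise ValueError("n_modules must be between 1 and 4")
    half = DEFAULT_PHANTOM_HALF
    front = standoff + half[0]
    normals = ["+x", "-x", "+z", "-z"][:n_modules]
    modules = [
        DetectorModule(i, n, front_distance=front, focal_distance=focal_distance)
        for i, n in enumerate(normals)
    ]
    return Scene(modules=modules, phantom_half_extents=half if phantom else None)


def build_single_module_scene(
    source_distance: float = 50.0, focal_distance: float = DEFAULT_FOCAL_DISTANCE
) -> Scene:
    """One module with its S front face ``source_distance`` mm from the lab
    origin (where a point source is placed); no phantom."""
    m = DetectorModule(0, "+x", front_distance=source_distance, focal_distance=focal_distance)
    return Scene(modules=[m], phantom_half_extents=None)


def build_scene(config: dict) -> Scene:
    """Build a scene from a configuration mapping.

    Recognised layouts: ``{"preset": "default", "focal_distance": ..,
    "n_modules": .., "phantom": bool}``, ``{"preset": "single_module",
    "source_distance": .., "focal_distance": ..}``, or an explicit module
    list as produced by :meth:`Scene.to_config`.
    """
    cfg = dict(config or {})
    preset = cfg.pop("preset", None)
    if preset == "default" or (preset is None and "modules" not in cfg):
        return build_default_scene(
            focal_distance=cfg.get("focal_distance", DEFAULT_FOCAL_DISTANCE),
            n_modules=cfg.get("n_modules", 4),
            standoff=cfg.get("standoff", DEFAULT_STANDOFF),
            phantom=cfg.get("phantom", True),
        )
    if preset == "single_module":
        return build_single_module_scene(
            source_distance=cfg.get("source_distance", 50.0),
            focal_distance=cfg.get("focal_distance", DEFAULT_FOCAL_DISTANCE),
        )
    return Scene.from_config(cfg)


def ray_path_in_box(origin, direction, box) -> tuple[float, float] | None:
    """Slab-method ray/AABB intersection.

    Returns (t_entry, t_exit) distances (mm, both >= 0; t_entry clipped at
    the origin when it lies inside) or None when the forward ray misses.
    ``box`` may be a CrystalBox or an (lo, hi) pair.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    n = float(np.linalg.norm(d))
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("direction must have nonzero norm")
    if abs(n - 1.0) > 1e-9:
        d = d / n
    if isinstance(box, CrystalBox):
        lo, hi = box.lo, box.hi
    else:
        lo, hi = (np.asarray(b, float) for b in box)
    t0, t1 = -np.inf, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-15:
            if o[k] < lo[k] or o[k] > hi[k]:
                return None
            continue
        ta = (lo[k] - o[k]) / d[k]
        tb = (hi[k] - o[k]) / d[k]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
    if t1 <= max(t0, 0.0):
        return None
    return max(t0, 0.0), t1
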