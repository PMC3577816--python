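"""Synthetic tabletop world viewed through a virtual pan/tilt camera.

The scene is a set of coloured balls ("world objects") living on the unit
direction sphere: a 2-DOF camera head only ever measures directions, so an
object is fully described by its (azimuth, elevation) direction, an angular
radius and an optional angular velocity.  The camera is an analytic pinhole
with a configurable focal length in pixels; it renders RGB frames with a
high-resolution foveal window at the image centre.

Coordinate conventions (fixed here, used by every other module):

* World directions are ``(azimuth, elevation)`` in radians.  Azimuth
  increases towards the camera's left, elevation upward.
* A camera pose is the absolute ``(verge, tilt)`` motor position of the
  single active camera.  Positive verge rotates the optical axis towards
  positive azimuth, positive tilt towards positive elevation.
* Image x grows rightward, y downward; pixel ``(i, j)`` covers the unit
  square ``[j, j+1) x [i, i+1)`` with its centre at ``(j+0.5, i+0.5)``.
* Projection: an object at direction ``(az, el)`` seen from pose
  ``(v, t)`` has its disc centre at::

      x = cx - f * tan(az - v)
      y = cy - f * tan(el - t)

  which is the exact inverse of the motor delta computed in
  :mod:`gazesim.oculomotor` — the round trip "project, saccade, re-project"
  lands the object on the image centre.

Rendering is deliberately aliasing-free in the set-theoretic sense: a pixel
takes the disc colour iff its centre lies inside the projected disc (a
circle of radius ``f * tan(angular_radius)`` in image space).  This keeps
frames bit-reproducible and every geometric test exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "COLOURS",
    "CameraIntrinsics",
    "CameraPose",
    "RetinalImage",
    "WorldObject",
    "angular_distance",
    "load_scene_spec",
    "make_scene",
    "render",
    "save_png",
    "step_scene",
]

#: Named colour classes recognised by scene specifications.
COLOURS: dict[str, tuple[float, float, float]] = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class WorldObject:
    """A coloured ball on the direction sphere."""

    id: str
    colour: tuple[float, float, float]
    direction: tuple[float, float]  # (azimuth, elevation), radians
    angular_radius: float  # radians
    angular_velocity: tuple[float, float] = (0.0, 0.0)  # rad/s

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.colour):
            raise ValueError(f"colour channels must lie in [0, 1]: {self.colour}")
        if not self.angular_radius > 0.0:
            raise ValueError("angular_radius must be positive")
        if not all(math.isfinite(v) for v in (*self.direction, *self.angular_velocity)):
            raise ValueError("direction and angular_velocity must be finite")


@dataclass(frozen=True)
class CameraPose:
    """Absolute (verge, tilt) motor position of the camera, in radians."""

    verge: float
    tilt: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.verge) and math.isfinite(self.tilt)):
            raise ValueError("camera pose must be finite")


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera geometry, foveal window and motor limits.

    The default 320x240 frame is a scaled-down stand-in for a native
    machine-vision sensor; the architecture is resolution agnostic.  The
    fovea is a centred square, by default one eighth of the image width.
    """

    width: int = 320
    height: int = 240
    focal_px: float = 240.0
    fovea_side: int = 40
    verge_limit: float = 1.0
    tilt_limit: float = 1.0
    background: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.focal_px <= 0:
            raise ValueError("image dimensions and focal length must be positive")
        if not 0 < self.fovea_side <= min(self.width, self.height):
            raise ValueError("fovea window must fit strictly inside the image")

    @property
    def cx(self) -> float:
        return self.width / 2.0

    @property
    def cy(self) -> float:
        return self.height / 2.0


@dataclass
class RetinalImage:
    """An RGB frame with a designated centred foveal window."""

    pixels: np.ndarray  # (H, W, 3) floats in [0, 1]
    fovea_side: int
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.pixels.shape[:2]
        if not 0 < self.fovea_side <= min(h, w):
            raise ValueError("fovea window must fit strictly inside the pixel grid")

    @property
    def fovea(self) -> np.ndarray:
        """View of the centred foveal square (full resolution)."""
        h, w = self.pixels.shape[:2]
        top = (h - self.fovea_side) // 2
        left = (w - self.fovea_side) // 2
        return self.pixels[top : top + self.fovea_side, left : left + self.fovea_side]


def angular_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two (azimuth, elevation) directions.

    The small-angle flat approximation is adequate for a desk-scale field
    of view (well under a radian) and keeps every geometric test exact.
    """
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _resolve_colour(value) -> tuple[float, float, float]:
    if isinstance(value, str):
        try:
            return COLOURS[value.lower()]
        except KeyError:
            raise ValueError(
                f"unknown colour name {value!r}; known names: {sorted(COLOURS)}"
            ) from None
    rgb = tuple(float(c) for c in value)
    if len(rgb) != 3:
        raise ValueError(f"colour must be a name or an RGB triple, got {value!r}")
    return rgb


def _check_overlaps(objects: Sequence[WorldObject]) -> None:
    for i, a in enumerate(objects):
        for b in objects[i + 1 :]:
            sep = angular_distance(a.direction, b.direction)
            if sep < a.angular_radius + b.angular_radius:
                raise ValueError(
                    f"objects {a.id!r} and {b.id!r} overlap: separation "
                    f"{sep:.4f} rad < sum of radii "
                    f"{a.angular_radius + b.angular_radius:.4f} rad"
                )


def make_scene(spec: Mapping | Sequence | int | None) -> list[WorldObject]:
    """Build a list of world objects from a scene specification.

    Two forms are accepted:

    * an explicit object list — ``{"objects": [{"colour": "red",
      "azimuth": 0.1, "elevation": -0.05, "radius": 0.09,
      "velocity": [0, 0]}, ...]}`` (a bare list works too);
    * a generated layout — ``{"counts": {"red": 2, "blue": 2},
      "layout": "arc", "radius": [0.027, 0.042], "elevation": -0.05,
      "span": 0.525, "jitter": 0.012, "seed": 0}`` placing the balls on a
      horizontal arc with seeded positional jitter.  ``radius`` may be a
      single angular radius or a ``[low, high]`` range sampled per ball
      (balls of varying apparent size, as on a real table); likewise
      ``saturation`` (default 1.0) mixes each ball's colour towards the
      mid-grey background, emulating the varying colour saturation of
      real objects under real lighting.

    The result is deterministic for a fixed spec (including its seed), and
    overlapping angular footprints are rejected with a diagnostic.
    """
    if spec is None:
        spec = {}
    if isinstance(spec, int):
        spec = {"counts": {"red": 2, "blue": 2}, "seed": spec}
    if isinstance(spec, Sequence) and not isinstance(spec, (str, bytes)):
        spec = {"objects": list(spec)}

    if "objects" in spec:
        objects = []
        for k, obj in enumerate(spec["objects"]):
            objects.append(
                WorldObject(
                    id=str(obj.get("id", f"obj{k}")),
                    colour=_resolve_colour(obj.get("colour", "red")),
                    direction=(
                        float(obj.get("azimuth", 0.0)),
                        float(obj.get("elevation", 0.0)),
                    ),
                    angular_radius=float(obj.get("radius", 0.09)),
                    angular_velocity=tuple(obj.get("velocity", (0.0, 0.0))),
                )
            )
        _check_overlaps(objects)
        return objects

    counts: Mapping[str, int] = spec.get("counts", {})
    n = int(sum(counts.values()))
    if n == 0:
        return []
    layout = spec.get("layout", "arc")
    if layout != "arc":
        raise ValueError(f"unknown layout {layout!r}")
    radius = spec.get("radius", 0.04)
    elevation = float(spec.get("elevation", -0.05))
    span = float(spec.get("span", 0.57))
    jitter = float(spec.get("jitter", 0.012))
    rng = np.random.default_rng(spec.get("seed", 0))

    # Alternate colour classes along the arc so that class and position are
    # not confounded; the seed perturbs positions only.
    palette: list[str] = []
    pool = {name: int(cnt) for name, cnt in counts.items() if cnt > 0}
    order = sorted(pool)
    while pool:
        for name in list(order):
            if pool.get(name, 0) > 0:
                palette.append(name)
                pool[name] -= 1
                if pool[name] == 0:
                    del pool[name]

    if n == 1:
        azimuths = np.array([0.0])
    else:
        azimuths = np.linspace(-span / 2.0, span / 2.0, n)
    saturation = spec.get("saturation", 1.0)
    objects = []
    for k, name in enumerate(palette):
        daz, del_ = rng.uniform(-jitter, jitter, size=2)
        if isinstance(radius, (list, tuple)):
            r = float(rng.uniform(radius[0], radius[1]))
        else:
            r = float(radius)
        if isinstance(saturation, (list, tuple)):
            sat = float(rng.uniform(saturation[0], saturation[1]))
        else:
            sat = float(saturation)
        pure = np.asarray(_resolve_colour(name))
        colour = tuple(sat * pure + (1.0 - sat) * 0.5)
        objects.append(
            WorldObject(
                id=f"{name}{k}",
                colour=colour,
                direction=(float(azimuths[k] + daz), float(elevation + del_)),
                angular_radius=r,
            )
        )
    _check_overlaps(objects)
    return objects


def load_scene_spec(path: str | Path) -> Mapping:
    """Read a scene specification from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _pixel_grids(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    key = (height, width)
    if key not in _GRID_CACHE:
        ys = np.arange(height, dtype=float) + 0.5
        xs = np.arange(width, dtype=float) + 0.5
        _GRID_CACHE[key] = tuple(np.meshgrid(ys, xs, indexing="ij"))  # type: ignore[assignment]
    return _GRID_CACHE[key]


def render(
    pose: CameraPose,
    scene: Iterable[WorldObject],
    time: float = 0.0,
    intrinsics: CameraIntrinsics = CameraIntrinsics(),
) -> RetinalImage:
    """Render the scene from a camera pose as a retinal image.

    Objects are drawn in list order (painter's order) as filled discs of
    their colour on the configured background.  Rendering is a pure
    function of ``(pose, scene, time)``.
    """
    if abs(pose.verge) > intrinsics.verge_limit or abs(pose.tilt) > intrinsics.tilt_limit:
        raise ValueError(
            f"pose {pose} outside motor limits "
            f"(±{intrinsics.verge_limit}, ±{intrinsics.tilt_limit})"
        )
    h, w = intrinsics.height, intrinsics.width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = intrinsics.background
    yy, xx = _pixel_grids(h, w)
    for obj in scene:
        daz = obj.direction[0] - pose.verge
        del_ = obj.direction[1] - pose.tilt
        # behind or far outside the frustum: tan is meaningless past +-pi/2
        if abs(daz) >= 1.4 or abs(del_) >= 1.4:
            continue
        x0 = intrinsics.cx - intrinsics.focal_px * math.tan(daz)
        y0 = intrinsics.cy - intrinsics.focal_px * math.tan(del_)
        r_px = intrinsics.focal_px * math.tan(obj.angular_radius)
        if x0 + r_px < 0 or x0 - r_px > w or y0 + r_px < 0 or y0 - r_px > h:
            continue
        mask = (xx - x0) ** 2 + (yy - y0) ** 2 < r_px**2
        img[mask] = obj.colour
    return RetinalImage(pixels=img, fovea_side=intrinsics.fovea_side, timestamp=time)


def step_scene(scene: Sequence[WorldObject], dt: float) -> list[WorldObject]:
    """Advance object motion by ``dt`` seconds (pure; ``dt = 0`` is identity)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return [
        replace(
            obj,
            direction=(
                obj.direction[0] + obj.angular_velocity[0] * dt,
                obj.direction[1] + obj.angular_velocity[1] * dt,
            ),
        )
        for obj in scene
    ]


def save_png(image: RetinalImage | np.ndarray, path: str | Path) -> None:
    """Write a frame (or any [0,1] float array) as an 8-bit PNG."""
    import imageio.v3 as iio

    pixels = image.pixels if isinstance(image, RetinalImage) else np.asarray(image)
    iio.imwrite(str(path), (np.clip(pixels, 0.0, 1.0) * 255).astype(np.uint8))
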