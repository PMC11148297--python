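"""Nested clutter environments for the homing task.

Six conditions with 0, 1, 2, 3, 10, or 99 identical, rotationally symmetric
tree objects.  The first three objects form a triangular arrangement exactly
10 vm from the goal so that the goal can be triangulated; conditions with
more objects always contain the objects of every lower condition as a prefix
(the constellation is constant within a condition for a fixed seed).  No
object may fall within an exclusion corridor around the outbound legs or the
direct return segment, so the walked path stays free of obstacles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .geometry import Course, Point2D, standard_course

__all__ = [
    "CONDITIONS",
    "LANDMARK_RADIUS",
    "DEFAULT_LANDMARK_ANGLES_DEG",
    "Environment",
    "PlacementError",
    "Violation",
    "build_environment",
    "validate_environment",
    "save_environment",
    "load_environment",
]

#: Allowed object counts, in ascending order.
CONDITIONS = (0, 1, 2, 3, 10, 99)

#: Distance of the three goal-surrounding objects from the goal, vm.
LANDMARK_RADIUS = 10.0

#: Polar angles (degrees, from the goal) of the three goal-surrounding
#: objects; one sits behind the approach axis.  Only the 10 vm radius and the
#: triangular arrangement are dictated by the task; the angles are a
#: configurable default.
DEFAULT_LANDMARK_ANGLES_DEG = (90.0, 210.0, 330.0)

DEFAULT_CORRIDOR_HALFWIDTH = 2.5
DEFAULT_FIELD_RADIUS = 60.0
DEFAULT_MIN_SPACING = 3.0
_MAX_OBJECTS = max(CONDITIONS)


class PlacementError(RuntimeError):
    """Raised when procedural object placement cannot satisfy constraints."""


class Violation(NamedTuple):
    rule: str
    object_index: int
    detail: str


@dataclass(frozen=True)
class Environment:
    """One clutter condition: object coordinates plus the course geometry."""

    condition: int
    objects: tuple[Point2D, ...]
    goal: Point2D
    waypoints: tuple[Point2D, Point2D]
    seed: int
    corridor_halfwidth: float = DEFAULT_CORRIDOR_HALFWIDTH

    def object_array(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 2))
        return np.asarray(self.objects, dtype=float)


def _segment_distances(points: np.ndarray, a: Point2D, b: Point2D) -> np.ndarray:
    """Distance of each point to the segment ``a``-``b``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(*(pts - a).T)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(pts - proj).T)


def _corridor_distances(points: np.ndarray, course: Course) -> np.ndarray:
    """Min distance of each point to the outbound polyline + return segment."""
    dists = [_segment_distances(points, a, b) for a, b in course.segments()]
    return np.min(np.vstack(dists), axis=0)


def build_environment(condition: int,
                      seed: int,
                      corridor_halfwidth: float = DEFAULT_CORRIDOR_HALFWIDTH,
                      course: Course | None = None,
                      landmark_angles_deg: Sequence[float] = DEFAULT_LANDMARK_ANGLES_DEG,
                      field_radius: float = DEFAULT_FIELD_RADIUS,
                      min_spacing: float = DEFAULT_MIN_SPACING,
                      max_tries: int = 20000) -> Environment:
    """Build one environment condition, deterministically for a fixed seed.

    The full 99-object constellation is generated once per seed and lower
    conditions take a prefix of it, which guarantees the nesting invariant by
    construction.  The first three objects sit exactly 10 vm from the goal at
    the configured angles; the remainder are rejection-sampled uniformly in a
    disc of radius ``field_radius`` around the course centroid, keeping at
    least ``min_spacing`` vm between objects and ``corridor_halfwidth`` vm of
    clearance around the outbound and direct-return paths.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unsupported condition {condition!r}; expected one of {CONDITIONS}")
    course = course or standard_course()
    goal = course.goal

    fixed = [
        Point2D(goal.x + LANDMARK_RADIUS * math.cos(math.radians(a)),
                goal.y + LANDMARK_RADIUS * math.sin(math.radians(a)))
        for a in landmark_angles_deg[:3]
    ]
    clearance = _corridor_distances(np.asarray(fixed), course)
    if np.any(clearance < corridor_halfwidth):
        bad = int(np.argmin(clearance))
        raise PlacementError(
            f"goal-surrounding object {bad} at angle {landmark_angles_deg[bad]} deg "
            f"lies {clearance[bad]:.2f} vm from the walked path "
            f"(corridor half-width {corridor_halfwidth} vm)")

    rng = np.random.default_rng(seed)
    centroid = np.mean(np.asarray([course.goal, *course.waypoints], dtype=float), axis=0)
    placed: list[Point2D] = list(fixed)
    tries = 0
    while len(placed) < _MAX_OBJECTS:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place object {len(placed)} after {max_tries} tries")
        tries += 1
        r = field_radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cand = Point2D(float(centroid[0] + r * math.cos(theta)),
                       float(centroid[1] + r * math.sin(theta)))
        cand_arr = np.asarray([cand])
        if _corridor_distances(cand_arr, course)[0] < corridor_halfwidth:
            continue
        if placed:
            d = np.hypot(*(np.asarray(placed) - cand_arr).T)
            if float(d.min()) < min_spacing:
                continue
        placed.append(cand)

    return Environment(condition=condition,
                       objects=tuple(placed[:condition]),
                       goal=goal,
                       waypoints=course.waypoints,
                       seed=seed,
                       corridor_halfwidth=corridor_halfwidth)


def validate_environment(env: Environment,
                         course: Course | None = None,
                         min_spacing: float | None = None) -> list[Violation]:
    """Check all environment invariants; returns an empty list iff valid.

    Rules checked: object count matches the condition, the first (up to)
    three objects lie exactly 10 vm from the goal, and every object clears
    the exclusion corridor.  Inter-object spacing is checked only when
    ``min_spacing`` is given (the spacing default applies to procedurally
    placed objects, not to externally supplied layouts).
    """
    violations: list[Violation] = []
    if env.condition not in CONDITIONS:
        violations.append(Violation("condition", -1, f"unsupported condition {env.condition}"))
    if len(env.objects) != env.condition:
        violations.append(Violation(
            "object-count", -1,
            f"{len(env.objects)} objects for condition {env.condition}"))
    objs = env.object_array()
    if objs.size == 0:
        return violations

    radii = np.hypot(objs[:, 0] - env.goal.x, objs[:, 1] - env.goal.y)
    for i in range(min(3, len(env.objects))):
        if abs(radii[i] - LANDMARK_RADIUS) > 1e-9:
            violations.append(Violation(
                "landmark-radius", i,
                f"distance to goal {radii[i]:.6f} vm != {LANDMARK_RADIUS}"))

    if course is None:
        course = standard_course()
        course = Course(goal=env.goal, waypoints=env.waypoints,
                        release_heading=course.release_heading,
                        leg1=course.leg1, leg2=course.leg2,
                        inner_angle_deg=course.inner_angle_deg)
    clearance = _corridor_distances(objs, course)
    for i in np.flatnonzero(clearance < env.corridor_halfwidth):
        violations.append(Violation(
            "corridor", int(i),
            f"object {clearance[i]:.3f} vm from walked path "
            f"(half-width {env.corridor_halfwidth} vm)"))

    if min_spacing is not None and len(env.objects) > 1:
        diff = objs[:, None, :] - objs[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(d, np.inf)
        for i in np.flatnonzero(d.min(axis=1) < min_spacing):
            violations.append(Violation(
                "spacing", int(i),
                f"nearest neighbour {d[i].min():.3f} vm < {min_spacing} vm"))
    return violations


def save_environment(env: Environment, path: str | Path) -> None:
    """Write an environment to a flat text file: a commented config block
    followed by one ``index,x,y`` row per object."""
    path = Path(path)
    lines = [
        f"# condition: {env.condition}",
        f"# seed: {env.seed}",
        f"# corridor_halfwidth: {env.corridor_halfwidth!r}",
        f"# goal: {env.goal.x!r},{env.goal.y!r}",
        f"# waypoint1: {env.waypoints[0].x!r},{env.waypoints[0].y!r}",
        f"# waypoint2: {env.waypoints[1].x!r},{env.waypoints[1].y!r}",
        "index,x,y",
    ]
    for i, obj in enumerate(env.objects):
        lines.append(f"{i},{float(obj.x)!r},{float(obj.y)!r}")
    path.write_text("\n".join(lines) + "\n")


def load_environment(path: str | Path) -> Environment:
    """Inverse of :func:`save_environment`."""
    meta: dict[str, str] = {}
    objects: list[Point2D] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif not line.startswith("index"):
            _, x, y = line.split(",")
            objects.append(Point2D(float(x), float(y)))

    def _point(key: str) -> Point2D:
        x, y = meta[key].split(",")
        return Point2D(float(x), float(y))

    return Environment(condition=int(meta["condition"]),
                       objects=tuple(objects),
                       goal=_point("goal"),
                       waypoints=(_point("waypoint1"), _point("waypoint2")),
                       seed=int(meta["seed"]),
                       corridor_halfwidth=float(meta["corridor_halfwidth"]))
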