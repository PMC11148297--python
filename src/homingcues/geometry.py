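"""Planar geometry of the triangle-completion course.

Conventions
-----------
* The goal (campfire) sits at the origin ``(0, 0)``; distances are in virtual
  metres (vm), which correspond to real metres in the VR environment.
* Angles are radians internally and degrees at reporting boundaries.
* Directional estimates are signed angles relative to a stated reference
  heading, positive counter-clockwise, wrapped to ``[-pi, pi]``.
* The standard outbound course leaves the goal along two legs of 35.4 vm and
  25 vm with a 45 degree inner angle; the participant is released at the end
  of the second leg and must turn back towards the goal.  With the default
  frame (first leg towards -x, counter-clockwise triangle) the ideal homing
  turn is approximately +90 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Point2D",
    "HomeVector",
    "PolarEstimate",
    "Course",
    "wrap_angle",
    "ideal_home_vector",
    "to_polar",
    "from_polar",
    "polar_decompose",
    "polar_compose",
    "position_error",
    "position_errors",
    "standard_course",
    "STANDARD_LEGS",
    "STANDARD_INNER_ANGLE_DEG",
    "APPROACH_START",
]

#: Outbound leg lengths of the standard course, in vm.
STANDARD_LEGS = (35.4, 25.0)
#: Inner angle between the two outbound legs, degrees.
STANDARD_INNER_ANGLE_DEG = 45.0


class Point2D(NamedTuple):
    """A point in the virtual plane, coordinates in vm."""

    x: float
    y: float


#: The avatar approaches the goal from here at trial start.
APPROACH_START = Point2D(0.0, -10.0)


@dataclass(frozen=True)
class HomeVector:
    """Ideal homing response at the release point.

    ``turn_angle_deg`` is the deviation of the home bearing from the
    continuation of the incoming heading, i.e. ``180 - interior_angle_deg``.
    """

    distance: float
    turn_angle_deg: float
    interior_angle_deg: float


@dataclass(frozen=True)
class PolarEstimate:
    """Polar decomposition of an endpoint: radial distance ``d`` (vm) and
    signed angle ``x`` (radians in ``[-pi, pi]``) relative to a reference
    heading.  ``degenerate`` flags an endpoint coinciding with the center,
    where the angle is undefined (reported as 0)."""

    d: float
    x: float
    degenerate: bool = False


def wrap_angle(theta):
    """Wrap angle(s) to ``[-pi, pi]`` (scalar or array)."""
    return (np.asarray(theta) + math.pi) % (2.0 * math.pi) - math.pi


def ideal_home_vector(leg1: float, leg2: float, inner_angle_deg: float) -> HomeVector:
    """Ideal home vector of a triangle with outbound legs ``leg1``, ``leg2``
    and inner angle ``inner_angle_deg`` between them.

    The return distance is the third side (law of cosines); the turn angle is
    the deviation of the home bearing from the continuation of the incoming
    heading at the release point.

    >>> hv = ideal_home_vector(35.4, 25.0, 45.0)
    >>> round(hv.turn_angle_deg)
    90
    """
    if leg1 <= 0 or leg2 <= 0:
        raise ValueError("outbound legs must be positive")
    if not 0.0 < inner_angle_deg <= 180.0:
        raise ValueError("inner angle must lie in (0, 180] degrees")
    gamma = math.radians(inner_angle_deg)
    dist_sq = leg1 * leg1 + leg2 * leg2 - 2.0 * leg1 * leg2 * math.cos(gamma)
    distance = math.sqrt(max(dist_sq, 0.0))
    if distance == 0.0:
        # degenerate triangle (legs coincide); the home turn is undefined
        return HomeVector(distance=0.0, turn_angle_deg=float("nan"),
                          interior_angle_deg=float("nan"))
    # interior angle at the release vertex, opposite leg1
    cos_beta = (leg2 * leg2 + dist_sq - leg1 * leg1) / (2.0 * leg2 * distance)
    beta = math.degrees(math.acos(min(1.0, max(-1.0, cos_beta))))
    return HomeVector(distance=distance, turn_angle_deg=180.0 - beta,
                      interior_angle_deg=beta)


def to_polar(endpoint: Point2D, center: Point2D, reference_heading: float) -> PolarEstimate:
    """Decompose ``endpoint`` into distance and signed angle (positive CCW)
    relative to ``center`` and ``reference_heading`` (radians)."""
    dx = endpoint[0] - center[0]
    dy = endpoint[1] - center[1]
    d = math.hypot(dx, dy)
    if d == 0.0:
        return PolarEstimate(d=0.0, x=0.0, degenerate=True)
    x = float(wrap_angle(math.atan2(dy, dx) - reference_heading))
    return PolarEstimate(d=d, x=x)


def from_polar(center: Point2D, reference_heading: float, d: float, x: float) -> Point2D:
    """Inverse of :func:`to_polar`."""
    theta = reference_heading + x
    return Point2D(center[0] + d * math.cos(theta), center[1] + d * math.sin(theta))


def polar_decompose(points: np.ndarray, center: Point2D, reference_heading: float):
    """Vectorised :func:`to_polar` for an ``(n, 2)`` array.

    Returns ``(d, x)`` arrays; degenerate points (at the center) get angle 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    delta = pts - np.asarray(center, dtype=float)
    d = np.hypot(delta[:, 0], delta[:, 1])
    x = np.where(d > 0.0,
                 wrap_angle(np.arctan2(delta[:, 1], delta[:, 0]) - reference_heading),
                 0.0)
    return d, x


def polar_compose(center: Point2D, reference_heading: float,
                  d: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorised :func:`from_polar`; returns an ``(n, 2)`` array."""
    d = np.asarray(d, dtype=float)
    theta = reference_heading + np.asarray(x, dtype=float)
    return np.column_stack([center[0] + d * np.cos(theta),
                            center[1] + d * np.sin(theta)])


def position_error(endpoint: Point2D, goal: Point2D) -> float:
    """Euclidean distance between an endpoint and the goal, in vm."""
    return math.hypot(endpoint[0] - goal[0], endpoint[1] - goal[1])


def position_errors(points: np.ndarray, goal: Point2D) -> np.ndarray:
    """Vectorised :func:`position_error` for an ``(n, 2)`` array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    delta = pts - np.asarray(goal, dtype=float)
    return np.hypot(delta[:, 0], delta[:, 1])


@dataclass(frozen=True)
class Course:
    """The outbound triangle: goal, the two waypoints, and the heading of
    travel on the second leg (the reference for directional estimates)."""

    goal: Point2D
    waypoints: tuple[Point2D, Point2D]
    release_heading: float
    leg1: float
    leg2: float
    inner_angle_deg: float

    @property
    def release(self) -> Point2D:
        """The release point (second waypoint), start of the return."""
        return self.waypoints[1]

    @property
    def home(self) -> HomeVector:
        return ideal_home_vector(self.leg1, self.leg2, self.inner_angle_deg)

    @property
    def ideal_turn(self) -> float:
        """Signed ideal homing turn (radians, positive CCW)."""
        est = to_polar(self.goal, self.release, self.release_heading)
        return est.x

    def segments(self) -> list[tuple[Point2D, Point2D]]:
        """Outbound legs plus the direct return segment."""
        w1, w2 = self.waypoints
        return [(self.goal, w1), (w1, w2), (w2, self.goal)]


def standard_course(leg1: float = STANDARD_LEGS[0],
                    leg2: float = STANDARD_LEGS[1],
                    inner_angle_deg: float = STANDARD_INNER_ANGLE_DEG,
                    first_leg_heading: float = math.pi) -> Course:
    """Build the standard outbound course.

    The goal sits at the origin; the first leg leaves along
    ``first_leg_heading`` (default -x) and the triangle turns
    counter-clockwise, so the ideal homing turn is positive (~ +90 degrees
    for the standard parameters).
    """
    if leg1 <= 0 or leg2 <= 0:
        raise ValueError("outbound legs must be positive")
    if not 0.0 < inner_angle_deg <= 180.0:
        raise ValueError("inner angle must lie in (0, 180] degrees")
    goal = Point2D(0.0, 0.0)
    w1 = Point2D(goal.x + leg1 * math.cos(first_leg_heading),
                 goal.y + leg1 * math.sin(first_leg_heading))
    # counter-clockwise turn by the exterior angle at the first waypoint
    second_heading = first_leg_heading + math.radians(180.0 - inner_angle_deg)
    w2 = Point2D(w1.x + leg2 * math.cos(second_heading),
                 w1.y + leg2 * math.sin(second_heading))
    return Course(goal=goal, waypoints=(w1, w2),
                  release_heading=float(wrap_angle(second_heading)),
                  leg1=leg1, leg2=leg2, inner_angle_deg=inner_angle_deg)
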