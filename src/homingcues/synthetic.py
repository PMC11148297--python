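"""Synthetic endpoint generators for the homing task.

The generators emulate the statistical structure the analysis assumes, with
all noise injected at the endpoint-report level (the PI system is treated
as noisy as a whole, without attributing noise to perception vs. motor
control):

* a PI-only generator sampling distance (truncated Gaussian) and direction
  (von Mises) estimates independently from the release point,
* an *integration* generator sampling from the normalised product surface
  ``f(x) * g_PI(d) * prod g_LM(d_i)`` (cue integration sharpens estimates),
* an *alternation* generator that picks one object per trial and samples
  from that object's normalised ``f(x) * g(d_i)`` component (a mixture,
  which spreads estimates), emulating trial-wise landmark confusion, and
* a study-level composer producing balanced multi-participant trial tables
  with per-participant biases and a clutter-confusion probability that
  reproduces the qualitative split between participants who do and do not
  degrade in clutter.  The confusion probability is a synthetic stand-in
  knob, not an empirically measured quantity.

Determinism: every generator is reproducible for a fixed seed; the study
composer derives one child seed per participant x condition from a single
root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .environment import CONDITIONS, Environment, build_environment
from .geometry import Course, Point2D, polar_compose, standard_course
from .mle import CombinedModel, FanModel, RingModel, default_extent, DEFAULT_RESOLUTION

__all__ = [
    "TRIAL_COLUMNS",
    "ParticipantProfile",
    "simulate_pi_endpoints",
    "simulate_integration_endpoints",
    "simulate_alternation_endpoints",
    "simulate_study",
    "default_cohort",
    "sample_from_model",
    "DEFAULT_LANDMARK_SIGMA",
]

#: Trial-table schema shared across the package.
TRIAL_COLUMNS = ("participant", "session", "condition", "trial_index", "x", "y", "valid")

#: Spread (vm) of the landmark distance estimate, standing in for the spread
#: observed in the one-object condition.
DEFAULT_LANDMARK_SIGMA = 2.0

#: High-clutter conditions in which trial-wise object confusion can occur.
CLUTTER_CONDITIONS = (10, 99)


@dataclass(frozen=True)
class ParticipantProfile:
    """Persistent individual biases and noise levels of one participant.

    Biases are applied to the ideal home vector: positive distance bias is
    overshooting, positive direction bias (degrees, CCW) overshoots the
    homing turn.  ``clutter_confusion_prob`` is the per-trial probability of
    mistaking a random object for one of the goal-surrounding trees in the
    high-clutter conditions.
    """

    id: str
    pi_direction_bias_deg: float = 0.0
    pi_distance_bias: float = 0.0
    pi_direction_sd_deg: float = 26.0
    pi_distance_sd: float = 4.0
    clutter_confusion_prob: float = 0.0

    def __post_init__(self):
        if not (self.pi_direction_sd_deg > 0 and self.pi_distance_sd > 0):
            raise ValueError("profile SDs must be > 0")
        if not 0.0 <= self.clutter_confusion_prob <= 1.0:
            raise ValueError("confusion probability must be in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_pi_endpoints(release: Point2D, reference_heading: float,
                          mu_d: float, sigma: float, mu_x: float, kappa: float,
                          n: int, seed=0) -> np.ndarray:
    """Sample ``n`` PI-only endpoints from the release point.

    Distances are Gaussian ``(mu_d, sigma)`` truncated at zero (by
    resampling; negligible mass for mu/sigma >= 5), angles von Mises
    ``(mu_x, kappa)``.  Returns an ``(n, 2)`` array of Cartesian endpoints.
    """
    if sigma <= 0 or kappa < 0 or n < 1:
        raise ValueError("require sigma > 0, kappa >= 0, n >= 1")
    rng = _rng(seed)
    d = rng.normal(mu_d, sigma, size=n)
    while True:
        bad = d <= 0.0
        if not bad.any():
            break
        d[bad] = rng.normal(mu_d, sigma, size=int(bad.sum()))
    x = rng.vonmises(mu_x, kappa, size=n) if kappa > 0 else rng.uniform(-math.pi, math.pi, n)
    return polar_compose(release, reference_heading, d, x)


def _grid_logdensity(model: CombinedModel, extent, resolution):
    xmin, xmax, ymin, ymax = extent
    xs = np.arange(xmin + resolution / 2.0, xmax, resolution)
    ys = np.arange(ymin + resolution / 2.0, ymax, resolution)
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return centers, model.log_density_at(centers)


def sample_from_model(model: CombinedModel, n: int, seed=0,
                      extent=None, resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
    """Sample endpoints from the normalised surface of a combined model.

    Grid-based: cells are drawn proportionally to the density at their
    centers and jittered uniformly within the cell, so the sample follows a
    piecewise-constant approximation at the grid resolution (0.25 vm by
    default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    extent = extent or default_extent(model)
    centers, logd = _grid_logdensity(model, extent, resolution)
    logd = logd - special.logsumexp(logd)
    with np.errstate(under="ignore"):
        p = np.exp(logd)
    p /= p.sum()
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("degenerate model surface (all-zero mass)")
    cells = rng.choice(len(p), size=n, p=p)
    jitter = rng.uniform(-resolution / 2.0, resolution / 2.0, size=(n, 2))
    return centers[cells] + jitter


def simulate_integration_endpoints(fan: FanModel, ring_pi: RingModel | None,
                                   rings_lm, n: int, seed=0,
                                   resolution: float = DEFAULT_RESOLUTION,
                                   extent=None) -> np.ndarray:
    """Sample endpoints from the integration (product) model.

    With no landmark rings and a PI ring centered on the fan vertex this
    reduces exactly to :func:`simulate_pi_endpoints` (the empty product),
    and that exact sampler is used; otherwise sampling is grid-based on the
    normalised product surface.
    """
    rings_lm = tuple(rings_lm)
    if not rings_lm and ring_pi is not None and tuple(ring_pi.center) == tuple(fan.vertex):
        return simulate_pi_endpoints(fan.vertex, fan.reference_heading,
                                     ring_pi.mu_d, ring_pi.sigma,
                                     fan.mu_x, fan.kappa, n, seed)
    model = CombinedModel(fan=fan, ring_pi=ring_pi, rings_lm=rings_lm,
                          mode="integration")
    return sample_from_model(model, n, seed=seed, extent=extent, resolution=resolution)


def _component_extent(ring: RingModel, margin_sigmas: float = 5.0):
    r = ring.mu_d + margin_sigmas * ring.sigma
    return (ring.center[0] - r, ring.center[0] + r,
            ring.center[1] - r, ring.center[1] + r)


def simulate_alternation_endpoints(env: Environment, fan: FanModel,
                                   ring_template: RingModel, n: int, seed=0,
                                   weights=None,
                                   resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
    """Sample endpoints from the alternation (mixture) model.

    Per trial one object is drawn by ``weights`` (equal by default) and the
    endpoint is sampled from that object's normalised
    ``f(x) * g(d_to_object)`` component, emulating a navigator who commits
    to a single - possibly misidentified - tree on each trial.
    """
    if len(env.objects) == 0:
        raise ValueError("alternation requires an environment with >= 1 object")
    if n < 1:
        raise ValueError("n must be >= 1")
    n_obj = len(env.objects)
    if weights is None:
        w = np.full(n_obj, 1.0 / n_obj)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_obj,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be non-negative over objects and sum to 1")
    rng = _rng(seed)
    counts = rng.multinomial(n, w)
    chunks = []
    for obj, count in zip(env.objects, counts):
        if count == 0:
            continue
        ring = RingModel(center=obj, mu_d=ring_template.mu_d, sigma=ring_template.sigma)
        component = CombinedModel(fan=fan, rings_lm=(ring,), mode="integration")
        chunks.append(sample_from_model(component, int(count), seed=rng,
                                        extent=_component_extent(ring),
                                        resolution=resolution))
    endpoints = np.vstack(chunks)
    return endpoints[rng.permutation(n)]


def _profile_fan_ring(profile: ParticipantProfile, course: Course
                      ) -> tuple[FanModel, RingModel]:
    """Generative PI components of one participant: the ideal home vector
    shifted by the participant's biases.  The generative concentration uses
    the Gaussian relation kappa = 1/sd^2 so the sampled angular spread
    matches the profile's direction SD."""
    home = course.home
    mu_d = home.distance + profile.pi_distance_bias
    mu_x = course.ideal_turn + math.radians(profile.pi_direction_bias_deg)
    kappa = 1.0 / math.radians(profile.pi_direction_sd_deg) ** 2
    fan = FanModel(vertex=course.release, reference_heading=course.release_heading,
                   mu_x=mu_x, kappa=kappa)
    ring = RingModel(center=course.release, mu_d=mu_d, sigma=profile.pi_distance_sd)
    return fan, ring


def simulate_study(profiles, conditions=CONDITIONS, reps_per_condition: int = 24,
                   sessions: int = 4, seed: int = 0,
                   course: Course | None = None, env_seed: int | None = None,
                   landmark_sigma: float = DEFAULT_LANDMARK_SIGMA,
                   resolution: float = DEFAULT_RESOLUTION) -> pd.DataFrame:
    """Simulate a balanced multi-participant study as a trial table.

    For each participant x condition, ``reps_per_condition`` trials are
    generated (``reps_per_condition`` must divide evenly across
    ``sessions``): PI-only in the zero-object condition; integration of PI
    with all present landmark rings in the 1-3 object conditions; and in
    the high-clutter conditions each trial is alternation-generated over
    *all* objects with the participant's confusion probability, otherwise
    integration-generated with the three goal-surrounding rings.

    Returns a table with columns ``participant, session, condition,
    trial_index, x, y, valid``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one participant profile is required")
    if reps_per_condition % sessions != 0:
        raise ValueError("reps_per_condition must be divisible by sessions")
    course = course or standard_course()
    env_seed = seed if env_seed is None else env_seed
    envs = {c: build_environment(c, seed=env_seed, course=course) for c in conditions}
    ring_template = RingModel(center=course.goal, mu_d=10.0, sigma=landmark_sigma)

    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(profiles) * len(conditions)))
    reps_per_session = reps_per_condition // sessions
    rows = []
    for profile in profiles:
        fan, ring_pi = _profile_fan_ring(profile, course)
        for condition in conditions:
            rng = np.random.default_rng(next(children))
            env = envs[condition]
            goal_rings = tuple(RingModel(center=obj, mu_d=10.0, sigma=landmark_sigma)
                               for obj in env.objects[:3])
            n = reps_per_condition
            if condition == 0:
                pts = simulate_pi_endpoints(course.release, course.release_heading,
                                            ring_pi.mu_d, ring_pi.sigma,
                                            fan.mu_x, fan.kappa, n, seed=rng)
            elif condition in CLUTTER_CONDITIONS:
                confused = rng.uniform(size=n) < profile.clutter_confusion_prob
                pts = np.empty((n, 2))
                n_conf = int(confused.sum())
                if n_conf:
                    pts[confused] = simulate_alternation_endpoints(
                        env, fan, ring_template, n_conf, seed=rng,
                        resolution=resolution)
                if n_conf < n:
                    pts[~confused] = simulate_integration_endpoints(
                        fan, ring_pi, goal_rings, n - n_conf, seed=rng,
                        resolution=resolution)
            else:
                pts = simulate_integration_endpoints(
                    fan, ring_pi, goal_rings, n, seed=rng, resolution=resolution)
            for i in range(n):
                rows.append((profile.id, i // reps_per_session + 1, condition, i,
                             pts[i, 0], pts[i, 1], True))
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def default_cohort(n_participants: int = 23, seed: int = 0,
                   confused_fraction: float = 11.0 / 23.0) -> list[ParticipantProfile]:
    """A cohort with the study's population structure: persistent
    individual distance/direction biases (population-level overshoot of
    both the ~25 vm return distance and the ~90 degree turn), heterogeneous
    PI noise around a ~26 degree directional spread, and a split between
    participants who do (high confusion probability) and do not (near zero)
    degrade in clutter."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_participants):
        confused = rng.uniform() < confused_fraction
        profiles.append(ParticipantProfile(
            id=f"p{i + 1:02d}",
            pi_distance_bias=float(rng.normal(1.5, 1.5)),
            pi_direction_bias_deg=float(rng.normal(8.0, 8.0)),
            pi_distance_sd=float(np.clip(rng.normal(4.0, 1.0), 1.5, None)),
            pi_direction_sd_deg=float(np.clip(rng.normal(26.0, 8.0), 8.0, None)),
            clutter_confusion_prob=float(rng.uniform(0.6, 0.9)) if confused
            else float(rng.uniform(0.0, 0.1)),
        ))
    return profiles
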