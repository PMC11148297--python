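"""Maximum-likelihood cue-combination models for homing endpoints.

The model family treats a goal estimate as a distance and a direction
estimate.  Distance information (from path integration or from a landmark)
is a Gaussian over radial distance,

    g(d) = 1/(sigma sqrt(2 pi)) * exp(-(d - mu_d)^2 / (2 sigma^2)),

whose 2D image is a ring (annulus) around its reference point.  Direction
information is a von Mises density over the signed homing angle,

    f(x) = 1/(2 pi I0(kappa)) * exp(kappa cos(x - mu_x)),

whose 2D image is a fan (wedge) opening from the release point; ``I0`` is
the modified Bessel function of order zero.  Several distance estimates are
combined either by multiplication (cue *integration*, a product of experts
that sharpens the estimate) or by summation (cue *alternation*, an
equal-weight mixture that spreads it), and the combined distance term is
always multiplied with the single direction term:

    L_combined = f(x) * g_combined(d),      l = sum over trials of log L.

Landmark rings are fixed at the true goal distance of 10 vm with a shared
spread measured from the one-object condition; only the four PI parameters
(mu_d, sigma, mu_x, kappa) are ever fitted, which keeps all model variants
in the same class so log-likelihoods, AIC and BIC rank them coherently.

All composition happens in log space.  ``L_combined`` as written is not a
normalised density over the plane (the paper-style score); pass
``normalize=True`` (the default in :func:`compare_models`) to divide by the
grid-integrated mass so that integration and alternation variants are
compared on proper densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .environment import Environment, LANDMARK_RADIUS
from .geometry import Point2D, polar_decompose, wrap_angle

__all__ = [
    "RingModel",
    "FanModel",
    "CombinedModel",
    "FitResult",
    "Surface",
    "ring_logdensity",
    "fan_logdensity",
    "kappa_from_circular_std",
    "kappa_from_resultant_length",
    "circular_mean_resultant",
    "circular_std",
    "combine_rings",
    "combined_loglik",
    "log_normalizer",
    "fit_pi_model",
    "landmark_rings",
    "compare_models",
    "bootstrap_parameter_cis",
    "evaluate_surface",
    "default_extent",
    "DEFAULT_RESOLUTION",
]

#: Default spatial grid resolution (vm) for surfaces and normalisation.
DEFAULT_RESOLUTION = 0.25

_LOG_TWO_PI = math.log(2.0 * math.pi)


def _log_i0(kappa) -> np.ndarray:
    """log I0(kappa), stable for large kappa via the scaled Bessel function."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


@dataclass(frozen=True)
class RingModel:
    """Gaussian distance estimate around ``center``: mean ``mu_d`` and
    spread ``sigma`` in vm.  Its 2D image is an annulus."""

    center: Point2D
    mu_d: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("ring sigma must be > 0")

    def logpdf(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        z = (d - self.mu_d) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * _LOG_TWO_PI

    def logpdf_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return self.logpdf(d)


@dataclass(frozen=True)
class FanModel:
    """Von Mises direction estimate opening from ``vertex``: mean direction
    ``mu_x`` (radians relative to ``reference_heading``, positive CCW) and
    concentration ``kappa``.  ``kappa = 0`` is the explicit uniform limit."""

    vertex: Point2D
    reference_heading: float
    mu_x: float
    kappa: float

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("fan kappa must be >= 0")
        object.__setattr__(self, "mu_x", float(wrap_angle(self.mu_x)))

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kappa == 0.0:
            return np.full(x.shape, -_LOG_TWO_PI)
        return self.kappa * np.cos(x - self.mu_x) - _LOG_TWO_PI - _log_i0(self.kappa)

    def logpdf_at(self, points: np.ndarray) -> np.ndarray:
        _, x = polar_decompose(points, self.vertex, self.reference_heading)
        return self.logpdf(x)


def ring_logdensity(d, model: RingModel) -> np.ndarray:
    """Log of the Gaussian distance density at ``d``."""
    return model.logpdf(d)


def fan_logdensity(x, model: FanModel) -> np.ndarray:
    """Log of the von Mises direction density at angle ``x`` (radians)."""
    return model.logpdf(x)


def circular_mean_resultant(x: np.ndarray) -> tuple[float, float]:
    """Circular mean and mean resultant length of angles ``x`` (radians)."""
    x = np.asarray(x, dtype=float)
    c, s = np.mean(np.cos(x)), np.mean(np.sin(x))
    return float(np.arctan2(s, c)), float(np.hypot(c, s))


def circular_std(x: np.ndarray) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in radians."""
    _, r = circular_mean_resultant(x)
    if r <= 0.0:
        return float("inf")
    return math.sqrt(max(-2.0 * math.log(min(r, 1.0)), 0.0))


def kappa_from_circular_std(std_x: float, estimator: str = "reciprocal") -> float:
    """Concentration parameter from a circular standard deviation (radians).

    ``estimator="reciprocal"`` applies the rule ``kappa = 1/std(x)`` used in
    the original analysis; ``"gaussian"`` applies the large-concentration
    relation ``kappa = 1/std^2``.  ``std -> inf`` maps to 0 (uniform).
    """
    if not std_x > 0:
        raise ValueError("circular std must be > 0")
    if math.isinf(std_x):
        return 0.0
    if estimator == "reciprocal":
        return 1.0 / std_x
    if estimator == "gaussian":
        return 1.0 / (std_x * std_x)
    raise ValueError(f"unknown estimator {estimator!r}")


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), the expected resultant length."""
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_from_resultant_length(r: float, kappa_max: float = 1e6) -> float:
    """Standard von Mises MLE of kappa: invert ``A(kappa) = R``.

    ``R`` is the mean resultant length of the sample.  ``R <= 0`` maps to 0
    (uniform); ``R`` close to 1 is clipped at ``kappa_max``.
    """
    if r <= 0.0:
        return 0.0
    if r >= _bessel_ratio(kappa_max):
        return kappa_max
    return float(optimize.brentq(lambda k: _bessel_ratio(k) - r, 1e-12, kappa_max,
                                 xtol=1e-10, rtol=1e-12))


def landmark_rings(env: Environment, sigma: float,
                   mu_d: float = LANDMARK_RADIUS) -> tuple[RingModel, ...]:
    """One ring per object, fixed at the true goal distance (10 vm) with a
    shared spread ``sigma`` (the spread observed in the one-object
    condition)."""
    return tuple(RingModel(center=obj, mu_d=mu_d, sigma=sigma) for obj in env.objects)


def _stack_ring_logpdfs(rings: Sequence[RingModel], points: np.ndarray) -> np.ndarray:
    return np.vstack([ring.logpdf_at(points) for ring in rings])


def _combine_ring_logpdfs(logs: np.ndarray, mode: str,
                          weights: np.ndarray | None) -> np.ndarray:
    if mode == "integration":
        return logs.sum(axis=0)
    if mode == "alternation":
        n = logs.shape[0]
        if weights is None:
            log_w = np.full(n, -math.log(n))
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
                raise ValueError("alternation weights must be non-negative and sum to 1")
            with np.errstate(divide="ignore"):
                log_w = np.log(w)
        return special.logsumexp(logs + log_w[:, None], axis=0)
    raise ValueError(f"unknown combination mode {mode!r}")


def combine_rings(rings: Sequence[RingModel], mode: str, point: Point2D,
                  weights: Sequence[float] | None = None) -> float:
    """Combined log-density of several rings at one point.

    Integration multiplies the component densities (sum of logs);
    alternation takes the equal-weight mixture ``(sum g_i)/n`` so that the
    result is still a density in each ring's distance coordinate.
    """
    if not rings:
        raise ValueError("at least one ring is required")
    logs = _stack_ring_logpdfs(rings, np.asarray([point], dtype=float))
    w = None if weights is None else np.asarray(weights, dtype=float)
    return float(_combine_ring_logpdfs(logs, mode, w)[0])


@dataclass(frozen=True)
class CombinedModel:
    """A full model variant: direction fan, optional PI distance ring, and
    zero or more landmark rings combined by ``mode``.

    The PI components are always of integration form; ``mode`` only governs
    how the landmark rings are combined with each other.  ``n_free`` records
    how many parameters were fitted (landmark rings are fixed), feeding AIC
    and BIC.
    """

    fan: FanModel
    ring_pi: RingModel | None = None
    rings_lm: tuple[RingModel, ...] = ()
    mode: str = "integration"
    weights: tuple[float, ...] | None = None
    n_free: int = 4

    def __post_init__(self):
        if self.mode not in ("integration", "alternation"):
            raise ValueError(f"unknown combination mode {self.mode!r}")

    def log_density_at(self, points: np.ndarray) -> np.ndarray:
        """Unnormalised log L_combined = log f(x) + log g_combined(d) at
        Cartesian points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        total = self.fan.logpdf_at(pts)
        if self.ring_pi is not None:
            total = total + self.ring_pi.logpdf_at(pts)
        if self.rings_lm:
            logs = _stack_ring_logpdfs(self.rings_lm, pts)
            w = None if self.weights is None else np.asarray(self.weights, dtype=float)
            total = total + _combine_ring_logpdfs(logs, self.mode, w)
        return total

    def with_mode(self, mode: str) -> "CombinedModel":
        return replace(self, mode=mode)


def default_extent(model: CombinedModel, margin_sigmas: float = 5.0
                   ) -> tuple[float, float, float, float]:
    """A bounding box covering the model's effective support: every ring's
    annulus out to ``mu_d + margin_sigmas * sigma`` around its center."""
    centers: list[tuple[float, float, float]] = []
    if model.ring_pi is not None:
        r = model.ring_pi
        centers.append((r.center[0], r.center[1], r.mu_d + margin_sigmas * r.sigma))
    for r in model.rings_lm:
        centers.append((r.center[0], r.center[1], r.mu_d + margin_sigmas * r.sigma))
    if not centers:
        raise ValueError("a fan-only model has unbounded radial support; "
                         "pass an explicit extent")
    xs = [c[0] - c[2] for c in centers] + [c[0] + c[2] for c in centers]
    ys = [c[1] - c[2] for c in centers] + [c[1] + c[2] for c in centers]
    return (min(xs), max(xs), min(ys), max(ys))


def _grid(extent: tuple[float, float, float, float], resolution: float):
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    xmin, xmax, ymin, ymax = extent
    xs = np.arange(xmin + resolution / 2.0, xmax, resolution)
    ys = np.arange(ymin + resolution / 2.0, ymax, resolution)
    xx, yy = np.meshgrid(xs, ys)
    return xs, ys, np.column_stack([xx.ravel(), yy.ravel()])


def log_normalizer(model: CombinedModel,
                   extent: tuple[float, float, float, float] | None = None,
                   resolution: float = DEFAULT_RESOLUTION) -> float:
    """log of the grid-integrated mass of ``exp(log_density_at)`` over the
    plane (midpoint rule)."""
    extent = extent or default_extent(model)
    _, _, centers = _grid(extent, resolution)
    logd = model.log_density_at(centers)
    return float(special.logsumexp(logd) + 2.0 * math.log(resolution))


def combined_loglik(model: CombinedModel, endpoints: np.ndarray,
                    normalize: bool = False,
                    extent: tuple[float, float, float, float] | None = None,
                    resolution: float = DEFAULT_RESOLUTION) -> float:
    """Summed log-likelihood of endpoints under a combined model.

    Endpoints coinciding with the fan vertex have no defined direction; they
    are excluded with a warning.  With ``normalize=True`` the density is
    divided by its grid-integrated mass over the plane, making log-
    likelihoods comparable across integration and alternation variants.
    """
    pts = np.atleast_2d(np.asarray(endpoints, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("endpoints must be non-empty")
    d, _ = polar_decompose(pts, model.fan.vertex, model.fan.reference_heading)
    keep = d > 0.0
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} endpoint(s) at the fan vertex "
                      "(direction undefined)", stacklevel=2)
        pts = pts[keep]
        if pts.shape[0] == 0:
            raise ValueError("all endpoints coincide with the fan vertex")
    ll = float(model.log_density_at(pts).sum())
    if normalize:
        ll -= pts.shape[0] * log_normalizer(model, extent=extent, resolution=resolution)
    return ll


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with likelihood-based fit measures."""

    params: Mapping[str, float]
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    model: CombinedModel | None = None
    cis: Mapping[str, tuple[float, float]] | None = None
    n_dropped: int = 0


def fit_pi_model(endpoints: np.ndarray, release: Point2D, reference_heading: float,
                 kappa_estimator: str = "reciprocal_std") -> FitResult:
    """Closed-form MLE of the four PI parameters from endpoints.

    ``mu_d`` and ``sigma`` are the Gaussian MLEs (mean and 1/n-denominator
    standard deviation) of the radial distances from the release point;
    ``mu_x`` is the circular mean of the homing angles.  ``kappa`` follows
    the configured estimator: ``"reciprocal_std"`` applies the
    ``kappa = 1/std(x)`` rule of the original analysis; ``"mle"`` inverts
    the Bessel ratio ``I1/I0`` at the mean resultant length (the standard
    von Mises MLE, used for parameter-recovery checks).
    """
    pts = np.atleast_2d(np.asarray(endpoints, dtype=float))
    d, x = polar_decompose(pts, release, reference_heading)
    keep = d > 0.0
    n_dropped = int((~keep).sum())
    d, x = d[keep], x[keep]
    if d.size < 3:
        raise ValueError(f"need >= 3 usable endpoints, got {d.size}")

    mu_d = float(d.mean())
    sigma = float(d.std(ddof=0))
    mu_x, r = circular_mean_resultant(x)
    # identical endpoints leave only rounding noise in the spread
    degenerate = sigma <= 1e-12 * max(1.0, abs(mu_d))
    if degenerate:
        sigma = 0.0

    if kappa_estimator == "reciprocal_std":
        cstd = circular_std(x)
        kappa = kappa_from_circular_std(cstd) if cstd > 0.0 else float("inf")
    elif kappa_estimator == "mle":
        kappa = kappa_from_resultant_length(r)
    else:
        raise ValueError(f"unknown kappa estimator {kappa_estimator!r}")

    if degenerate or not np.isfinite(kappa):
        params = {"mu_d": mu_d, "sigma": sigma, "mu_x": mu_x, "kappa": kappa}
        return FitResult(params=params, loglik=float("nan"), aic=float("nan"),
                         bic=float("nan"), n_obs=int(d.size), converged=False,
                         n_dropped=n_dropped)

    fan = FanModel(vertex=release, reference_heading=reference_heading,
                   mu_x=mu_x, kappa=kappa)
    ring = RingModel(center=release, mu_d=mu_d, sigma=sigma)
    ll = float(fan.logpdf(x).sum() + ring.logpdf(d).sum())
    k = 4
    n = int(d.size)
    return FitResult(params={"mu_d": mu_d, "sigma": sigma, "mu_x": mu_x, "kappa": kappa},
                     loglik=ll, aic=2.0 * k - 2.0 * ll,
                     bic=k * math.log(n) - 2.0 * ll,
                     n_obs=n, converged=True,
                     model=CombinedModel(fan=fan, ring_pi=ring),
                     n_dropped=n_dropped)


def compare_models(candidates: Mapping[str, CombinedModel], endpoints: np.ndarray,
                   normalize: bool = True,
                   resolution: float = DEFAULT_RESOLUTION,
                   extent: tuple[float, float, float, float] | None = None
                   ) -> pd.DataFrame:
    """Rank model variants on the same endpoints by log-likelihood.

    Returns a table (index = candidate name) with ``loglik``, ``aic``,
    ``bic`` and a 1-based ``rank`` by log-likelihood.  The attribute
    ``attrs["consistent"]`` flags whether the loglik/AIC/BIC orderings
    agree.  By default log-likelihoods are normalized over the plane so
    integration and alternation variants are compared on proper densities.
    """
    pts = np.atleast_2d(np.asarray(endpoints, dtype=float))
    n = pts.shape[0]
    rows = {}
    for name, model in candidates.items():
        ll = combined_loglik(model, pts, normalize=normalize,
                             resolution=resolution, extent=extent)
        rows[name] = {"loglik": ll,
                      "aic": 2.0 * model.n_free - 2.0 * ll,
                      "bic": model.n_free * math.log(n) - 2.0 * ll,
                      "n_obs": n}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["rank"] = table["loglik"].rank(ascending=False, method="min").astype(int)
    order_ll = tuple(table.sort_values("loglik", ascending=False).index)
    order_aic = tuple(table.sort_values("aic").index)
    order_bic = tuple(table.sort_values("bic").index)
    table.attrs["consistent"] = order_ll == order_aic == order_bic
    return table.sort_values("rank")


def bootstrap_parameter_cis(endpoints: np.ndarray, release: Point2D,
                            reference_heading: float, B: int = 1000,
                            conf: float = 0.95, seed: int = 0,
                            kappa_estimator: str = "reciprocal_std"
                            ) -> dict[str, tuple[float, float]]:
    """Nonparametric percentile bootstrap CIs for the four PI parameters.

    Trials are resampled with replacement ``B`` times and the closed-form
    fit recomputed on each resample.  Degenerate resamples (zero distance
    spread) are skipped; their count is reported under ``"n_skipped"``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    pts = np.atleast_2d(np.asarray(endpoints, dtype=float))
    d, x = polar_decompose(pts, release, reference_heading)
    keep = d > 0.0
    d, x = d[keep], x[keep]
    n = d.size
    if n < 3:
        raise ValueError("need >= 3 usable endpoints")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    d_mat = d[idx]
    mu_d = d_mat.mean(axis=1)
    sigma = d_mat.std(axis=1, ddof=0)
    c = np.cos(x)[idx].mean(axis=1)
    s = np.sin(x)[idx].mean(axis=1)
    mu_x = np.arctan2(s, c)
    r = np.clip(np.hypot(c, s), 0.0, 1.0)

    ok = sigma > 0.0
    n_skipped = int((~ok).sum())
    if kappa_estimator == "reciprocal_std":
        with np.errstate(divide="ignore"):
            cstd = np.sqrt(np.maximum(-2.0 * np.log(np.where(r > 0, r, np.nan)), 0.0))
            kappa = np.where(cstd > 0, 1.0 / cstd, np.inf)
    elif kappa_estimator == "mle":
        kappa = np.array([kappa_from_resultant_length(float(ri)) for ri in r])
    else:
        raise ValueError(f"unknown kappa estimator {kappa_estimator!r}")

    lo_q, hi_q = 100.0 * (1.0 - conf) / 2.0, 100.0 * (1.0 + conf) / 2.0
    out: dict = {}
    for name, values in (("mu_d", mu_d), ("sigma", sigma),
                         ("mu_x", mu_x), ("kappa", kappa)):
        vals = values[np.isfinite(values)]
        if vals.size == 0:  # e.g. kappa on constant angles (all resamples at R=1)
            out[name] = (float("inf"), float("inf"))
            continue
        out[name] = (float(np.percentile(vals, lo_q)), float(np.percentile(vals, hi_q)))
    out["n_skipped"] = n_skipped
    return out


@dataclass(frozen=True)
class Surface:
    """Gridded, normalised likelihood surface of a model (heatmap data)."""

    values: np.ndarray
    x_centers: np.ndarray
    y_centers: np.ndarray
    resolution: float

    @property
    def argmax(self) -> Point2D:
        iy, ix = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return Point2D(float(self.x_centers[ix]), float(self.y_centers[iy]))

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "likelihood": self.values.ravel()})


def evaluate_surface(model: CombinedModel,
                     extent: tuple[float, float, float, float] | None = None,
                     resolution: float = DEFAULT_RESOLUTION) -> Surface:
    """Evaluate the model density on a spatial grid, normalised to sum 1.

    Cell values are proportional to ``exp(log_density)`` at cell centers;
    darker-is-likelier heatmaps and the argmax cell come straight from this.
    """
    if extent is None:
        extent = default_extent(model)
    xs, ys, centers = _grid(extent, resolution)
    logd = model.log_density_at(centers).reshape(len(ys), len(xs))
    logd -= special.logsumexp(logd)
    return Surface(values=np.exp(logd), x_centers=xs, y_centers=ys,
                   resolution=resolution)
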