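"""Trial-table file format, pipeline configuration, and the end-to-end
analysis pipeline.

Trial tables are plain CSV with the columns ``participant, session,
condition, trial_index, x, y, valid``; rows with blank endpoints are parsed
with ``valid = False`` so the exclusion filter can count them.  Every
numeric output carries a provenance header (comment lines with the config
hash, seed and package version) so a bundle is traceable to its exact
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import CONDITIONS, build_environment, save_environment
from .geometry import polar_decompose, standard_course
from .metrics import (ci_outlier_group, classify_participants, clutter_deltas,
                      exclusion_filter, summarize_performance)
from .mle import (CombinedModel, RingModel, compare_models, evaluate_surface,
                  fit_pi_model, landmark_rings)
from .synthetic import TRIAL_COLUMNS, default_cohort, simulate_study

__all__ = [
    "TrialFormatError",
    "ConfigError",
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "estimate_landmark_sigma",
    "run_pipeline",
]

log = logging.getLogger("homingcues")


class TrialFormatError(ValueError):
    """A trial file does not match the expected schema."""


class ConfigError(ValueError):
    """A pipeline configuration is malformed."""


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV (provenance comment lines are ignored).

    A missing column raises :class:`TrialFormatError` naming it; a row with
    a blank or non-numeric endpoint is kept with ``valid = False``.
    """
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # malformed CSV
        raise TrialFormatError(str(exc)) from exc
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialFormatError(f"missing column(s): {', '.join(missing)}")
    table = table[list(TRIAL_COLUMNS)].copy()
    for coord in ("x", "y"):
        table[coord] = pd.to_numeric(table[coord], errors="coerce")
    parseable = table[["x", "y"]].notna().all(axis=1)
    table["valid"] = table["valid"].astype(bool) & parseable
    table["session"] = table["session"].astype(int)
    table["condition"] = table["condition"].astype(int)
    table["trial_index"] = table["trial_index"].astype(int)
    return table


def _provenance_header(provenance: dict | None) -> str:
    lines = [f"# homingcues {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_trials(table: pd.DataFrame, path: str | Path,
                 provenance: dict | None = None) -> None:
    """Write a trial table as CSV with a provenance comment header."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialFormatError(f"missing column(s): {', '.join(missing)}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(provenance))
        table[list(TRIAL_COLUMNS)].to_csv(fh, index=False)


def _write_csv(frame: pd.DataFrame, path: Path, provenance: dict | None,
               index: bool = False) -> None:
    with path.open("w") as fh:
        fh.write(_provenance_header(provenance))
        frame.to_csv(fh, index=index)


@dataclass(frozen=True)
class DesignBlock:
    participants: int = 23
    conditions: tuple[int, ...] = CONDITIONS
    reps_per_condition: int = 24
    sessions: int = 4
    seed: int = 0


@dataclass(frozen=True)
class EnvironmentBlock:
    seed: int = 0
    corridor_halfwidth: float = 2.5


@dataclass(frozen=True)
class ModelBlock:
    kappa_estimator: str = "reciprocal_std"
    grid_resolution: float = 0.5
    bootstrap_B: int = 500
    confidence: float = 0.95
    landmark_sigma: float | None = None  # None: estimate from condition-1 data
    bootstrap_seed: int = 0


@dataclass(frozen=True)
class PathsBlock:
    output_dir: str = "results"
    trials: str | None = None  # input trial table; None: simulate


_BLOCKS = {"design": DesignBlock, "environment": EnvironmentBlock,
           "model": ModelBlock, "paths": PathsBlock}


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; every stochastic stage has an explicit
    seed and unknown keys are rejected."""

    design: DesignBlock = field(default_factory=DesignBlock)
    environment: EnvironmentBlock = field(default_factory=EnvironmentBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    paths: PathsBlock = field(default_factory=PathsBlock)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_BLOCKS)
        if unknown:
            raise ConfigError(f"unknown config block(s): {sorted(unknown)}")
        blocks = {}
        for name, block_cls in _BLOCKS.items():
            sub = dict(raw.get(name, {}))
            known = set(block_cls.__dataclass_fields__)
            extra = set(sub) - known
            if extra:
                raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(extra)}")
            if "conditions" in sub:
                sub["conditions"] = tuple(sub["conditions"])
            blocks[name] = block_cls(**sub)
        return cls(**blocks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        # paths are excluded: the digest identifies the analysis, not where
        # its outputs land
        payload = {name: asdict(getattr(self, name))
                   for name in ("design", "environment", "model")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def estimate_landmark_sigma(trials: pd.DataFrame, landmark, fallback: float = 2.0,
                            condition: int = 1) -> float:
    """Spread of the landmark distance estimate: the SD of radial distances
    from the first landmark in the one-object condition (falls back to
    ``fallback`` when that condition is absent or degenerate)."""
    cell = trials[(trials["condition"] == condition) & trials["valid"].astype(bool)]
    if len(cell) < 3:
        return fallback
    pts = cell[["x", "y"]].to_numpy(float)
    d = np.hypot(pts[:, 0] - landmark[0], pts[:, 1] - landmark[1])
    sigma = float(d.std(ddof=1))
    return sigma if sigma > 0 else fallback


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis: simulate or load trials, filter, summarise,
    classify, fit and compare cue-combination models, and export surfaces.

    Deterministic for a fixed config: identical seeds produce identical CSV
    outputs.  Returns a manifest mapping artifact names to file paths.
    """
    out_dir = Path(config.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config.digest(), "seed": config.design.seed}
    manifest: dict[str, str] = {}
    course = standard_course()

    def _stage(name):
        log.info("pipeline stage: %s", name)

    try:
        _stage("trials")
        if config.paths.trials:
            trials = read_trials(config.paths.trials)
        else:
            trials = simulate_study(
                default_cohort(config.design.participants, seed=config.design.seed),
                conditions=config.design.conditions,
                reps_per_condition=config.design.reps_per_condition,
                sessions=config.design.sessions,
                seed=config.design.seed,
                env_seed=config.environment.seed,
                course=course)
        write_trials(trials, out_dir / "trials.csv", provenance)
        manifest["trials"] = str(out_dir / "trials.csv")

        _stage("environments")
        envs = {}
        for cond in config.design.conditions:
            envs[cond] = build_environment(
                cond, seed=config.environment.seed,
                corridor_halfwidth=config.environment.corridor_halfwidth,
                course=course)
            save_environment(envs[cond], out_dir / f"environment_{cond}.csv")
            manifest[f"environment_{cond}"] = str(out_dir / f"environment_{cond}.csv")

        _stage("exclusion")
        clean, report = exclusion_filter(trials, max_sessions=config.design.sessions)
        _write_csv(pd.DataFrame([report]), out_dir / "exclusion_report.csv", provenance)
        manifest["exclusion_report"] = str(out_dir / "exclusion_report.csv")

        _stage("summary")
        summary = summarize_performance(clean)
        _write_csv(summary, out_dir / "summary.csv", provenance)
        manifest["summary"] = str(out_dir / "summary.csv")

        _stage("classification")
        conds = set(config.design.conditions)
        if {0, 3, 99} <= conds:
            deltas = clutter_deltas(summary)
            _write_csv(deltas, out_dir / "clutter_deltas.csv", provenance)
            manifest["clutter_deltas"] = str(out_dir / "clutter_deltas.csv")
            labels = classify_participants(clean)
            _write_csv(labels, out_dir / "classification.csv", provenance)
            manifest["classification"] = str(out_dir / "classification.csv")
            ci_groups = ci_outlier_group(deltas, seed=config.design.seed)
            _write_csv(ci_groups, out_dir / "ci_groups.csv", provenance)
            manifest["ci_groups"] = str(out_dir / "ci_groups.csv")

        _stage("model-fits")
        fits = {}
        for cond in config.design.conditions:
            cell = clean[clean["condition"] == cond]
            pts = cell.loc[cell["valid"].astype(bool), ["x", "y"]].to_numpy(float)
            if len(pts) < 3:
                continue
            fits[cond] = fit_pi_model(pts, course.release, course.release_heading,
                                      kappa_estimator=config.model.kappa_estimator)
        fit_rows = [{"condition": cond, **fit.params, "loglik": fit.loglik,
                     "aic": fit.aic, "bic": fit.bic, "n_obs": fit.n_obs}
                    for cond, fit in fits.items()]
        _write_csv(pd.DataFrame(fit_rows), out_dir / "pi_fits.csv", provenance)
        manifest["pi_fits"] = str(out_dir / "pi_fits.csv")

        _stage("model-comparison")
        sigma_lm = config.model.landmark_sigma
        if sigma_lm is None and 1 in envs and envs[1].objects:
            sigma_lm = estimate_landmark_sigma(clean, envs[1].objects[0])
        sigma_lm = sigma_lm or 2.0
        res = config.model.grid_resolution
        for cond, fit in fits.items():
            if cond == 0 or fit.model is None or not envs[cond].objects:
                continue
            rings = landmark_rings(envs[cond], sigma=sigma_lm)
            pi_cond = fit.model
            candidates = {
                "pi_only": pi_cond,
                "integration": CombinedModel(fan=pi_cond.fan, ring_pi=pi_cond.ring_pi,
                                             rings_lm=rings, mode="integration"),
                "alternation": CombinedModel(fan=pi_cond.fan, ring_pi=pi_cond.ring_pi,
                                             rings_lm=rings, mode="alternation"),
            }
            if 0 in fits and fits[0].model is not None:
                pi_zero = fits[0].model
                candidates["integration_zero_fit"] = CombinedModel(
                    fan=pi_zero.fan, ring_pi=pi_zero.ring_pi,
                    rings_lm=rings, mode="integration")
            cell = clean[clean["condition"] == cond]
            pts = cell.loc[cell["valid"].astype(bool), ["x", "y"]].to_numpy(float)
            table = compare_models(candidates, pts, resolution=res)
            _write_csv(table, out_dir / f"comparison_{cond}.csv", provenance, index=True)
            manifest[f"comparison_{cond}"] = str(out_dir / f"comparison_{cond}.csv")

            best = table.index[0]
            surface = evaluate_surface(candidates[best], resolution=res)
            _write_csv(surface.to_frame(), out_dir / f"surface_{cond}.csv", provenance)
            manifest[f"surface_{cond}"] = str(out_dir / f"surface_{cond}.csv")
        if 0 in fits and fits[0].model is not None:
            surface = evaluate_surface(fits[0].model, resolution=res)
            _write_csv(surface.to_frame(), out_dir / "surface_0.csv", provenance)
            manifest["surface_0"] = str(out_dir / "surface_0.csv")

        _stage("manifest")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        manifest["manifest"] = str(out_dir / "manifest.json")
    except Exception as exc:
        partial = out_dir / "manifest.partial.json"
        partial.write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed ({exc}); partial manifest at {partial}") from exc
    return manifest
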