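"""Simulated cohort experiments on the steering circuit.

Four protocols mirror the simulated optogenetic/olfactory experiments:

* ``odor``          -- odor pulse gates an (allocentric or frontal) wind bump;
* ``sparse``        -- per-fly random 15% of hDeltaC neurons driven at the
                       high optogenetic power during the light window, the
                       same pattern on every trial of that fly;
* ``broad``         -- all 20 hDeltaC neurons driven uniformly at the low
                       (0.75) or high (2.3) power;
* ``ablation``      -- broad activation with the mutual-inhibition weights
                       set to zero;
* ``control``       -- hDeltaC output clamped to zero (models empty-driver
                       genetic controls); trajectories are purely
                       noise-driven.

Each cohort simulates ``n_flies`` x ``n_trials`` trials in a single batched
integration; per-trial initial headings are uniform random.  A master seed
makes cohorts bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import StimulusSchedule, integrate_batch
from .params import CircuitParams

__all__ = ["ExperimentConfig", "SimCohort", "run_experiment",
           "run_odor_navigation", "run_sparse_activation",
           "run_broad_activation", "run_control_no_hdc"]

_KINDS = ("odor", "frontal_odor", "sparse", "broad", "ablation", "control")


@dataclass
class ExperimentConfig:
    """Protocol description for one simulated cohort."""

    kind: str = "odor"
    n_flies: int = 3
    n_trials: int = 3
    pre_s: float = 5.0
    stim_s: float = 10.0
    post_s: float = 10.0
    wind_direction: float = 0.0
    light_level: str = "high"
    params: CircuitParams = field(default_factory=CircuitParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; "
                             f"choose from {_KINDS}")
        if self.n_flies < 1 or self.n_trials < 1:
            raise ValueError("n_flies and n_trials must be >= 1")
        if min(self.pre_s, self.stim_s, self.post_s) < 0:
            raise ValueError("durations must be >= 0")
        if self.stim_s < self.params.dt:
            raise ValueError("stimulus window shorter than one time step")
        if self.light_level not in ("low", "high"):
            raise ValueError("light_level must be 'low' or 'high'")
        if not np.isfinite(self.wind_direction):
            raise ValueError("invalid wind direction")

    @property
    def duration(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def stim_window(self) -> tuple[float, float]:
        return (self.pre_s, self.pre_s + self.stim_s)


@dataclass
class SimCohort:
    """Simulated trajectories for a cohort of model flies.

    Trajectory arrays have shape ``(n_flies * n_trials, n_samples)`` with
    rows ordered fly-major; ``patterns`` holds the per-fly hDeltaC
    activation vectors (zeros where the protocol uses none).
    """

    config: ExperimentConfig
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    fly: np.ndarray
    trial: np.ndarray
    patterns: np.ndarray
    initial_heading: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.x.shape[0]

    def pattern_is_zero(self, fly: int) -> bool:
        return not np.any(self.patterns[fly] > 0)

    def to_tracks(self) -> pd.DataFrame:
        """Long-format track table compatible with the behavior pipeline.

        The model fly walks where it points, so ``orientation`` is the
        simulated heading.
        """
        n, T = self.x.shape
        return pd.DataFrame({
            "fly": np.repeat(self.fly, T),
            "trial": np.repeat(self.trial, T),
            "condition": self.config.kind,
            "t": np.tile(self.t, n),
            "x": self.x.ravel(),
            "y": self.y.ravel(),
            "orientation": self.heading.ravel(),
        })

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["params"] = self.config.params.to_dict()
        return {
            "config": cfg,
            "patterns": self.patterns.tolist(),
            "initial_heading": self.initial_heading.tolist(),
            "zero_pattern_flies": [int(f) for f in range(self.config.n_flies)
                                   if self.pattern_is_zero(f)],
        }

    def write(self, outdir: str | Path) -> None:
        """One trajectory CSV per fly/trial plus a JSON cohort manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i in range(self.n_runs):
            df = pd.DataFrame({"t": self.t, "x": self.x[i], "y": self.y[i],
                               "heading": self.heading[i], "speed": self.speed[i]})
            df.to_csv(outdir / f"fly{self.fly[i]:03d}_trial{self.trial[i]:03d}.csv",
                      index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def _draw_patterns(config: ExperimentConfig) -> np.ndarray:
    """Per-fly hDeltaC drive patterns for the protocol.

    Sparse patterns are drawn once per fly from a fly-specific seed stream
    and reused across that fly's trials; all-zero draws (probability
    0.85^20, about 4%) are retained, mirroring the variability of
    stochastic genetic labeling.
    """
    p = config.params
    n = config.n_flies
    if config.kind == "sparse":
        out = np.zeros((n, p.n_neurons))
        for f in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1000 + f]))
            out[f] = (rng.random(p.n_neurons) < p.sparse_prob) * p.opto_power_high
        return out
    if config.kind in ("broad", "ablation"):
        level = p.opto_power_low if config.light_level == "low" else p.opto_power_high
        return np.full((n, p.n_neurons), level)
    return np.zeros((n, p.n_neurons))


def run_experiment(config: ExperimentConfig) -> SimCohort:
    """Simulate one cohort under the configured protocol."""
    p = config.params
    if config.kind == "ablation":
        p = p.replace(w_ii=0.0)
    n_runs = config.n_flies * config.n_trials
    fly = np.repeat(np.arange(config.n_flies), config.n_trials)
    trial = np.tile(np.arange(config.n_trials), config.n_flies)

    patterns = _draw_patterns(config)
    run_patterns = patterns[fly]

    is_odor = config.kind in ("odor", "frontal_odor")
    sched = StimulusSchedule.pulse(
        config.duration, p.dt,
        wind_direction=config.wind_direction,
        odor_window=config.stim_window if is_odor else None,
        light_window=None if is_odor or config.kind == "control"
        else config.stim_window,
        opto_pattern=None if is_odor or config.kind == "control" else run_patterns,
        representation="frontal" if config.kind == "frontal_odor" else "allocentric",
        hdc_clamped=config.kind == "control",
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    h0 = rng.uniform(0.0, 360.0, n_runs)
    res = integrate_batch(p, sched, h0, rng)
    return SimCohort(config=config, t=res["t"], x=res["x"], y=res["y"],
                     heading=res["heading"], speed=res["speed"], fly=fly,
                     trial=trial, patterns=patterns, initial_heading=h0)


def run_odor_navigation(config: ExperimentConfig) -> SimCohort:
    """Odor-gated wind-bump navigation (allocentric or frontal encoding)."""
    if config.kind not in ("odor", "frontal_odor"):
        raise ValueError("config.kind must be 'odor' or 'frontal_odor'")
    return run_experiment(config)


def run_sparse_activation(config: ExperimentConfig) -> SimCohort:
    """Sparse (15%) random hDeltaC activation, fly-specific pattern."""
    if config.kind != "sparse":
        raise ValueError("config.kind must be 'sparse'")
    return run_experiment(config)


def run_broad_activation(config: ExperimentConfig) -> SimCohort:
    """Uniform hDeltaC activation at the configured light level."""
    if config.kind not in ("broad", "ablation"):
        raise ValueError("config.kind must be 'broad' or 'ablation'")
    return run_experiment(config)


def run_control_no_hdc(config: ExperimentConfig) -> SimCohort:
    """Empty-driver control: hDeltaC output clamped to zero."""
    if config.kind != "control":
        raise ValueError("config.kind must be 'control'")
    return run_experiment(config)
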