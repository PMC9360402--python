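"""Synthetic test-data generators.

Two generators produce inputs with the statistical structure the analysis
modules assume, so the full pipeline is testable without any recorded
data:

* :func:`gen_tracks` -- 50 Hz walking trajectories in the wind-tunnel
  layout (70 s trials, odor pulse at 30-40 s): a heading random walk with
  Bernoulli turn events; during the odor window the fly intermittently
  snaps into an upwind "surge" state whose occupancy is calibrated so the
  mean upwind drift equals the requested value; after odor OFF the turn
  rate can be multiplied to mimic local search.  These are statistical
  fixtures: heading decorrelation is deliberately fast so windowed means
  are stable at modest cohort sizes (see docs/methods.md).
* :func:`gen_neural` -- per-fly, per-trial scalar responses for the
  five-direction wind/odor protocol (5 blocks of 5 directions), with
  von Mises direction tuning (shared or fly-specific preferred direction,
  or untuned), odor responses stronger than wind responses, per-fly
  response scaling, and Gaussian noise.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neural import DIRECTIONS

__all__ = ["SynthTrackParams", "SynthNeuralParams", "gen_tracks", "gen_neural"]


@dataclass
class SynthTrackParams:
    """Parameters of the synthetic walking-trajectory generator."""

    fs: float = 50.0                 # Hz
    trial_s: float = 70.0            # s
    v_base: float = 6.0              # mm/s groundspeed
    v_jitter: float = 0.5            # mm/s per-frame speed noise
    turn_rate: float = 12.0          # events/s, baseline
    turn_kick_std: float = 90.0      # deg per event
    odor_window: tuple = (30.0, 40.0)
    drift: float = 3.0               # mm/s mean upwind drift during odor
    surge_dwell_s: float = 0.1       # mean dwell of surge/wander states
    surge_heading_std: float = 10.0  # deg, heading spread while surging
    off_window_s: float = 2.0        # s of elevated turning after odor OFF
    off_multiplier: float = 2.0      # turn-rate multiplier after OFF
    arena: dict | None = None        # {"x": (lo, hi), "y": (lo, hi)} or None
    n_flies: int = 20
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.trial_s <= 0:
            raise ValueError("fs and trial_s must be > 0")
        if min(self.turn_rate, self.turn_kick_std, self.off_multiplier) < 0:
            raise ValueError("rates and magnitudes must be >= 0")
        lo, hi = self.odor_window
        if not (0 <= lo <= hi <= self.trial_s):
            raise ValueError("odor window must lie within the trial")
        if not 0 <= self.drift:
            raise ValueError("drift must be >= 0")


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unbounded coordinate into [lo, hi] as if reflected by walls."""
    width = hi - lo
    z = np.mod(pos - lo, 2 * width)
    return lo + np.where(z <= width, z, 2 * width - z)


def gen_tracks(params: SynthTrackParams) -> pd.DataFrame:
    """Generate a cohort of synthetic tracks (long format).

    The surge-state occupancy during odor is ``q = drift / (v_base * c)``
    where ``c = E[cos(heading)]`` in the surge state (analytic for the
    Gaussian surge distribution), so the generated mean upwind velocity
    matches ``drift`` by construction.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.fs
    n = int(round(p.trial_s * p.fs))
    t = np.arange(n) * dt
    odor = (t >= p.odor_window[0]) & (t < p.odor_window[1])
    off = (t >= p.odor_window[1]) & (t < p.odor_window[1] + p.off_window_s)

    # surge occupancy calibrated to the requested drift
    sigma_rad = np.deg2rad(p.surge_heading_std)
    c_surge = np.exp(-sigma_rad**2 / 2.0)
    q = min(1.0, p.drift / (p.v_base * c_surge)) if p.drift > 0 else 0.0
    p_switch = dt / p.surge_dwell_s

    frames = []
    for fly in range(p.n_flies):
        for trial in range(p.n_trials):
            heading = np.empty(n)
            heading[0] = rng.uniform(0, 360)
            # baseline turn events, rate multiplied after odor OFF
            rate = np.full(n, float(p.turn_rate))
            rate[off] *= p.off_multiplier
            events = rng.random(n) < np.minimum(1.0, rate * dt)
            kicks = rng.normal(0.0, p.turn_kick_std, n) * events
            # two-state surge/wander occupancy during odor (Markov renewal:
            # at each switch event the state is redrawn with P(surge) = q)
            idx = np.arange(n)
            switch = rng.random(n) < p_switch
            switch[0] = True
            enter = rng.random(n) < q
            last_sw = np.maximum.accumulate(np.where(switch, idx, 0))
            surging = enter[last_sw] & odor
            surge_headings = rng.normal(0.0, p.surge_heading_std, n)
            # heading = cumulative kicks since the last reset frame.  Surge
            # frames reset heading to a fresh upwind draw; the first wander
            # frame after a surge resets it uniformly, so wander segments
            # contribute zero expected upwind drift by construction.
            wander_start = np.concatenate([[False], surging[:-1]]) & ~surging
            resets = surging | wander_start
            uniform_headings = rng.uniform(0.0, 360.0, n)
            kicks[resets] = 0.0
            ck = np.cumsum(kicks)
            reset_idx = np.maximum.accumulate(np.where(resets, idx, 0))
            reset_val = np.where(surging, surge_headings,
                                 np.where(wander_start, uniform_headings,
                                          heading[0]))
            heading = reset_val[reset_idx] + ck - ck[reset_idx]
            speed = p.v_base + rng.normal(0.0, p.v_jitter, n)
            speed = np.clip(speed, 0.0, None)
            rad = np.deg2rad(heading)
            x = np.concatenate([[0.0], np.cumsum(dt * speed * np.sin(rad))[:-1]])
            y = np.concatenate([[0.0], np.cumsum(dt * speed * np.cos(rad))[:-1]])
            if p.arena is not None:
                (x0, x1), (y0, y1) = p.arena["x"], p.arena["y"]
                x = _reflect(x + rng.uniform(x0, x1), x0, x1)
                y = _reflect(y + rng.uniform(y0, y1), y0, y1)
            frames.append(pd.DataFrame({
                "fly": fly, "trial": trial, "condition": "synthetic",
                "t": t, "x": x, "y": y, "orientation": heading % 360.0}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SynthNeuralParams:
    """Parameters of the synthetic neural-response generator."""

    n_flies: int = 8
    n_blocks: int = 5                # blocks of one trial per direction
    kappa: float = 8.0               # von Mises concentration; 0 = untuned
    mu: float | None = None          # shared preferred direction; None = per fly
    odor_gain: float = 3.0           # response amplitude during odor
    wind_gain: float = 1.5           # response amplitude during wind
    noise_std: float = 1.0
    scale_sigma: float = 0.2         # lognormal sigma of per-fly scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("concentration must be >= 0")
        if self.noise_std <= 0:
            raise ValueError("noise std must be > 0")


def gen_neural(params: SynthNeuralParams) -> pd.DataFrame:
    """Generate a tidy response table for the five-direction protocol.

    Per fly, a preferred direction is drawn uniformly (or fixed at ``mu``);
    tuning is a von Mises curve normalized to peak 1.  Phase amplitudes
    are odor > wind-on = odor-off > wind-off = baseline = 0, all scaled by
    a per-fly lognormal factor, plus Gaussian noise.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    for fly in range(p.n_flies):
        mu = p.mu if p.mu is not None else rng.uniform(-180.0, 180.0)
        scale = float(np.exp(rng.normal(0.0, p.scale_sigma)))
        if p.kappa > 0:
            def tuning(d):
                return np.exp(p.kappa * (np.cos(np.deg2rad(d - mu)) - 1.0))
        else:
            def tuning(d):
                return 1.0
        trial = 0
        for _block in range(p.n_blocks):
            dirs = rng.permutation(DIRECTIONS)
            for d in dirs:
                amp = {"baseline": 0.0,
                       "wind_on": p.wind_gain * tuning(d),
                       "odor": p.odor_gain * tuning(d),
                       "odor_off": p.wind_gain * tuning(d),
                       "wind_off": 0.0}
                for phase, a in amp.items():
                    rows.append({
                        "fly": fly, "trial": trial, "direction": float(d),
                        "phase": phase,
                        "response": scale * a + rng.normal(0.0, p.noise_std)})
                trial += 1
    return pd.DataFrame(rows)
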