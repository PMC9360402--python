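"""Rate-based fan-shaped-body (FB) steering circuit.

The model maps three inputs -- allocentric heading, wind direction, and
odor/optogenetic drive -- onto angular velocity and groundspeed of a
simulated walking fly.  Directions are encoded as one-cycle sinusoidal
activity "bumps" over the FB (0 deg = left edge, 360 deg = right edge):

* heading bumps enter the PFL output populations with anatomical phase
  shifts (left PFL3 -90 deg, right PFL3 +90 deg, PFL2 180 deg);
* an odor-gated wind bump drives 20 hDeltaC local neurons, whose output is
  shifted 180 deg across the FB, projected into 8-column space and
  sigmoid-thresholded, with additive Ornstein-Uhlenbeck noise;
* an 8-neuron mutual-inhibition layer with slow adaptation sharpens the
  column signal (its 180 deg-shifted output is subtracted from the hDeltaC
  output);
* left/right PFL3 sums are compared to set turning, and the PFL2 sum sets
  groundspeed; heading and speed are integrated into an (x, y) trajectory.

Conventions (all angles degrees): heading and wind direction are
allocentric, 0 deg points upwind (+y), increasing toward +x; positive
heading change rotates the fly toward +x.  Egocentric wind is
``wrap(wind_allo - heading)`` in (-180, 180].

Neural state variables relax on millisecond time constants while behavior
is sampled at ``dt`` = 50 ms, so each behavioral step runs ``n_inner``
exponential-Euler substeps of the neural (and heading) dynamics; the
output noise uses the exact Ornstein-Uhlenbeck one-step propagator.  See
docs/methods.md for the numerical scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import CircuitParams, build_w_hdc, build_w_ii

__all__ = [
    "CircuitState",
    "StimulusFrame",
    "StimulusSchedule",
    "Trajectory",
    "sigmoid",
    "phase_shift_180",
    "wrap_angle",
    "heading_input",
    "wind_input_allocentric",
    "wind_input_frontal",
    "hdc_input",
    "hdc_output",
    "ou_noise_step",
    "mutual_inhibition_step",
    "local_output",
    "pfl_step",
    "turn_step",
    "speed_step",
    "integrate",
    "integrate_batch",
]


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def sigmoid(x, theta: float, k: float):
    """Logistic activation 1 / (1 + exp(-(x - theta)/k)).

    ``k`` must be nonzero; non-finite inputs raise, since they indicate a
    diverged circuit state.
    """
    if k == 0:
        raise ValueError("sigmoid slope k must be nonzero")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite input to sigmoid (diverged state?)")
    with np.errstate(over="ignore"):  # saturated tail underflows to 0 or 1
        return 1.0 / (1.0 + np.exp(-(x - theta) / k))


def phase_shift_180(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift a circular activity vector half-way around the FB.

    For an even-length vector this rolls by n/2 indices (10 of 20 for the
    hDeltaC population, 4 of 8 for columns); applying it twice is the
    identity.
    """
    v = np.asarray(v)
    n = v.shape[axis]
    if n % 2:
        raise ValueError("phase_shift_180 requires an even-length axis")
    return np.roll(v, n // 2, axis=axis)


def wrap_angle(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def heading_input(heading, phase_shift: float, fb_locations: np.ndarray) -> np.ndarray:
    """Phase-shifted heading-tuned one-cycle sinusoid, range [0, 2].

    ``cos(fb_loc - (180 - heading + phase_shift)) + 1`` evaluated at the
    given FB locations (degrees); ``heading`` may be scalar or a batch
    vector, in which case the result has shape ``(batch, len(fb_locations))``.
    """
    heading = np.asarray(heading, dtype=float)
    arg = np.deg2rad(fb_locations - (180.0 - heading[..., None] + phase_shift))
    return np.cos(arg) + 1.0


def wind_input_allocentric(wind_direction, fb_locations: np.ndarray) -> np.ndarray:
    """Wind bump that follows the allocentric wind direction (Eq.-style cos+1)."""
    wind_direction = np.asarray(wind_direction, dtype=float)
    arg = np.deg2rad(fb_locations - (180.0 - wind_direction[..., None]))
    return np.cos(arg) + 1.0


def wind_input_frontal(heading, wind_direction, params: CircuitParams,
                       fb_locations: np.ndarray | None = None) -> np.ndarray:
    """Frontal (PFN-based) wind representation.

    Sum of two heading-tuned sinusoids entering with the left/right PFN
    anatomical phase shifts (+/-45 deg), each scaled by the wind tuning of
    that PFN population, ``sin(wind_ego + (90 - peak))``.  Unlike the
    allocentric bump this can be negative (rear wind inverts the scales).
    """
    if fb_locations is None:
        fb_locations = params.neuron_centers
    heading = np.asarray(heading, dtype=float)
    wind_ego = wrap_angle(np.asarray(wind_direction, dtype=float) - heading)
    scale_l = np.sin(np.deg2rad(wind_ego + (90.0 - params.peak_left)))
    scale_r = np.sin(np.deg2rad(wind_ego + (90.0 - params.peak_right)))
    bump_l = np.cos(np.deg2rad(
        fb_locations - (180.0 - heading[..., None] + params.phase_shift_left_pfn)))
    bump_r = np.cos(np.deg2rad(
        fb_locations - (180.0 - heading[..., None] + params.phase_shift_right_pfn)))
    return bump_l * scale_l[..., None] + bump_r * scale_r[..., None]


def hdc_input(wind_bump: np.ndarray, odor_on, opto_pattern: np.ndarray) -> np.ndarray:
    """Total hDeltaC drive: odor-gated wind bump plus optogenetic drive."""
    wind_bump = np.asarray(wind_bump, dtype=float)
    opto_pattern = np.asarray(opto_pattern, dtype=float)
    if wind_bump.shape[-1] != opto_pattern.shape[-1]:
        raise ValueError("wind bump and optogenetic pattern lengths differ")
    gain = np.asarray(odor_on, dtype=float)
    return wind_bump * gain[..., None] + opto_pattern


def hdc_output(hdc_activity: np.ndarray, w_hdc: np.ndarray,
               noise_state: np.ndarray, params: CircuitParams) -> np.ndarray:
    """Columnar hDeltaC output: S(W . phi180(activity)) + noise."""
    shifted = phase_shift_180(np.asarray(hdc_activity, dtype=float))
    col = shifted @ w_hdc.T
    return sigmoid(col, params.theta_hdc, params.k_hdc) + noise_state


def ou_noise_step(n: np.ndarray, params: CircuitParams,
                  rng: np.random.Generator, dt: float | None = None) -> np.ndarray:
    """Advance the filtered-noise state by one behavioral step.

    Uses the exact one-step propagator of the Ornstein-Uhlenbeck process
    ``dn = -n/tau dt + sigma sqrt(2/tau) dW``, so the stationary standard
    deviation equals ``sigma_n`` for any step size (the naive Euler update
    is unstable at dt >> tau_n).
    """
    if dt is None:
        dt = params.dt
    decay = np.exp(-dt / params.tau_n)
    scale = params.sigma_n * np.sqrt(max(0.0, 1.0 - decay * decay))
    return n * decay + scale * rng.standard_normal(np.shape(n))


def mutual_inhibition_step(u: np.ndarray, a: np.ndarray, local_input: np.ndarray,
                           params: CircuitParams, w_ii: np.ndarray | None = None,
                           dt: float | None = None):
    """One substep of the mutual-inhibition / adaptation dynamics.

    ``tau_u du/dt = -u + S_mi(-W_ii u - g a + input)`` and
    ``tau_a da/dt = -a + u``, advanced synchronously by ``dt`` (default the
    inner substep) with exponential-Euler updates, which remain stable for
    any step-to-time-constant ratio.
    """
    if w_ii is None:
        w_ii = build_w_ii(params)
    if dt is None:
        dt = params.dt_inner
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    target = sigmoid(-(u @ w_ii.T) - params.g_adapt * a + local_input,
                     params.theta_mi, params.k_mi)
    eu = np.exp(-dt / params.tau_u)
    ea = np.exp(-dt / params.tau_a)
    u_new = target + (u - target) * eu
    a_new = u + (a - u) * ea
    return u_new, a_new


def local_output(hdc_out: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Total local-neuron output to PFL: hDeltaC output minus shifted inhibition."""
    return np.asarray(hdc_out, dtype=float) - phase_shift_180(np.asarray(u, dtype=float))


def pfl_step(pfl: np.ndarray, heading, phase_shift: float, local_out: np.ndarray,
             params: CircuitParams, dt: float | None = None) -> np.ndarray:
    """One substep of a PFL population: relax toward S_pfl(heading bump + local)."""
    if dt is None:
        dt = params.dt_inner
    inp = heading_input(heading, phase_shift, params.column_centers) + local_out
    target = sigmoid(inp, params.theta_pfl, params.k_pfl)
    return target + (np.asarray(pfl, dtype=float) - target) * np.exp(-dt / params.tau_pfl)


def turn_step(pfl3_left: np.ndarray, pfl3_right: np.ndarray, params: CircuitParams,
              rng: np.random.Generator):
    """Heading change (deg) over one behavioral step for frozen PFL3 activity.

    Deterministic steering ``m1 (sum right - sum left)`` (with ``m1``
    converted from its reference sampling rate to deg per behavioral step)
    plus a Bernoulli(lambda) spontaneous-turn event whose realized turn
    angle is drawn from N(0, sigma_turn^2).
    """
    l = np.asarray(pfl3_left, dtype=float).sum(axis=-1)
    r = np.asarray(pfl3_right, dtype=float).sum(axis=-1)
    m1_step = params.m1 * params.rate_reference_hz * params.dt
    det = m1_step * (r - l)
    event = rng.random(np.shape(det)) < params.p_turn
    kick = params.sigma_turn * rng.standard_normal(np.shape(det))
    return det + np.where(event, kick, 0.0)


def speed_step(pfl2: np.ndarray, params: CircuitParams):
    """Groundspeed in mm/s: v_base + m2 * sum(PFL2)."""
    return params.v_base + params.m2 * np.asarray(pfl2, dtype=float).sum(axis=-1)


# --------------------------------------------------------------------------
# state, stimulus, trajectory containers
# --------------------------------------------------------------------------

@dataclass
class CircuitState:
    """Instantaneous circuit activities plus agent pose.

    Activity arrays may carry a leading batch axis for cohort simulations.
    """

    u: np.ndarray
    a: np.ndarray
    n: np.ndarray
    pfl3_left: np.ndarray
    pfl3_right: np.ndarray
    pfl2: np.ndarray
    heading: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, params: CircuitParams, heading=0.0, batch: int | None = None
                ) -> "CircuitState":
        shape = (params.n_columns,) if batch is None else (batch, params.n_columns)
        z = lambda: np.zeros(shape)
        b = () if batch is None else (batch,)
        heading = np.broadcast_to(np.asarray(heading, dtype=float), b).copy()
        return cls(u=z(), a=z(), n=z(), pfl3_left=z(), pfl3_right=z(), pfl2=z(),
                   heading=heading % 360.0, x=np.zeros(b), y=np.zeros(b),
                   speed=np.full(b, params.v_base), t=0.0)

    def validate(self) -> None:
        for name in ("u", "a", "n", "pfl3_left", "pfl3_right", "pfl2",
                     "heading", "x", "y", "speed"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite circuit state in '{name}'")


@dataclass
class StimulusFrame:
    """Stimulus at one behavioral step: wind direction, odor gate, opto drive."""

    wind_direction_allo: float = 0.0
    odor_on: bool = False
    opto_pattern: np.ndarray | None = None

    def pattern(self, n_neurons: int) -> np.ndarray:
        if self.opto_pattern is None:
            return np.zeros(n_neurons)
        p = np.asarray(self.opto_pattern, dtype=float)
        if p.shape != (n_neurons,):
            raise ValueError("opto_pattern length must equal n_neurons")
        if np.any(p < 0):
            raise ValueError("opto_pattern values must be >= 0")
        return p


@dataclass
class StimulusSchedule:
    """Vectorised stimulus protocol for a (batched) simulation.

    ``odor_on`` and ``light_on`` are per-step booleans of length
    ``n_steps``; ``opto_pattern`` is the drive applied while the light is
    on (per run when 2-D); ``wind_direction`` may be scalar or per-run.
    """

    n_steps: int
    wind_direction: np.ndarray | float = 0.0
    odor_on: np.ndarray | None = None
    light_on: np.ndarray | None = None
    opto_pattern: np.ndarray | None = None
    representation: str = "allocentric"
    hdc_clamped: bool = False

    def __post_init__(self) -> None:
        if self.representation not in ("allocentric", "frontal"):
            raise ValueError("representation must be 'allocentric' or 'frontal'")
        for name in ("odor_on", "light_on"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros(self.n_steps, dtype=bool)
            else:
                v = np.asarray(v, dtype=bool)
                if v.shape != (self.n_steps,):
                    raise ValueError(f"{name} must have length n_steps")
            setattr(self, name, v)

    @classmethod
    def from_frames(cls, frames: Sequence[StimulusFrame], n_neurons: int
                    ) -> "StimulusSchedule":
        """Build a schedule from a per-step sequence of :class:`StimulusFrame`."""
        n = len(frames)
        wind = np.array([f.wind_direction_allo for f in frames], dtype=float)
        if not np.all(np.isfinite(wind)):
            raise ValueError("non-finite wind direction in stimulus")
        odor = np.array([f.odor_on for f in frames], dtype=bool)
        pats = np.stack([f.pattern(n_neurons) for f in frames])
        sched = cls(n_steps=n, wind_direction=float(wind[0]), odor_on=odor,
                    light_on=np.any(pats > 0, axis=1))
        sched._per_step_pattern = pats  # type: ignore[attr-defined]
        sched._per_step_wind = wind  # type: ignore[attr-defined]
        return sched

    @classmethod
    def pulse(cls, duration: float, dt: float, wind_direction=0.0,
              odor_window: tuple[float, float] | None = None,
              light_window: tuple[float, float] | None = None,
              opto_pattern: np.ndarray | None = None,
              representation: str = "allocentric",
              hdc_clamped: bool = False) -> "StimulusSchedule":
        """Constant wind with optional odor and/or light pulses."""
        n = int(round(duration / dt))
        t = np.arange(n) * dt
        odor = np.zeros(n, dtype=bool)
        light = np.zeros(n, dtype=bool)
        if odor_window is not None:
            odor = (t >= odor_window[0]) & (t < odor_window[1])
        if light_window is not None:
            light = (t >= light_window[0]) & (t < light_window[1])
        return cls(n_steps=n, wind_direction=wind_direction, odor_on=odor,
                   light_on=light, opto_pattern=opto_pattern,
                   representation=representation, hdc_clamped=hdc_clamped)


@dataclass
class Trajectory:
    """Uniformly sampled pose series (t, x, y, heading, speed)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y,
                             "heading": self.heading, "speed": self.speed})

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


# --------------------------------------------------------------------------
# integration engine
# --------------------------------------------------------------------------

def integrate_batch(params: CircuitParams, schedule: StimulusSchedule,
                    initial_heading, rng: np.random.Generator,
                    record_activity: bool = False) -> dict:
    """Run a batch of circuit simulations under a shared stimulus schedule.

    Per behavioral step, in order: pose update (x += dt v sin h,
    y += dt v cos h using the current state), exact OU noise update,
    stimulus assembly, ``n_inner`` substeps of the hDeltaC -> mutual
    inhibition -> local output -> PFL -> heading loop, the spontaneous-turn
    event, and the PFL2 speed readout.  Returns arrays of shape
    ``(batch, n_steps + 1)`` for x, y, heading, speed.

    Random-draw order per step (one seeded generator for the whole batch):
    noise normals ``(batch, n_columns)``, event uniforms ``(batch,)``,
    turn-angle normals ``(batch,)``.
    """
    heading = np.atleast_1d(np.asarray(initial_heading, dtype=float)) % 360.0
    B = heading.shape[0]
    C, N = params.n_columns, params.n_neurons
    T = schedule.n_steps
    w_hdc = build_w_hdc(N, C)
    w_ii = build_w_ii(params)
    cols = params.column_centers
    neur = params.neuron_centers

    pattern = schedule.opto_pattern
    if pattern is None:
        pattern = np.zeros((B, N))
    else:
        pattern = np.asarray(pattern, dtype=float)
        if pattern.ndim == 1:
            pattern = np.broadcast_to(pattern, (B, N))
        if np.any(pattern < 0):
            raise ValueError("opto_pattern values must be >= 0")
    wind = np.broadcast_to(np.asarray(schedule.wind_direction, dtype=float), (B,))
    per_step_pattern = getattr(schedule, "_per_step_pattern", None)
    per_step_wind = getattr(schedule, "_per_step_wind", None)

    u = np.zeros((B, C)); a = np.zeros((B, C)); noise = np.zeros((B, C))
    pfl3l = np.zeros((B, C)); pfl3r = np.zeros((B, C)); pfl2 = np.zeros((B, C))

    x = np.zeros(B); y = np.zeros(B)
    v = np.full(B, params.v_base)

    out_x = np.empty((B, T + 1)); out_y = np.empty((B, T + 1))
    out_h = np.empty((B, T + 1)); out_v = np.empty((B, T + 1))
    out_x[:, 0], out_y[:, 0], out_h[:, 0], out_v[:, 0] = x, y, heading, v
    act_rec = [] if record_activity else None

    dt, dti, n_inner = params.dt, params.dt_inner, params.n_inner
    eu = np.exp(-dti / params.tau_u)
    ea = np.exp(-dti / params.tau_a)
    ep = np.exp(-dti / params.tau_pfl)
    decay_n = np.exp(-dt / params.tau_n)
    scale_n = params.sigma_n * np.sqrt(max(0.0, 1.0 - decay_n * decay_n))
    m1i = params.m1_inner
    p_turn = params.p_turn
    rad = np.pi / 180.0
    sh_l, sh_r, sh_2 = (params.phase_shift_left_pfl3, params.phase_shift_right_pfl3,
                        params.phase_shift_pfl2)
    allo = schedule.representation == "allocentric"
    # the allocentric wind bump never depends on heading: precompute
    wind_bump_allo = wind_input_allocentric(wind, neur) if allo else None

    for step in range(T):
        # Eq-13-style pose update with the current heading and speed
        x = x + dt * v * np.sin(heading * rad)
        y = y + dt * v * np.cos(heading * rad)

        noise = noise * decay_n + scale_n * rng.standard_normal((B, C))
        odor = float(schedule.odor_on[step])
        if per_step_pattern is not None:
            opto = np.broadcast_to(per_step_pattern[step], (B, N))
            wind_step = np.broadcast_to(per_step_wind[step], (B,))
        else:
            opto = pattern * float(schedule.light_on[step])
            wind_step = wind

        if allo:
            if per_step_pattern is not None:
                bump = wind_input_allocentric(wind_step, neur)
            else:
                bump = wind_bump_allo
            act = bump * odor + opto
            col = phase_shift_180(act) @ w_hdc.T
            hout = sigmoid(col, params.theta_hdc, params.k_hdc) + noise
            if schedule.hdc_clamped:
                hout = np.zeros((B, C))

        for _ in range(n_inner):
            if not allo:
                bump = wind_input_frontal(heading, wind_step, params, neur)
                act = bump * odor + opto
                col = phase_shift_180(act) @ w_hdc.T
                hout = sigmoid(col, params.theta_hdc, params.k_hdc) + noise
                if schedule.hdc_clamped:
                    hout = np.zeros((B, C))
            tgt = sigmoid(-(u @ w_ii.T) - params.g_adapt * a + hout,
                          params.theta_mi, params.k_mi)
            u_new = tgt + (u - tgt) * eu
            a = u + (a - u) * ea
            u = u_new
            local = hout - phase_shift_180(u)
            hb = 180.0 - heading[:, None]
            pfl3l = _relax(pfl3l, np.cos((cols - (hb + sh_l)) * rad) + 1.0 + local,
                           params, ep)
            pfl3r = _relax(pfl3r, np.cos((cols - (hb + sh_r)) * rad) + 1.0 + local,
                           params, ep)
            pfl2 = _relax(pfl2, np.cos((cols - (hb + sh_2)) * rad) + 1.0 + local,
                          params, ep)
            heading = heading + m1i * (pfl3r.sum(axis=1) - pfl3l.sum(axis=1))

        event = rng.random(B) < p_turn
        kick = params.sigma_turn * rng.standard_normal(B)
        heading = (heading + np.where(event, kick, 0.0)) % 360.0
        v = params.v_base + params.m2 * pfl2.sum(axis=1)

        out_x[:, step + 1], out_y[:, step + 1] = x, y
        out_h[:, step + 1], out_v[:, step + 1] = heading, v
        if record_activity:
            act_rec.append({"u": u.copy(), "a": a.copy(), "hdc_out": hout.copy(),
                            "pfl3_left": pfl3l.copy(), "pfl3_right": pfl3r.copy(),
                            "pfl2": pfl2.copy()})

    for name, arr in (("x", out_x), ("y", out_y), ("heading", out_h),
                      ("speed", out_v)):
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FloatingPointError(
                f"non-finite {name} at run {bad[0]}, step {bad[1]}")

    t = np.arange(T + 1) * dt
    out = {"t": t, "x": out_x, "y": out_y, "heading": out_h, "speed": out_v,
           "state": CircuitState(u=u, a=a, n=noise, pfl3_left=pfl3l,
                                 pfl3_right=pfl3r, pfl2=pfl2, heading=heading,
                                 x=x, y=y, speed=v, t=float(t[-1]))}
    if record_activity:
        out["activity"] = act_rec
    return out


def _relax(pfl, inp, params, decay):
    tgt = sigmoid(inp, params.theta_pfl, params.k_pfl)
    return tgt + (pfl - tgt) * decay


def integrate(state: CircuitState, stimulus, params: CircuitParams,
              rng: np.random.Generator) -> Trajectory:
    """Integrate a single simulated fly and return its :class:`Trajectory`.

    ``stimulus`` is either a :class:`StimulusSchedule` or a sequence of
    per-step :class:`StimulusFrame` objects.  The starting pose is taken
    from ``state`` (internal activities are initialized at zero; use
    :func:`integrate_batch` for finer control or cohort runs).
    """
    state.validate()
    if not isinstance(stimulus, StimulusSchedule):
        stimulus = StimulusSchedule.from_frames(list(stimulus), params.n_neurons)
    res = integrate_batch(params, stimulus, np.atleast_1d(state.heading), rng)
    traj = Trajectory(t=res["t"], x=res["x"][0] + float(np.atleast_1d(state.x)[0]),
                      y=res["y"][0] + float(np.atleast_1d(state.y)[0]),
                      heading=res["heading"][0], speed=res["speed"][0],
                      meta={"params": params.to_dict()})
    return traj
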