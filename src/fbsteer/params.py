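"""Parameters of the fan-shaped-body steering circuit.

:class:`CircuitParams` is the single source of truth for every constant in
the rate model: anatomical phase shifts of the PFL and PFN populations,
sigmoid slopes and thresholds of the three nonlinear layers, the
mutual-inhibition weights and adaptation, noise, and the motor couplings
that turn population activity into angular velocity and groundspeed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["CircuitParams", "build_w_ii", "build_w_hdc"]


@dataclass
class CircuitParams:
    """All steering-circuit constants plus integration settings.

    Angles are in degrees, times in seconds, positions in mm.  Activity is
    dimensionless (sigmoid output, bounded in (0, 1)).  The defaults are the
    published parameter set of the model; ``rate_reference_hz`` records the
    sampling rate at which the motor-coupling constant ``m1`` and the turn
    event rate ``lambda_turn`` are quoted (see notes in docs/methods.md on
    rate-unit reconciliation).
    """

    # anatomical phase shifts of output/input populations entering the FB
    phase_shift_left_pfl3: float = -90.0
    phase_shift_right_pfl3: float = 90.0
    phase_shift_pfl2: float = 180.0
    phase_shift_left_pfn: float = 45.0
    phase_shift_right_pfn: float = -45.0
    # egocentric wind direction maximally activating each PFN population
    peak_left: float = -45.0
    peak_right: float = 45.0
    # optogenetic drive levels (activity units) and sparse labeling probability
    opto_power_low: float = 0.75
    opto_power_high: float = 2.3
    sparse_prob: float = 0.15
    # hDeltaC sigmoid
    k_hdc: float = 0.1
    theta_hdc: float = 0.7
    # exponentially filtered (Ornstein-Uhlenbeck) output noise
    tau_n: float = 0.010
    sigma_n: float = 0.03
    # mutual inhibition layer
    w_ii: float = 1.1
    g_adapt: float = 0.5
    tau_u: float = 0.001
    tau_a: float = 0.100
    # Threshold sign convention: the default keeps the mutual-inhibition layer
    # subthreshold (quiescent) at rest, which is required for calm baseline
    # walking and light-driven turning; see docs/methods.md.
    k_mi: float = 0.1
    theta_mi: float = 0.15
    # PFL output layer
    tau_pfl: float = 0.001
    k_pfl: float = 0.1
    theta_pfl: float = 1.7
    # motor couplings and baseline random turning
    lambda_turn: float = 0.0003
    sigma_turn: float = 20.0
    m1: float = 0.03
    v_base: float = 6.0
    m2: float = 0.25
    # integration
    dt: float = 0.05
    dt_inner: float = 0.001
    rate_reference_hz: float = 20000.0
    n_neurons: int = 20
    n_columns: int = 8

    def __post_init__(self) -> None:
        for name in ("tau_n", "tau_u", "tau_a", "tau_pfl", "dt", "dt_inner"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.sparse_prob <= 1.0:
            raise ValueError("sparse_prob must lie in [0, 1]")
        if self.sigma_n < 0 or self.sigma_turn < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.n_columns < 2 or self.n_columns % 2:
            raise ValueError("n_columns must be even and >= 2")
        if self.n_neurons < self.n_columns:
            raise ValueError("n_neurons must be >= n_columns")

    # ---- derived geometry -------------------------------------------------
    @property
    def column_centers(self) -> np.ndarray:
        """FB column centers in degrees, (k + 1/2) * 360 / n_columns."""
        w = 360.0 / self.n_columns
        return (np.arange(self.n_columns) + 0.5) * w

    @property
    def neuron_centers(self) -> np.ndarray:
        """hDeltaC neuron positions in degrees, (j + 1/2) * 360 / n_neurons."""
        w = 360.0 / self.n_neurons
        return (np.arange(self.n_neurons) + 0.5) * w

    @property
    def n_inner(self) -> int:
        """Number of neural-dynamics substeps per behavioral step."""
        return max(1, round(self.dt / self.dt_inner))

    @property
    def m1_inner(self) -> float:
        """Steering gain in deg per inner substep per unit activity."""
        return self.m1 * self.rate_reference_hz * self.dt_inner

    @property
    def p_turn(self) -> float:
        """Per-behavioral-step probability of a spontaneous turn event."""
        return min(1.0, self.lambda_turn * self.rate_reference_hz * self.dt)

    # ---- (de)serialisation ------------------------------------------------
    def replace(self, **kwargs) -> "CircuitParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown circuit parameters: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CircuitParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_w_ii(params: CircuitParams) -> np.ndarray:
    """Mutual-inhibition weight matrix: columns i and i + n/2 inhibit each other.

    Symmetric, zero diagonal, nonzero (= ``w_ii``) only between opposite
    columns.
    """
    n = params.n_columns
    w = np.zeros((n, n))
    idx = np.arange(n)
    w[idx, (idx + n // 2) % n] = params.w_ii
    return w


def build_w_hdc(n_neurons: int = 20, n_columns: int = 8) -> np.ndarray:
    """Feedforward transform from neuron space to FB column space.

    Each neuron's output footprint is one column wide (360/n_columns deg),
    centered at the neuron's FB position.  Element (i, j) is the fraction of
    overlap between column i's span and neuron j's footprint; each row is
    normalized so the total input to a column is 1.
    """
    if n_neurons < n_columns:
        raise ValueError("n_neurons must be >= n_columns")
    col_w = 360.0 / n_columns
    half = col_w / 2.0
    centers = (np.arange(n_neurons) + 0.5) * (360.0 / n_neurons)
    w = np.zeros((n_columns, n_neurons))
    for i in range(n_columns):
        lo_i, hi_i = i * col_w, (i + 1) * col_w
        for j in range(n_neurons):
            # circular overlap of [c-half, c+half) with [lo_i, hi_i)
            total = 0.0
            for shift in (-360.0, 0.0, 360.0):
                lo_j = centers[j] - half + shift
                hi_j = centers[j] + half + shift
                total += max(0.0, min(hi_i, hi_j) - max(lo_i, lo_j))
            w[i, j] = total
    w /= w.sum(axis=1, keepdims=True)
    return w
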