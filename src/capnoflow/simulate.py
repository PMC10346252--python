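"""Forward (direct) simulation of the discrete transport model.

The semi-discrete system dc/dt = F·c + G·q is integrated with an implicit
Euler scheme: (I − δt·F)·c_{k+1} = c_k + δt·G·q_{k+1}.  Since every
eigenvalue of F has non-positive real part, the inverse of A = I − δt·F is
contractive and the scheme is unconditionally stable.  The scalar NDIR
observation is y_k = hᵀ·c_k + v_k with seeded Gaussian noise added only to
the observation, never to the states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .grid import GridModel
from .params import ModelParams, pressure_to_concentration

__all__ = [
    "InputSignal",
    "Trajectory",
    "InvalidInputError",
    "InvalidChronogramError",
    "make_step_input",
    "make_chronogram",
    "step_implicit",
    "simulate_direct",
]


class InvalidInputError(ValueError):
    """Malformed input signal or mismatched sampling."""


class InvalidChronogramError(InvalidInputError):
    """Chronogram phases overlap or leave gaps."""


@dataclass(frozen=True)
class InputSignal:
    """Blood-inlet boundary concentration sampled on a uniform time grid."""

    times: np.ndarray       # s
    values: np.ndarray      # mol·m-3
    dt: float               # s
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise InvalidInputError("times and values must have equal length")
        if np.any(np.asarray(self.values) < 0):
            raise InvalidInputError("boundary concentrations must be non-negative")
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed state history with the scalar NDIR observation series."""

    times: np.ndarray                 # s
    states: np.ndarray                # (n_steps, N), mol·m-3
    observations: np.ndarray          # (n_steps,), mol·m-3 (noise included)
    dt: float                         # s
    noise_variance: float = 0.0       # (mol·m-3)^2
    noise_seed: int | None = None
    inputs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.states) == len(self.observations)):
            raise InvalidInputError("trajectory arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_start: float, t_stop: float) -> "Trajectory":
        """Sub-trajectory with t_start ≤ t < t_stop (e.g. to trim initialization)."""
        m = (self.times >= t_start) & (self.times < t_stop)
        return replace(
            self,
            times=self.times[m],
            states=self.states[m],
            observations=self.observations[m],
            inputs=None if self.inputs is None else self.inputs[m],
        )

    # -- plain-text round trip ----------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write (time, c_1..c_N, y) CSV plus a JSON sidecar with metadata."""
        path = Path(path)
        n = self.states.shape[1]
        header = "time_s," + ",".join(f"c_{i+1}" for i in range(n)) + ",y"
        cols = [self.times, self.states, self.observations[:, None]]
        if self.inputs is not None:
            header += ",q_blood"
            cols.append(self.inputs[:, None])
        body = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.17g")
        sidecar = {
            "dt": self.dt,
            "noise_variance": self.noise_variance,
            "noise_seed": self.noise_seed,
            "n_states": n,
            "has_inputs": self.inputs is not None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Trajectory":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        n = meta["n_states"]
        return cls(
            times=data[:, 0],
            states=data[:, 1 : 1 + n],
            observations=data[:, 1 + n],
            dt=meta["dt"],
            noise_variance=meta["noise_variance"],
            noise_seed=meta["noise_seed"],
            inputs=data[:, 2 + n] if meta["has_inputs"] else None,
        )


# ---------------------------------------------------------------------------
# input signals
# ---------------------------------------------------------------------------

def make_step_input(
    P_low: float,
    P_high: float,
    t_init: float,
    t_total: float,
    dt: float = 1.0,
    params: ModelParams | None = None,
) -> InputSignal:
    """Step transition between two capnia levels given as blood pressures.

    Constant at the concentration equivalent of ``P_low`` for t < t_init, then
    at the ``P_high`` level until ``t_total``.  The default parameters map
    40 mmHg to ~1.099 mol·m⁻³ (normocapnia) and 50 mmHg to ~1.373 mol·m⁻³
    (hypercapnia).
    """
    if P_low < 0 or P_high < 0:
        raise InvalidInputError("pressures must be non-negative")
    if not t_init < t_total:
        raise InvalidInputError("need t_init < t_total")
    p = params if params is not None else ModelParams()
    c_low = pressure_to_concentration(P_low, p.beta_blood)
    c_high = pressure_to_concentration(P_high, p.beta_blood)
    times = np.arange(0.0, t_total, dt)
    values = np.where(times < t_init, c_low, c_high)
    return InputSignal(times=times, values=values, dt=dt, label="step")


def make_chronogram(
    phases: Sequence[tuple[float, float, float]],
    dt: float = 1.0,
) -> InputSignal:
    """Piecewise-constant capnia chronogram from (start s, duration s, level) rows.

    Phases must be contiguous and non-overlapping; the signal spans from the
    first phase start to the end of the last phase.
    """
    if not phases:
        raise InvalidChronogramError("empty chronogram")
    phases = sorted(phases, key=lambda p: p[0])
    for (s0, d0, _), (s1, _, _) in zip(phases, phases[1:]):
        if abs((s0 + d0) - s1) > 1e-9:
            raise InvalidChronogramError(
                f"phase starting at {s1} s is not contiguous with previous end {s0 + d0} s"
            )
    t0 = phases[0][0]
    t_end = phases[-1][0] + phases[-1][1]
    times = np.arange(t0, t_end, dt)
    values = np.empty_like(times)
    for start, duration, level in phases:
        if level < 0:
            raise InvalidChronogramError("capnia levels must be non-negative")
        values[(times >= start) & (times < start + duration)] = level
    return InputSignal(times=times, values=values, dt=dt, label="chronogram")


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def step_implicit(
    c_k: np.ndarray,
    q_next: np.ndarray,
    lu: tuple,
    G: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One implicit-Euler step: solve (I − δt·F)·c_{k+1} = c_k + δt·G·q_{k+1}.

    ``lu`` is the precomputed LU factorization of A = I − δt·F.
    """
    return lu_solve(lu, c_k + dt * (G @ q_next))


def simulate_direct(
    grid: GridModel,
    input_signal: InputSignal,
    dt: float | None = None,
    noise_variance: float = 0.0,
    seed: int | None = None,
    c0: np.ndarray | None = None,
    c_inlet: float = 0.0,
) -> Trajectory:
    """Integrate the direct problem over the input signal's time support.

    The state starts at ``c0`` (zero by default, giving the initialization
    transient visible before the profile settles at the first capnia level).
    ``c_inlet`` is the collection-cell fresh-air inlet concentration (zero
    when an inlet CO2 filter is assumed).  Observation noise with variance
    ``noise_variance`` is drawn from a generator seeded with ``seed``.
    """
    if dt is None:
        dt = input_signal.dt
    if abs(dt - input_signal.dt) > 1e-12:
        raise InvalidInputError(
            f"time step {dt} does not match the input signal's {input_signal.dt}"
        )
    n = grid.n_states
    A = np.eye(n) - dt * grid.F
    lu = lu_factor(A)

    n_steps = len(input_signal)
    states = np.empty((n_steps, n))
    c = np.zeros(n) if c0 is None else np.asarray(c0, dtype=float).copy()
    q = np.array([0.0, c_inlet])
    for k in range(n_steps):
        q[0] = input_signal.values[k]
        c = step_implicit(c, q, lu, grid.G, dt)
        states[k] = c

    y = states[:, grid.h_index].copy()
    if noise_variance > 0.0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, np.sqrt(noise_variance), size=n_steps)

    return Trajectory(
        times=input_signal.times.copy(),
        states=states,
        observations=y,
        dt=dt,
        noise_variance=noise_variance,
        noise_seed=seed,
        inputs=input_signal.values.copy(),
    )
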