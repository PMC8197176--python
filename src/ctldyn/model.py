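"""Five-state ODE model of tumour/CTL dynamics after adoptive cell transfer.

The model tracks proliferating tumour cells ``T_p``, quiescent tumour cells
``T_q``, intratumoural cytotoxic T lymphocytes (CTLs) ``E``, an auto-inductive
stimulus ``I`` driving CTL mitosis, and a tumour resistance factor ``R``
driving CTL apoptosis.  With ``T = T_p + T_q`` the dynamics are

    dT_p/dt = g*T_p - (k_e + k_q) * (T_p/T) * E + d_q*T_q
    dT_q/dt = k_q * (T_p/T) * E - k_e * (T_q/T) * E - d_q*T_q
    dE/dt   = s * T**(2/3) + E * (I - R)
    dI/dt   = k_i * E/T - d_i * I
    dR/dt   = k_r * E/T - d_r * R

Killing is shared between proliferating and quiescent cells in proportion to
their fraction of the tumour, so the total tumour population obeys
``d(T_p+T_q)/dt = g*T_p - k_e*E`` exactly.  CTLs infiltrate across the tumour
boundary (approximately spherical, hence the 2/3 power) at constant rate ``s``
per unit area; ``s`` is zero before the day of adoptive transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import warnings

import numpy as np
import yaml
from scipy.integrate import ODEintWarning, odeint

__all__ = [
    "ModelParameters",
    "ModelState",
    "Trajectory",
    "IntegrationError",
    "derivatives",
    "simulate",
    "default_initial_state",
    "load_params",
    "save_params",
]

# rate-constant fields, in serialisation order
_RATE_NAMES = ("g", "s", "k_e", "k_i", "d_i", "k_r", "d_r", "k_q", "d_q")

# below one cell the denominators of the per-capita terms E/T and T_x/T are
# clamped to one cell, so the terms go to zero continuously as the tumour
# vanishes: the model is only meant for regimes where tumour cells are
# frequent, and the clamp removes the T -> 0 singularity without introducing
# a discontinuous right-hand side (a hard cut-off makes adaptive steppers
# chatter when trajectories hover at the threshold).
_T_FLOOR = 1.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to meet its tolerances."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and treatment schedule.

    Units: ``g, k_i, d_i, k_r, d_r, d_q`` in day^-1; ``k_e, k_q`` in
    CTL^-1 day^-1; ``s`` in TC^-2/3 day^-1; ``transfer_day`` in days after
    tumour inoculation.  ``d_r`` is fixed to 0 by default (resistance does
    not measurably decay on the 15-day timescale of the experiments).
    """

    g: float = 0.5
    s: float = 0.0
    k_e: float = 0.0
    k_i: float = 0.0
    d_i: float = 0.0
    k_r: float = 0.0
    d_r: float = 0.0
    k_q: float = 0.0
    d_q: float = 0.0
    transfer_day: float = 3.0

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        if not np.isfinite(self.transfer_day) or self.transfer_day < 0:
            raise ValueError(f"transfer_day must be finite and >= 0, got {self.transfer_day}")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in _RATE_NAMES}
        d["transfer_day"] = float(self.transfer_day)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ModelState:
    """State (T_p, T_q, E, I, R) at one time point.

    ``I`` and ``R`` have units of events CTL^-1 day^-1; the cell
    compartments are absolute counts.
    """

    T_p: float
    T_q: float = 0.0
    E: float = 0.0
    I: float = 0.0
    R: float = 0.0

    def __post_init__(self) -> None:
        for name in ("T_p", "T_q", "E", "I", "R"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"state component {name} must be finite and >= 0, got {value}")

    @property
    def T(self) -> float:
        """Total tumour cells, T_p + T_q."""
        return self.T_p + self.T_q

    def as_array(self) -> np.ndarray:
        return np.array([self.T_p, self.T_q, self.E, self.I, self.R], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)  # floor solver round-off
        return cls(*y)


def default_initial_state() -> ModelState:
    """Day-0 initial conditions: 1200 tumour cells, no CTLs, no I or R."""
    return ModelState(T_p=1200.0, T_q=0.0, E=0.0, I=0.0, R=0.0)


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: states on a strictly increasing day grid."""

    times: np.ndarray          # shape (n,), days
    states: np.ndarray         # shape (n, 5), columns T_p, T_q, E, I, R
    params: ModelParameters

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0) and times.size > 1:
            raise ValueError("times must be a strictly increasing 1-D grid")
        if states.shape != (times.size, 5):
            raise ValueError("states must have shape (len(times), 5)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def T_p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def T_q(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 4]

    def state_at(self, day: float) -> ModelState:
        """State at ``day``, linearly interpolated between grid points.

        Raises ``ValueError`` outside the simulated span.
        """
        if day < self.times[0] - 1e-9 or day > self.times[-1] + 1e-9:
            raise ValueError(
                f"day {day} outside trajectory span [{self.times[0]}, {self.times[-1]}]"
            )
        y = np.array([np.interp(day, self.times, self.states[:, j]) for j in range(5)])
        return ModelState.from_array(y)


def _rhs(t: float, y, p: ModelParameters, s_active: bool):
    T_p, T_q, E, I, R = y
    T = T_p + T_q
    denom = T if T >= _T_FLOOR else _T_FLOOR
    frac_p = T_p / denom
    frac_q = T_q / denom
    per_capita = E / denom
    quiesce = p.k_q * frac_p * E
    recover = p.d_q * T_q
    dT_p = p.g * T_p - (p.k_e + p.k_q) * frac_p * E + recover
    dT_q = quiesce - p.k_e * frac_q * E - recover
    s = p.s if s_active else 0.0
    dE = s * (T if T > 0.0 else 0.0) ** (2.0 / 3.0) + E * (I - R)
    dI = p.k_i * per_capita - p.d_i * I
    dR = p.k_r * per_capita - p.d_r * R
    return [dT_p, dT_q, dE, dI, dR]


def derivatives(state: ModelState, params: ModelParameters, t: float) -> np.ndarray:
    """Time derivative (dT_p, dT_q, dE, dI, dR) at ``state`` and time ``t``.

    The infiltration term is active only for ``t >= transfer_day``.
    """
    if not isinstance(state, ModelState):
        state = ModelState(*np.asarray(state, dtype=float))
    return np.array(_rhs(t, state.as_array(), params, s_active=t >= params.transfer_day))


def simulate(
    params: ModelParameters,
    t_grid: Sequence[float],
    init: ModelState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    state_cap: float = 1e12,
    mxstep: int = 10_000,
) -> Trajectory:
    """Integrate the model over ``t_grid`` (days, strictly increasing).

    Uses the adaptive, stiffness-switching LSODA solver.  The integration is
    split at ``transfer_day`` and the solver restarted there, so the step
    change in the infiltration rate ``s`` is handled exactly rather than
    smeared by the adaptive stepper.

    The auto-inductive CTL term can blow up in finite time in extreme
    corners of parameter space; a trajectory whose components exceed
    ``state_cap`` (or exhaust ``mxstep`` solver steps per output interval)
    raises an :class:`IntegrationError` naming the failing interval rather
    than letting the stepper grind towards the singularity.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array of days")
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if init is None:
        init = default_initial_state()

    out = np.empty((t_grid.size, 5))
    if t_grid.size == 1:
        out[0] = init.as_array()
        return Trajectory(times=t_grid, states=out, params=params)

    td = params.transfer_day
    # segment boundaries: [t0 .. td] with s off, [td .. tend] with s on
    segments: list[tuple[float, float, bool]] = []
    t0, tend = float(t_grid[0]), float(t_grid[-1])
    if td <= t0:
        segments.append((t0, tend, True))
    elif td >= tend:
        segments.append((t0, tend, False))
    else:
        segments.append((t0, td, False))
        segments.append((td, tend, True))

    y = init.as_array()
    out[0] = y
    for a, b, active in segments:
        mask = (t_grid > a) & (t_grid <= b)
        # always evaluate at the segment end so the next segment restarts there
        t_eval = np.union1d(np.concatenate(([a], t_grid[mask])), [b])
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", ODEintWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            ys, info = odeint(
                _rhs,
                y,
                t_eval,
                args=(params, active),
                rtol=rtol,
                atol=atol,
                mxstep=mxstep,
                tfirst=True,
                full_output=True,
            )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(ys)):
            raise IntegrationError(
                f"integration failed on [{a}, {b}] (s {'active' if active else 'inactive'}): "
                f"{info['message']}"
            )
        if np.max(ys) > state_cap:
            raise IntegrationError(
                f"state exceeded {state_cap:g} on [{a}, {b}] — trajectory blowing up"
            )
        out[mask] = ys[np.isin(t_eval, t_grid[mask])]
        y = ys[-1]

    out = np.maximum(out, 0.0)  # floor solver round-off below zero
    return Trajectory(times=t_grid, states=out, params=params)


# ---------------------------------------------------------------------------
# parameter-set serialisation and packaged best-fit parameter sets

def save_params(params: ModelParameters, path) -> None:
    """Write a parameter set to a flat YAML file keyed by symbol name."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(source) -> ModelParameters:
    """Load a parameter set.

    ``source`` is either a path to a flat YAML file or the name of a packaged
    set: ``"act_only"`` (adoptive transfer alone) or ``"act_mab"`` (adoptive
    transfer plus agonist anti-CD137 antibody).
    """
    if isinstance(source, str) and source in ("act_only", "act_mab"):
        text = resources.files("ctldyn.data").joinpath(f"{source}.yaml").read_text()
        return ModelParameters.from_dict(yaml.safe_load(text))
    with open(source) as fh:
        return ModelParameters.from_dict(yaml.safe_load(fh))
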