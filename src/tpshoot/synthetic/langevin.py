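"""Langevin dynamics on analytic potentials (BAOAB splitting).

With friction = 0 and temperature = 0 the integrator reduces exactly to
velocity Verlet, so conservative trajectories conserve energy to O(dt^2).
All randomness flows through an explicit ``numpy.random.Generator`` or seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import IntegrationBlowupError, ValidationError
from .potentials import PotentialSpec


@dataclass
class EngineState:
    """Positions, velocities and time of the toy system."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_1d(np.asarray(self.velocities, dtype=float))
        if self.positions.shape != self.velocities.shape:
            raise ValidationError(
                "positions and velocities must have identical dimensionality"
            )

    def copy(self) -> "EngineState":
        return EngineState(self.positions.copy(), self.velocities.copy(), self.time)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_mb_velocities(
    masses: np.ndarray | float, temperature: float, seed
) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw: i.i.d. zero-mean Gaussians with
    variance temperature/mass per component (temperature in kT units)."""
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if np.any(masses <= 0):
        raise ValidationError("masses must be positive")
    if temperature < 0:
        raise ValidationError("temperature must be non-negative")
    if temperature == 0:
        return np.zeros_like(masses)
    rng = _as_rng(seed)
    return rng.normal(0.0, np.sqrt(temperature / masses))


class ToyEngine:
    """Stepping engine bundling a potential with integration parameters.

    One BAOAB step: half-kick, half-drift, Ornstein-Uhlenbeck velocity
    update, half-drift, half-kick.
    """

    def __init__(
        self,
        potential: PotentialSpec,
        dt: float,
        friction: float = 1.0,
        temperature: float = 1.0,
        masses: np.ndarray | float = 1.0,
    ):
        if dt <= 0:
            raise ValidationError("dt must be positive")
        if friction < 0:
            raise ValidationError("friction must be non-negative")
        if temperature < 0:
            raise ValidationError("temperature must be non-negative")
        self.potential = potential
        self.dt = float(dt)
        self.friction = float(friction)
        self.temperature = float(temperature)
        self.masses = np.atleast_1d(np.asarray(masses, dtype=float))
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be positive")
        self._c1 = np.exp(-self.friction * self.dt)
        self._c2 = np.sqrt(max(0.0, 1.0 - self._c1 * self._c1))

    def _broadcast_masses(self, q: np.ndarray) -> np.ndarray:
        if self.masses.size == q.size:
            return self.masses
        return np.broadcast_to(self.masses, q.shape)

    def step(self, state: EngineState, rng: np.random.Generator) -> EngineState:
        q = state.positions.copy()
        v = state.velocities.copy()
        m = self._broadcast_masses(q)
        half = 0.5 * self.dt
        v -= half * self.potential.gradient(q) / m
        q += half * v
        if self.friction > 0:
            sigma = np.sqrt(self.temperature / m)
            v = self._c1 * v + self._c2 * sigma * rng.standard_normal(v.shape)
        q += half * v
        v -= half * self.potential.gradient(q) / m
        return EngineState(q, v, state.time + self.dt)

    def energy(self, state: EngineState) -> float:
        m = self._broadcast_masses(state.positions)
        kinetic = 0.5 * float(np.sum(m * state.velocities**2))
        return kinetic + self.potential.energy(state.positions)


def langevin_propagate(
    state: EngineState,
    potential: PotentialSpec,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    seed,
    masses: np.ndarray | float = 1.0,
) -> list[EngineState]:
    """Propagate ``n_steps`` Langevin steps; returns n_steps + 1 states
    including the initial one.  Identical seeds give identical trajectories."""
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    engine = ToyEngine(potential, dt, friction, temperature, masses)
    rng = _as_rng(seed)
    out = [state.copy()]
    current = state
    for i in range(n_steps):
        current = engine.step(current, rng)
        if not (
            np.all(np.isfinite(current.positions))
            and np.all(np.isfinite(current.velocities))
        ):
            raise IntegrationBlowupError(i + 1)
        out.append(current)
    return out
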