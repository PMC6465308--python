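"""Two-segment transition-path shooting.

From a candidate transition state, a pair of trajectory segments is shot
off with Maxwell-Boltzmann velocities, one segment with sign-inverted
initial velocities.  If the conjugate segments commit to opposite metastable
states, the time-reversed segment is prepended to form one continuous,
unbiased transition path.  Repeated shots from a point estimate its
committor; the detailed-balance weight ratio of two paths is the ratio
n_old/n_new of their configuration counts inside the shooting range (the
union of occluded and connected access states).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegeneratePathError,
    StitchContractError,
    UndefinedCommittorError,
    ValidationError,
)
from .hydration import AccessState
from .synthetic.langevin import EngineState, ToyEngine, draw_mb_velocities


class Outcome(enum.Enum):
    TO_A = "A"
    TO_B = "B"
    UNCOMMITTED = "uncommitted"


@dataclass(frozen=True)
class StateDefinition:
    """Named metastable state with a predicate on engine states."""

    name: str
    predicate: Callable[[EngineState], bool]

    def __contains__(self, state: EngineState) -> bool:
        return bool(self.predicate(state))


def interval_state(name: str, coord: int, lo: float, hi: float) -> StateDefinition:
    """State defined by one coordinate lying in [lo, hi]."""
    return StateDefinition(
        name, lambda s, c=coord, a=lo, b=hi: a <= s.positions[c] <= b
    )


@dataclass
class ShotResult:
    outcome: Outcome
    segment: list
    steps_to_commit: int | None


@dataclass
class TransitionPath:
    """Stitched continuous path between opposite states.

    ``frames`` is time-ordered; ``shooting_index`` locates the (single)
    shooting point; ``provenance`` labels each frame as backward / shoot /
    forward; ``endpoints`` holds the state names at the two ends.
    """

    frames: list
    times: np.ndarray
    shooting_index: int
    provenance: list
    endpoints: tuple

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ShootingRecord:
    """Descriptors of one shooting point plus its outcome tallies."""

    point_id: object
    q: np.ndarray
    n_to_A: int = 0
    n_to_B: int = 0
    n_uncommitted: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.atleast_1d(np.asarray(self.q, dtype=float)))
        if min(self.n_to_A, self.n_to_B, self.n_uncommitted) < 0:
            raise ValidationError("tallies must be non-negative")
        if not np.all(np.isfinite(self.q)):
            raise ValidationError("descriptors must be finite")

    @property
    def n_committed(self) -> int:
        return self.n_to_A + self.n_to_B


@dataclass
class CommittorEstimate:
    phi_B: float
    n_committed: int
    std_error: float


def run_until_committed(
    state: EngineState,
    engine: ToyEngine,
    states: tuple,
    max_steps: int,
    rng: np.random.Generator,
) -> ShotResult:
    """Propagate until the A or B predicate first holds (first passage) or
    ``max_steps`` is exhausted.  The returned segment is truncated at the
    first-passage frame and includes the initial state."""
    if max_steps < 1:
        raise ValidationError("max_steps must be >= 1")
    state_a, state_b = states
    segment = [state.copy()]
    if state in state_a:
        return ShotResult(Outcome.TO_A, segment, 0)
    if state in state_b:
        return ShotResult(Outcome.TO_B, segment, 0)
    current = state
    for step in range(1, max_steps + 1):
        current = engine.step(current, rng)
        segment.append(current)
        if current in state_a:
            return ShotResult(Outcome.TO_A, segment, step)
        if current in state_b:
            return ShotResult(Outcome.TO_B, segment, step)
    return ShotResult(Outcome.UNCOMMITTED, segment, None)


def stitch(
    forward: ShotResult, backward: ShotResult, point: EngineState
) -> TransitionPath:
    """Reverse the backward segment in time, prepend it to the forward
    segment, and remap times to a strictly increasing axis.  The shooting
    point appears exactly once."""
    committed = {Outcome.TO_A, Outcome.TO_B}
    if forward.outcome not in committed or backward.outcome not in committed:
        raise StitchContractError("both segments must be committed")
    if forward.outcome == backward.outcome:
        raise StitchContractError("segments committed to the same state")
    back = list(reversed(backward.segment))[:-1]  # drop duplicate shooting point
    frames = [s.copy() for s in back] + [s.copy() for s in forward.segment]
    n_back = len(back)
    dt = (
        forward.segment[1].time - forward.segment[0].time
        if len(forward.segment) > 1
        else 1.0
    )
    times = dt * np.arange(len(frames))
    for fr, t in zip(frames, times):
        fr.time = float(t)
    first = "A" if backward.outcome == Outcome.TO_A else "B"
    last = "A" if forward.outcome == Outcome.TO_A else "B"
    provenance = ["backward"] * n_back + ["shoot"] + ["forward"] * (
        len(forward.segment) - 1
    )
    return TransitionPath(
        frames=frames,
        times=times,
        shooting_index=n_back,
        provenance=provenance,
        endpoints=(first, last),
    )


def shoot_pair(
    point: EngineState,
    engine: ToyEngine,
    states: tuple,
    temperature: float,
    max_steps: int,
    seed,
):
    """One two-segment shot: draw Maxwell-Boltzmann velocities, run the
    forward segment with them and the backward segment with their sign
    inverse (independent thermostat noise), and stitch when the outcomes
    are opposite.  Random draws are consumed in a fixed order: velocities,
    forward noise, backward noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vel_rng, fwd_rng, bwd_rng = rng.spawn(3)
    masses = np.broadcast_to(engine.masses, point.positions.shape)
    v = draw_mb_velocities(masses, temperature, vel_rng)
    fwd_start = EngineState(point.positions.copy(), v.copy(), point.time)
    bwd_start = EngineState(point.positions.copy(), -v, point.time)
    forward = run_until_committed(fwd_start, engine, states, max_steps, fwd_rng)
    backward = run_until_committed(bwd_start, engine, states, max_steps, bwd_rng)
    committed = {Outcome.TO_A, Outcome.TO_B}
    path = None
    if (
        forward.outcome in committed
        and backward.outcome in committed
        and forward.outcome != backward.outcome
    ):
        path = stitch(forward, backward, point)
    return forward, backward, path


def estimate_committor(results: Sequence[ShotResult]) -> CommittorEstimate:
    """Fraction of committed shots reaching B, with binomial standard
    error; uncommitted shots are excluded."""
    n_b = sum(1 for r in results if r.outcome is Outcome.TO_B)
    n_a = sum(1 for r in results if r.outcome is Outcome.TO_A)
    n = n_a + n_b
    if n == 0:
        raise UndefinedCommittorError("no committed shots")
    p = n_b / n
    return CommittorEstimate(phi_B=p, n_committed=n, std_error=np.sqrt(p * (1 - p) / n))


def in_shooting_range(access_state: AccessState) -> bool:
    """Shooting range = union of occluded and connected access states."""
    return access_state in (AccessState.OCCLUDED, AccessState.CONNECTED)


def path_weight_ratio(n_old: int, n_new: int) -> Fraction:
    """Detailed-balance weight ratio p_new/p_old = n_old/n_new of shooting-
    range configuration counts; exact rational."""
    if n_old < 1 or n_new < 1:
        raise DegeneratePathError(
            "a transition path must contain at least one shooting-range configuration"
        )
    return Fraction(n_old, n_new)


def chain_weight(ratios: Sequence[Fraction]) -> Fraction:
    """Exact product of weight ratios over a chain of accepted moves."""
    out = Fraction(1)
    for r in ratios:
        out *= r
    return out


def select_shooting_points(
    path: TransitionPath,
    model=None,
    n_points: int = 1,
    seed=None,
    range_mask: np.ndarray | None = None,
    descriptor_fn: Callable | None = None,
):
    """Pick candidate shooting frames from a transition path.

    Without a reaction-coordinate model: uniform random draw (without
    replacement) from the frames flagged by ``range_mask`` (the shooting
    range).  With a model: the frames minimizing |predicted committor - 0.5|
    using ``descriptor_fn(frame) -> descriptor vector``.
    Returns (indices, frames).
    """
    if len(path) == 0:
        raise ValidationError("empty path")
    if model is None:
        if range_mask is None:
            raise ValidationError("range_mask required when no model is given")
        candidates = np.flatnonzero(np.asarray(range_mask, dtype=bool))
        if candidates.size == 0:
            warnings.warn("no frames in shooting range; empty selection")
            return np.empty(0, dtype=int), []
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        k = min(n_points, candidates.size)
        idx = np.sort(rng.choice(candidates, size=k, replace=False))
    else:
        from .rcopt import predict

        if descriptor_fn is None:
            raise ValidationError("descriptor_fn required when a model is given")
        indices = np.arange(len(path))
        if range_mask is not None:
            indices = indices[np.asarray(range_mask, dtype=bool)]
        if indices.size == 0:
            warnings.warn("no frames in shooting range; empty selection")
            return np.empty(0, dtype=int), []
        scores = np.array(
            [
                abs(predict(model, descriptor_fn(path.frames[i])) - 0.5)
                for i in indices
            ]
        )
        order = np.argsort(scores, kind="stable")
        idx = np.sort(indices[order[: min(n_points, indices.size)]])
    return idx, [path.frames[i] for i in idx]
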