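"""Analytic toy potentials for the Langevin engine.

The default transition-path testbed is a symmetric 2D double well

    V(x, y) = h * ((x/a)^2 - 1)^2 + (1/2) k y^2

with barrier height h (kT units), well separation 2a (minima at x = +/- a)
and orthogonal stiffness k.  The saddle sits at x = 0, so the x = 0 plane is
an exact committor-1/2 surface by symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ..errors import ValidationError

PotentialKind = Literal["double_well_1d", "double_well_2d", "harmonic"]

_KIND_DIM = {"double_well_1d": 1, "double_well_2d": 2}


@dataclass(frozen=True)
class PotentialSpec:
    """Analytic potential: kind, barrier height (kT), well separation
    (distance between minima) and orthogonal stiffness."""

    kind: PotentialKind = "double_well_2d"
    barrier_height: float = 5.0
    well_separation: float = 2.0
    orthogonal_stiffness: float = 5.0
    dimensionality: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("double_well_1d", "double_well_2d", "harmonic"):
            raise ValidationError(f"unknown potential kind {self.kind!r}")
        if self.barrier_height <= 0:
            raise ValidationError("barrier height must be positive")
        if self.well_separation <= 0:
            raise ValidationError("well separation must be positive")
        if self.orthogonal_stiffness <= 0:
            raise ValidationError("orthogonal stiffness must be positive")
        dim = self.dimensionality
        if self.kind in _KIND_DIM:
            if dim is not None and dim != _KIND_DIM[self.kind]:
                raise ValidationError(
                    f"{self.kind} is {_KIND_DIM[self.kind]}-dimensional"
                )
            object.__setattr__(self, "dimensionality", _KIND_DIM[self.kind])
        elif dim is None:
            object.__setattr__(self, "dimensionality", 1)
        elif dim < 1:
            raise ValidationError("dimensionality must be >= 1")

    @property
    def half_separation(self) -> float:
        return self.well_separation / 2.0

    def energy(self, q: np.ndarray) -> float:
        q = np.asarray(q, dtype=float)
        h, a, k = self.barrier_height, self.half_separation, self.orthogonal_stiffness
        if self.kind == "harmonic":
            return 0.5 * k * float(np.dot(q, q))
        u = (q[0] / a) ** 2 - 1.0
        v = h * u * u
        if self.kind == "double_well_2d":
            v += 0.5 * k * q[1] ** 2
        return float(v)

    def gradient(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        h, a, k = self.barrier_height, self.half_separation, self.orthogonal_stiffness
        if self.kind == "harmonic":
            return k * q
        g = np.zeros_like(q)
        u = (q[0] / a) ** 2 - 1.0
        g[0] = 4.0 * h * u * q[0] / (a * a)
        if self.kind == "double_well_2d":
            g[1] = k * q[1]
        return g

    def minima(self) -> np.ndarray:
        """Analytic minima, one per row."""
        if self.kind == "harmonic":
            return np.zeros((1, self.dimensionality))
        a = self.half_separation
        m = np.zeros((2, self.dimensionality))
        m[0, 0], m[1, 0] = -a, a
        return m
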