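"""Frame and atom-selection containers shared by the analysis modules.

A :class:`Frame` is one time point of a system: coordinates in Angstrom,
optional velocities, an optional orthorhombic box, and a time stamp.
An :class:`AtomSelection` is a named set of 0-based indices into a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class Frame:
    """One time point: N x 3 coordinates (Angstrom), optional velocities
    and orthorhombic box, and a time stamp."""

    coordinates: np.ndarray
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError(
                f"coordinates must be (N, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValidationError("frame must contain at least one atom")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValidationError(
                    "velocities must have the same shape as coordinates"
                )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValidationError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            coordinates=self.coordinates.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            box=None if self.box is None else self.box.copy(),
            time=self.time,
        )


@dataclass(frozen=True)
class AtomSelection:
    """Named, unique, 0-based index set into a Frame."""

    name: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        if len(np.unique(idx)) != idx.size:
            raise ValidationError(f"selection {self.name!r} has duplicate indices")
        if idx.size and idx.min() < 0:
            raise ValidationError(f"selection {self.name!r} has negative indices")
        object.__setattr__(self, "indices", idx)

    def validate(self, n_atoms: int) -> None:
        if self.indices.size and self.indices.max() >= n_atoms:
            raise ValidationError(
                f"selection {self.name!r} indexes beyond frame size {n_atoms}"
            )

    def __len__(self) -> int:
        return int(self.indices.size)

    def coords(self, frame: Frame) -> np.ndarray:
        self.validate(frame.n_atoms)
        return frame.coordinates[self.indices]


def minimum_image(displacements: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention (orthorhombic box) to displacement
    vectors; pass-through when box is None."""
    d = np.asarray(displacements, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)
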