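"""Synthetic shooting-outcome records from a known committor model.

Descriptors are drawn from a configurable Gaussian; each shot is
uncommitted with a fixed probability (independent of the reaction
coordinate) and otherwise reaches state B with probability
[1 + tanh(Q_true)] / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import DegenerateDescriptorsWarning, ValidationError

if False:  # pragma: no cover - type-checking only, avoids an import cycle
    from ..rcopt import RCModel


@dataclass(frozen=True)
class DescriptorDistribution:
    """Gaussian descriptor distribution: per-descriptor means and either a
    std vector (independent) or a full covariance matrix."""

    mean: np.ndarray
    std: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "mean", mean)
        if self.cov is not None:
            cov = np.asarray(self.cov, dtype=float)
            if cov.shape != (mean.size, mean.size):
                raise ValidationError("covariance shape mismatch")
            object.__setattr__(self, "cov", cov)
        else:
            std = (
                np.ones_like(mean)
                if self.std is None
                else np.broadcast_to(
                    np.asarray(self.std, dtype=float), mean.shape
                ).copy()
            )
            if np.any(std < 0):
                raise ValidationError("std must be non-negative")
            object.__setattr__(self, "std", std)

    @property
    def dim(self) -> int:
        return int(self.mean.size)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.cov is not None:
            return rng.multivariate_normal(self.mean, self.cov, size=n)
        return self.mean + self.std * rng.standard_normal((n, self.dim))

    def is_degenerate(self) -> bool:
        if self.cov is not None:
            return bool(np.all(np.diag(self.cov) == 0))
        return bool(np.all(self.std == 0))


def standard_rc_model(coefficients, names=None) -> "RCModel":
    """RCModel with identity standardization, convenient as generator truth."""
    from ..rcopt import RCModel

    coefficients = np.atleast_1d(np.asarray(coefficients, dtype=float))
    k = coefficients.size - 1
    if names is None:
        names = [f"q{i + 1}" for i in range(k)]
    return RCModel(
        descriptor_names=list(names),
        coefficients=coefficients,
        means=np.zeros(k),
        scales=np.ones(k),
    )


def gen_shooting_records(
    true_model: "RCModel",
    descriptor_distribution: DescriptorDistribution,
    n_points: int,
    shots_per_point: int,
    uncommitted_rate: float = 0.0,
    seed=None,
) -> list[ShootingRecord]:
    """Draw shooting points and binomial outcome tallies from the true
    committor model; tallies sum to shots_per_point at every point."""
    from ..rcopt import committor_model
    from ..tps import ShootingRecord

    if shots_per_point < 1:
        raise ValidationError("shots_per_point must be >= 1")
    if not (0.0 <= uncommitted_rate < 1.0):
        raise ValidationError("uncommitted_rate must lie in [0, 1)")
    if descriptor_distribution.dim != true_model.n_descriptors:
        raise ValidationError("descriptor distribution does not match model")
    if descriptor_distribution.is_degenerate():
        warnings.warn(
            "all descriptors have zero variance", DegenerateDescriptorsWarning
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = descriptor_distribution.draw(n_points, rng)
    p_b = committor_model(true_model.reaction_coordinate(q))
    p_b = np.atleast_1d(p_b)
    records = []
    for i in range(n_points):
        n_unc = int(rng.binomial(shots_per_point, uncommitted_rate))
        committed = shots_per_point - n_unc
        n_b = int(rng.binomial(committed, p_b[i])) if committed else 0
        records.append(
            ShootingRecord(
                point_id=i,
                q=q[i],
                n_to_A=committed - n_b,
                n_to_B=n_b,
                n_uncommitted=n_unc,
            )
        )
    return records
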