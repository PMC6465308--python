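"""Run configuration: YAML file with schema validation and lossless
round-trip, plus deterministic stage-seed derivation from one master seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..errors import ValidationError


@dataclass
class RunConfig:
    seed: int = 0
    # toy engine
    potential_kind: str = "double_well_2d"
    barrier_height: float = 5.0
    well_separation: float = 2.0
    orthogonal_stiffness: float = 5.0
    dt: float = 0.01
    friction: float = 1.0
    temperature: float = 1.0
    mass: float = 1.0
    max_steps: int = 5000
    # metastable-state thresholds on the toy x coordinate
    state_a_max: float = -0.75
    state_b_min: float = 0.75
    # shooting-range window on x (toy analogue of occluded/connected)
    range_lo: float = -0.5
    range_hi: float = 0.5
    # hydration
    alpha: float = 10.0
    beta: float = 5.0
    gamma: float = 5.0
    cluster_cutoff: float = 3.0
    contact_cutoff: float = 3.0
    slab_center: float = 0.0
    slab_width: float = 10.0
    # optimizer
    mc_steps: int = 3000
    mc_restarts: int = 5
    proposal_scale: float = 0.5
    n_bootstrap: int = 200
    uncertainty: str = "bootstrap"

    def validate(self) -> "RunConfig":
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.friction < 0 or self.temperature < 0:
            raise ValidationError("friction and temperature must be non-negative")
        if self.barrier_height <= 0 or self.well_separation <= 0:
            raise ValidationError("barrier height and well separation must be positive")
        if self.max_steps < 1 or self.mc_steps < 1 or self.mc_restarts < 1:
            raise ValidationError("step counts must be >= 1")
        if not self.state_a_max < self.state_b_min:
            raise ValidationError("state A must lie below state B on x")
        if min(self.alpha, self.beta, self.gamma, self.cluster_cutoff) <= 0:
            raise ValidationError("hydration parameters must be positive")
        if self.slab_width < 0:
            raise ValidationError("slab width must be non-negative")
        if self.uncertainty not in ("bootstrap", "mc_spread", "hessian", "none"):
            raise ValidationError(f"unknown uncertainty recipe {self.uncertainty!r}")
        return self

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(
            [self.seed, int.from_bytes(stage.encode(), "little") % (2**63)]
        )
        return int(ss.generate_state(1)[0])


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
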