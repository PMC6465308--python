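"""Synthetic protein/water fixture frames with known ground truth.

A fixture contains a static "dimerization" pseudo-atom cloud, a mobile
"transporter" cloud displaced from its stored inward reference by a known
z-translation and in-plane-axis rotation, a single probe atom at the
transporter centroid, and water points whose single-linkage connectivity at
the 3.0 A cutoff realizes a requested access state by construction:

* inward/outward bulk waters form 2.9 A-spaced vertical chains anchored
  within attachment range of the respective face of the retained region,
  laterally offset from the probe so they never contact it directly;
* "pore" waters build 2.9 A-spaced straight bridges from the probe to the
  requested chain(s); left-over pore waters form an isolated clump.

The rigid transform is produced with scipy's Rotation so that the
rigid-body analysis module can be validated against an independent
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ..errors import FixtureInfeasibleError, ValidationError
from ..frames import AtomSelection, Frame
from ..hydration import AccessState, HydrationParams, Slab

_SPACING = 2.9  # water chain spacing, below the 3.0 A clustering cutoff
_CONTACT = 2.5  # probe-to-first-bridge-water distance, below 3.0 A
_LATERAL = 8.0  # bulk-chain lateral offset from the probe
_EDGE = 1.0  # first chain water sits this far inside the retained boundary
_N_DOMAIN = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Requested fixture geometry and ground truth."""

    delta_z_true: float = 0.0
    delta_phi_true: float = 0.0
    access_state_true: AccessState = AccessState.OCCLUDED
    n_waters_inward: int = 4
    n_waters_outward: int = 4
    n_waters_pore: int = 30
    box: tuple = (60.0, 60.0, 80.0)
    seed: int = 0
    slab_width: float = 10.0

    def __post_init__(self) -> None:
        if min(self.n_waters_inward, self.n_waters_outward, self.n_waters_pore) < 0:
            raise ValidationError("water counts must be non-negative")
        if not (0.0 <= self.delta_phi_true < 180.0):
            raise ValidationError("delta_phi_true must lie in [0, 180)")
        if any(b <= 0 for b in self.box):
            raise ValidationError("box edges must be positive")


@dataclass
class FixtureGroundTruth:
    delta_z: float
    delta_phi: float
    access_state: AccessState
    rotation_axis: np.ndarray
    probe_position: np.ndarray
    n_waters_inward: int
    n_waters_outward: int
    n_waters_pore: int
    seed: int


@dataclass
class FixtureResult:
    frame: Frame
    ref_in: Frame
    selections: dict
    ground_truth: FixtureGroundTruth
    slab: Slab
    hydration_params: HydrationParams


def _bridge(start_anchor: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Straight chain from ``start_anchor`` toward ``target`` with spacing
    <= 2.9 A and last point within 2.9 A of the target."""
    delta = target - start_anchor
    length = float(np.linalg.norm(delta))
    m = max(1, math.ceil(length / _SPACING))
    step = delta / m
    return start_anchor + np.outer(np.arange(m), step)


def gen_fixture(spec: FixtureSpec) -> FixtureResult:
    """Build the fixture frame, its inward reference and the ground truth."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    lx, ly, lz = box
    half_slab = spec.slab_width / 2.0
    z_lo, z_hi = half_slab, lz - half_slab  # retained region boundaries

    center = np.array([lx / 2.0, ly / 2.0, lz / 2.0])
    probe_final_z = center[2] + spec.delta_z_true
    if not (z_lo + 3.0 < probe_final_z < z_hi - 3.0):
        raise FixtureInfeasibleError(
            "probe would leave the retained water region; reduce |delta_z_true|"
        )

    # static scaffold cloud, left of centre
    dimer = np.array([lx / 2.0 - 18.0, ly / 2.0, lz / 2.0]) + rng.uniform(
        -4.0, 4.0, size=(_N_DOMAIN, 3)
    )
    # mobile cloud, recentred so its centroid is exactly the probe reference
    transporter_ref = center + rng.uniform(-4.0, 4.0, size=(_N_DOMAIN, 3))
    transporter_ref = transporter_ref - transporter_ref.mean(axis=0) + center

    axis = np.array([1.0, 0.0, 0.0])  # in-plane rotation axis
    rot = Rotation.from_rotvec(np.deg2rad(spec.delta_phi_true) * axis)
    shift = np.array([0.0, 0.0, spec.delta_z_true])
    transporter = rot.apply(transporter_ref - center) + center + shift
    probe = center + shift

    waters: list[np.ndarray] = []
    # bulk chains, laterally offset so they never contact the probe directly
    chain_in = np.empty((0, 3))
    if spec.n_waters_inward > 0:
        z0 = z_lo + _EDGE
        z_top = z0 + _SPACING * (spec.n_waters_inward - 1)
        if z_top > z_hi - 3.0 - _EDGE:
            raise FixtureInfeasibleError("inward chain would reach the outward face")
        chain_in = np.column_stack(
            [
                np.full(spec.n_waters_inward, center[0] - _LATERAL),
                np.full(spec.n_waters_inward, center[1]),
                z0 + _SPACING * np.arange(spec.n_waters_inward),
            ]
        )
        waters.append(chain_in)
    chain_out = np.empty((0, 3))
    if spec.n_waters_outward > 0:
        z0 = z_hi - _EDGE
        z_bot = z0 - _SPACING * (spec.n_waters_outward - 1)
        if z_bot < z_lo + 3.0 + _EDGE:
            raise FixtureInfeasibleError("outward chain would reach the inward face")
        chain_out = np.column_stack(
            [
                np.full(spec.n_waters_outward, center[0] + _LATERAL),
                np.full(spec.n_waters_outward, center[1]),
                z0 - _SPACING * np.arange(spec.n_waters_outward),
            ]
        )
        waters.append(chain_out)

    state = spec.access_state_true
    need_in = state in (AccessState.INWARD, AccessState.CONNECTED)
    need_out = state in (AccessState.OUTWARD, AccessState.CONNECTED)
    if need_in and spec.n_waters_inward == 0:
        raise FixtureInfeasibleError(f"{state.value} state requires inward waters")
    if need_out and spec.n_waters_outward == 0:
        raise FixtureInfeasibleError(f"{state.value} state requires outward waters")

    bridges: list[np.ndarray] = []
    if need_in:
        target = chain_in[-1]
        u = (target - probe) / np.linalg.norm(target - probe)
        bridges.append(_bridge(probe + _CONTACT * u, target))
    if need_out:
        target = chain_out[-1]
        u = (target - probe) / np.linalg.norm(target - probe)
        bridges.append(_bridge(probe + _CONTACT * u, target))
    n_bridge = sum(len(b) for b in bridges)
    if n_bridge > spec.n_waters_pore:
        raise FixtureInfeasibleError(
            f"{state.value} state needs {n_bridge} pore waters, "
            f"spec provides {spec.n_waters_pore}"
        )
    waters.extend(bridges)

    # spare pore waters: isolated 2.9 A grid well away from probe, chains
    # and bridges (all of which sit at y <= center_y), at mid-box z
    n_spare = spec.n_waters_pore - n_bridge
    if n_spare > 0:
        y0 = center[1] + 12.0
        xs = np.arange(2.0, lx - 2.0, _SPACING)
        n_rows = math.ceil(n_spare / len(xs))
        if y0 + _SPACING * (n_rows - 1) > ly - 1.0:
            raise FixtureInfeasibleError("too many spare pore waters for the box")
        gx, gy = np.meshgrid(xs, y0 + _SPACING * np.arange(n_rows))
        clump = np.column_stack(
            [
                gx.ravel()[:n_spare],
                gy.ravel()[:n_spare],
                np.full(n_spare, probe_final_z),
            ]
        )
        waters.append(clump)

    water_coords = (
        np.vstack(waters) if waters else np.empty((0, 3))
    )

    def assemble(trans: np.ndarray, probe_pos: np.ndarray) -> Frame:
        coords = np.vstack([dimer, trans, probe_pos[None, :], water_coords])
        return Frame(coordinates=coords, box=box.copy())

    frame = assemble(transporter, probe)
    ref_in = assemble(transporter_ref, center)

    n_d = _N_DOMAIN
    n_w = water_coords.shape[0]
    selections = {
        "dimer": AtomSelection("dimer", np.arange(n_d)),
        "transporter": AtomSelection("transporter", np.arange(n_d, 2 * n_d)),
        "probe": AtomSelection("probe", np.array([2 * n_d])),
        "waters": AtomSelection("waters", np.arange(2 * n_d + 1, 2 * n_d + 1 + n_w)),
    }
    truth = FixtureGroundTruth(
        delta_z=spec.delta_z_true,
        delta_phi=spec.delta_phi_true,
        access_state=state,
        rotation_axis=axis,
        probe_position=probe,
        n_waters_inward=spec.n_waters_inward,
        n_waters_outward=spec.n_waters_outward,
        n_waters_pore=spec.n_waters_pore,
        seed=spec.seed,
    )
    return FixtureResult(
        frame=frame,
        ref_in=ref_in,
        selections=selections,
        ground_truth=truth,
        slab=Slab(center=0.0, width=spec.slab_width),
        hydration_params=HydrationParams(center=probe),
    )


def random_fixture_spec(rng: np.random.Generator, seed: int | None = None) -> FixtureSpec:
    """Random feasible FixtureSpec covering all four access states."""
    state = rng.choice(list(AccessState))
    n_in = int(rng.integers(1, 8))
    n_out = int(rng.integers(1, 8))
    return FixtureSpec(
        delta_z_true=float(rng.uniform(-4.0, 4.0)),
        delta_phi_true=float(rng.uniform(0.0, 25.0)),
        access_state_true=state,
        n_waters_inward=n_in,
        n_waters_outward=n_out,
        n_waters_pore=40,
        seed=int(rng.integers(2**31)) if seed is None else seed,
    )
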