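"""Rigid-body domain order parameters.

Superposition is least-squares (Kabsch/SVD) with proper-rotation enforcement.
The domain motion of a frame relative to inward- and outward-open reference
structures is reported as the translation of the mobile-domain geometric
centre and the angle/axis of the optimal domain rotation, after aligning the
whole frame on the static (dimerization) domain.  The combined order
parameters follow the averaging convention

    dphi = (dphi_in - dphi_out) / 2        dz = (dz_in + dz_out) / 2

Angles are handled internally in radians and reported in degrees; the
rotation angle is non-negative by convention, with any sign absorbed into
the axis direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import AxisUndefinedError, DegeneracyError, ValidationError
from .frames import AtomSelection, Frame

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidBodyFit:
    """Optimal proper rotation R and translation t mapping mobile
    coordinates onto the reference: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation

    def apply_to_frame(self, frame: Frame) -> Frame:
        out = frame.copy()
        out.coordinates = self.apply(frame.coordinates)
        if out.velocities is not None:
            out.velocities = out.velocities @ self.rotation.T
        return out


@dataclass
class DomainMotion:
    """Per-frame domain order parameters relative to both references."""

    dphi_in: float
    dphi_out: float
    dz_in: float
    dz_out: float
    axis_in: np.ndarray | None
    axis_out: np.ndarray | None
    rotation_mode: str = "after_fit"
    time: float = 0.0

    @property
    def dphi(self) -> float:
        return (self.dphi_in - self.dphi_out) / 2.0

    @property
    def dz(self) -> float:
        return (self.dz_in + self.dz_out) / 2.0


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError("rotation matrix must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
        raise ValidationError("matrix is not orthogonal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
        raise ValidationError("matrix is not a proper rotation (det != +1)")
    return R


def rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Axis-angle rotation matrix:
    R = cos(phi) I + (1 - cos(phi)) e e^T + sin(phi) [e]_x."""
    e = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValidationError("axis must be non-zero")
    e = e / norm
    phi = np.deg2rad(angle_deg)
    cross = np.array(
        [[0.0, -e[2], e[1]], [e[2], 0.0, -e[0]], [-e[1], e[0], 0.0]]
    )
    return (
        np.cos(phi) * np.eye(3)
        + (1.0 - np.cos(phi)) * np.outer(e, e)
        + np.sin(phi) * cross
    )


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle in degrees, in [0, 180], from cos = (trace - 1)/2.

    Evaluated as atan2(|skew(R)|/2, (trace - 1)/2), which equals the
    arccos of the clamped trace argument for any proper rotation but stays
    accurate near 0 and 180 degrees where arccos loses precision.
    """
    R = _check_rotation(R)
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    s = 0.5 * np.linalg.norm(
        [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
    )
    return float(np.degrees(np.arctan2(s, c)))


def rotation_axis(R: np.ndarray, angle_deg: float, tol: float = 1e-9) -> np.ndarray:
    """Unit rotation axis e = (R32-R23, R13-R31, R21-R12) / (2 sin phi);
    undefined at 0 and 180 degrees."""
    R = _check_rotation(R)
    phi = np.deg2rad(angle_deg)
    s = np.sin(phi)
    if angle_deg <= 0 or angle_deg >= 180 or abs(s) < tol:
        raise AxisUndefinedError(
            f"rotation axis undefined at angle {angle_deg} degrees"
        )
    e = np.array(
        [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
    ) / (2.0 * s)
    return e


def _resolve_coords(obj: Frame | np.ndarray, selection: AtomSelection | None):
    coords = obj.coordinates if isinstance(obj, Frame) else np.asarray(obj, float)
    if selection is not None:
        if isinstance(obj, Frame):
            selection.validate(obj.n_atoms)
        coords = coords[selection.indices]
    return coords


def superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    fit_selection: AtomSelection | None = None,
) -> RigidBodyFit:
    """Least-RMSD proper rotation + translation of ``mobile`` onto
    ``reference`` over ``fit_selection`` (Kabsch).  Raises
    :class:`DegeneracyError` for < 3 points or a collinear point set."""
    P = _resolve_coords(mobile, fit_selection)
    Q = _resolve_coords(reference, fit_selection)
    if P.shape != Q.shape:
        raise ValidationError("mobile and reference selections differ in size")
    n = P.shape[0]
    if n < 3:
        raise DegeneracyError("superposition requires at least 3 points")
    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p_mean, Q - q_mean
    # collinear point sets leave the rotation about the line undetermined
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise DegeneracyError("collinear point set: rotation is not unique")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return RigidBodyFit(rotation=R, translation=t, rmsd=rmsd)


def _domain_rotation(frame_coords, ref_coords):
    fit = superpose(frame_coords, ref_coords)
    angle = rotation_angle(fit.rotation)
    try:
        axis = rotation_axis(fit.rotation, angle)
    except AxisUndefinedError:
        axis = None
    return angle, axis


def domain_motion(
    frame: Frame,
    ref_in: Frame,
    ref_out: Frame,
    fit_selection: AtomSelection,
    domain_selection: AtomSelection,
    rotation_mode: Literal["after_fit", "direct"] = "after_fit",
) -> DomainMotion:
    """Domain translation and rotation relative to both references.

    For each reference: align the frame on ``fit_selection``, take the
    geometric-centre difference of ``domain_selection`` (z-component is the
    vertical displacement), and extract the rotation of the optimal
    domain-on-domain superposition.  ``rotation_mode='direct'`` skips the
    prior whole-frame alignment when fitting the domain rotation.
    """
    results = {}
    for tag, ref in (("in", ref_in), ("out", ref_out)):
        fit = superpose(frame, ref, fit_selection)
        aligned = fit.apply(frame.coordinates)
        dvec = (
            aligned[domain_selection.indices].mean(axis=0)
            - ref.coordinates[domain_selection.indices].mean(axis=0)
        )
        source = (
            aligned if rotation_mode == "after_fit" else frame.coordinates
        )
        angle, axis = _domain_rotation(
            source[domain_selection.indices],
            ref.coordinates[domain_selection.indices],
        )
        results[tag] = (float(dvec[2]), angle, axis)
    dz_in, dphi_in, axis_in = results["in"]
    dz_out, dphi_out, axis_out = results["out"]
    return DomainMotion(
        dphi_in=dphi_in,
        dphi_out=dphi_out,
        dz_in=dz_in,
        dz_out=dz_out,
        axis_in=axis_in,
        axis_out=axis_out,
        rotation_mode=rotation_mode,
        time=frame.time,
    )


def average_structure(
    trajectory: Sequence[Frame],
    window: Sequence[int] | slice | None = None,
    fit_selection: AtomSelection | None = None,
) -> Frame:
    """Superpose the window frames onto the first window frame over
    ``fit_selection`` and average coordinates per atom."""
    if window is None:
        frames = list(trajectory)
    elif isinstance(window, slice):
        frames = list(trajectory[window])
    else:
        frames = [trajectory[i] for i in window]
    if not frames:
        raise ValidationError("average_structure: empty window")
    first = frames[0]
    acc = np.zeros_like(first.coordinates)
    for fr in frames:
        if fr.n_atoms != first.n_atoms:
            raise ValidationError("frames differ in atom count")
        if fit_selection is not None:
            fit = superpose(fr, first, fit_selection)
            acc += fit.apply(fr.coordinates)
        else:
            acc += fr.coordinates
    out = first.copy()
    out.coordinates = acc / len(frames)
    return out
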