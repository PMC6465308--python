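"""Water access to a buried site: continuous order parameter and
discrete access-state classification.

The continuous order parameter sums, over water oxygens, a radial sigmoid
weight times a signed axial weight:

    n_access = sum_i sigma_r(|r_i - r0|) * sigma_z(z_i - z0)
    sigma_r(x) = 1 / (1 + exp(beta (x - alpha)))
    sigma_z(x) = (x / gamma) * exp(1/2 - x^2 / (2 gamma^2))

so waters below the centre plane count negative (inward) and waters above
count positive (outward).  Defaults: alpha = 10 A, beta = 5 /A, gamma = 5 A.

The discrete state classifies a probe atom by which bulk water clusters it
contacts: single-linkage clustering of water oxygens at a 3.0 A cutoff under
the minimum-image convention, after excluding a slab at the centre of the
bulk solvent phase so that the inward and outward reservoirs are separated.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import EmptySelectionWarning, ValidationError
from .frames import AtomSelection, Frame, minimum_image


class AccessState(enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"
    OCCLUDED = "occluded"
    CONNECTED = "connected"


@dataclass(frozen=True)
class HydrationParams:
    """Parameters of the continuous hydration order parameter; z0 is tied
    to the z-component of the centre r0."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = 10.0
    beta: float = 5.0
    gamma: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValidationError("alpha, beta, gamma must be positive")

    @property
    def z0(self) -> float:
        return float(self.center[2])


@dataclass(frozen=True)
class Slab:
    """Excluded z-slab at the centre of the bulk solvent phase.

    ``center`` is a z coordinate (default 0, i.e. the periodic box face for
    a membrane centred in the box); ``width`` is the full slab thickness.
    """

    center: float = 0.0
    width: float = 10.0

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValidationError("slab width must be non-negative")


@dataclass
class WaterClustering:
    """Single-linkage partition of the retained (non-slab) waters.

    ``labels`` has one entry per water in the input selection; excluded
    (slab) waters carry label -1.  ``bulk_in``/``bulk_out`` are the label
    sets of clusters attached to the inward / outward face of the retained
    region; a membrane-spanning cluster may appear in both.
    """

    cutoff: float
    labels: np.ndarray
    bulk_in: frozenset
    bulk_out: frozenset
    slab: Slab
    water_indices: np.ndarray

    @property
    def n_clusters(self) -> int:
        retained = self.labels[self.labels >= 0]
        return int(len(np.unique(retained)))


def sigma_r(x, params: HydrationParams) -> np.ndarray | float:
    """Radial sigmoid weight, 0.5 at x = alpha; saturates smoothly."""
    x = np.asarray(x, dtype=float)
    arg = np.clip(params.beta * (x - params.alpha), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(arg))
    return float(out) if out.ndim == 0 else out


def sigma_z(x, params: HydrationParams) -> np.ndarray | float:
    """Signed axial weight, antisymmetric with extrema +/-1 at x = +/-gamma."""
    x = np.asarray(x, dtype=float)
    g = params.gamma
    out = (x / g) * np.exp(0.5 - x * x / (2.0 * g * g))
    return float(out) if out.ndim == 0 else out


def n_access(
    frame: Frame,
    water_selection: AtomSelection,
    params: HydrationParams,
) -> float:
    """Signed hydration count of the site at params.center: positive means
    outward-weighted water access, negative inward."""
    if len(water_selection) == 0:
        warnings.warn(
            "n_access: empty water selection, returning 0", EmptySelectionWarning
        )
        return 0.0
    waters = water_selection.coords(frame)
    disp = minimum_image(waters - params.center, frame.box)
    r = np.linalg.norm(disp, axis=1)
    return float(np.sum(sigma_r(r, params) * sigma_z(disp[:, 2], params)))


def _wrap_z(z: np.ndarray, slab: Slab, box_z: float) -> np.ndarray:
    """z coordinates re-expressed with the slab centre at 0, wrapped into
    [0, box_z): the retained region is then [width/2, box_z - width/2]."""
    return np.mod(z - slab.center, box_z)


def cluster_waters(
    frame: Frame,
    water_selection: AtomSelection,
    cutoff: float = 3.0,
    slab: Slab = Slab(),
    bulk_attach: float = 3.0,
) -> WaterClustering:
    """Single-linkage clustering of water oxygens under minimum image.

    Waters inside the excluded slab are removed before clustering.  A
    cluster is attached to the inward (outward) bulk face when any member
    lies within ``bulk_attach`` (in z) of the low-z (high-z) boundary of the
    retained region.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if frame.box is None:
        raise ValidationError("cluster_waters requires a periodic box")
    water_selection.validate(frame.n_atoms)
    coords = water_selection.coords(frame)
    n = coords.shape[0]
    labels = np.full(n, -1, dtype=int)
    box = frame.box
    box_z = float(box[2])
    zw = _wrap_z(coords[:, 2], slab, box_z)
    half = slab.width / 2.0
    retained = (zw >= half) & (zw <= box_z - half)
    idx = np.flatnonzero(retained)
    if idx.size == 0:
        return WaterClustering(
            cutoff=cutoff,
            labels=labels,
            bulk_in=frozenset(),
            bulk_out=frozenset(),
            slab=slab,
            water_indices=water_selection.indices.copy(),
        )
    pts = np.mod(coords[idx], box)
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    m = idx.size
    if pairs.size:
        data = np.ones(pairs.shape[0])
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(m, m))
    else:
        graph = coo_matrix((m, m))
    _, comp = connected_components(graph, directed=False)
    labels[idx] = comp
    z_ret = zw[idx]
    in_face = comp[z_ret - half <= bulk_attach]
    out_face = comp[(box_z - half) - z_ret <= bulk_attach]
    return WaterClustering(
        cutoff=cutoff,
        labels=labels,
        bulk_in=frozenset(int(c) for c in in_face),
        bulk_out=frozenset(int(c) for c in out_face),
        slab=slab,
        water_indices=water_selection.indices.copy(),
    )


def classify_access(
    frame: Frame,
    probe: AtomSelection,
    clustering: WaterClustering,
    contact_cutoff: float = 3.0,
) -> AccessState:
    """Access state of a single probe atom.

    inward  : probe contacts inward-bulk cluster(s) only
    outward : probe contacts outward-bulk cluster(s) only
    connected: probe contacts both sides (including one spanning cluster)
    occluded : probe contacts no bulk cluster
    """
    if len(probe) != 1:
        raise ValidationError("probe selection must contain exactly one atom")
    probe.validate(frame.n_atoms)
    p = frame.coordinates[probe.indices[0]]
    waters = frame.coordinates[clustering.water_indices]
    retained = clustering.labels >= 0
    if not np.any(retained):
        return AccessState.OCCLUDED
    disp = minimum_image(waters[retained] - p, frame.box)
    dist = np.linalg.norm(disp, axis=1)
    contacted = set(
        int(c) for c in np.unique(clustering.labels[retained][dist <= contact_cutoff])
    )
    touches_in = bool(contacted & clustering.bulk_in)
    touches_out = bool(contacted & clustering.bulk_out)
    if touches_in and touches_out:
        return AccessState.CONNECTED
    if touches_in:
        return AccessState.INWARD
    if touches_out:
        return AccessState.OUTWARD
    return AccessState.OCCLUDED
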