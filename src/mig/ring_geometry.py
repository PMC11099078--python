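"""Geometry of the 14-spoke gamma-TuRC: helical axis, closure, closed reference.

The ring axis is the total-least-squares line through four anchor centroids
(two gamma-tubulin residues and two GCP body residues, over spokes 1-13),
oriented from the GCP base toward the gamma-tubulin layer.  All per-spoke
quantities (radius, azimuth, height, pitch and rotation increments) are the
cylindrical coordinates of gamma-tubulin centres of mass about that axis.

Closure is quantified as the in-plane separation of the spoke 1 and 14
gamma-tubulins: ~4.7 nm for the open ring, zero for a perfectly
microtubule-compatible (closed) ring.  Deviations from the hypothetical
fully closed conformation are Euclidean distances between matched
gamma-tubulin centres after aligning on spokes 3-9, where conformational
changes between states are minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model_io import (
    AnnotationError,
    AtomRecord,
    DegenerateConfigurationError,
    RigidTransform,
    StructureModel,
    center_of_mass,
    select_atoms,
    superpose_points,
)
from .synthetic_assembly import (
    DensityMap,
    GAMMA_ANCHOR_LOWER,
    GAMMA_ANCHOR_UPPER,
    GCP_ANCHORS,
    RingParams,
    make_ring,
    synthesize_density,
)


class EmptyMaskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelicalAxis:
    """Origin plus unit direction; direction points from GCP base to gamma layer."""

    origin: np.ndarray
    direction: np.ndarray
    reference: Optional[np.ndarray] = None     # azimuth-zero direction (unit, normal)

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)
        ref = self.reference
        if ref is not None:
            ref = np.asarray(ref, dtype=float).reshape(3)
            ref = ref - (ref @ d) * d
            nr = np.linalg.norm(ref)
            if nr < 1e-12:
                raise ValueError("azimuth reference is parallel to the axis")
            object.__setattr__(self, "reference", ref / nr)

    def frame(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, direction) with e1 the azimuth reference."""
        d = self.direction
        e1 = self.reference
        if e1 is None:
            seed = np.zeros(3)
            seed[int(np.argmin(np.abs(d)))] = 1.0
            e1 = seed - (seed @ d) * d
            e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        return e1, e2, d

    def cylindrical(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(radius, azimuth_deg, height) of points about the axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        e1, e2, d = self.frame()
        x, y, h = pts @ e1, pts @ e2, pts @ d
        return np.hypot(x, y), np.degrees(np.arctan2(y, x)), h

    def in_plane(self, points: np.ndarray) -> np.ndarray:
        """Projection of points onto the plane normal to the axis (3D coords)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        h = pts @ self.direction
        return pts - np.outer(h, self.direction) + self.origin

    def transformed(self, transform: RigidTransform) -> "HelicalAxis":
        ref = None if self.reference is None else transform.rotation @ self.reference
        return HelicalAxis(
            transform.apply(self.origin),
            transform.rotation @ self.direction,
            ref,
        )


@dataclass(frozen=True)
class AnchorSelector:
    component: str            # "gamma_tubulin" | "gcp2".."gcp6"
    residue_number: int
    residue_name: Optional[str] = None


def _default_anchor_centroids() -> List[List[AnchorSelector]]:
    gcp_upper = [AnchorSelector(g, num, nm) for g, ((num, nm), _) in GCP_ANCHORS.items()]
    gcp_lower = [AnchorSelector(g, num, nm) for g, (_, (num, nm)) in GCP_ANCHORS.items()]
    return [
        [AnchorSelector("gamma_tubulin", *GAMMA_ANCHOR_UPPER[::1])],
        [AnchorSelector("gamma_tubulin", *GAMMA_ANCHOR_LOWER[::1])],
        gcp_upper,
        gcp_lower,
    ]


@dataclass
class AnchorSpec:
    """Four centroid definitions over spokes 1-13 fixing the ring axis.

    Defaults: gamma-tubulin Thr145 and Tyr152 centroids, then the two
    per-GCP residue sets (e.g. GCP2 Ser369/Leu216).  The first two centroids
    define the gamma layer, the last two the GCP base; the axis direction is
    oriented from base to layer.
    """

    centroids: List[List[AnchorSelector]] = field(default_factory=_default_anchor_centroids)
    spokes: Sequence[int] = tuple(range(1, 14))
    gamma_layer_centroids: Tuple[int, ...] = (0, 1)
    base_centroids: Tuple[int, ...] = (2, 3)

    def resolve(self, model: StructureModel) -> np.ndarray:
        """(n_centroids, 3) centroid coordinates on the model."""
        if model.annotation is None or not model.annotation.spoke_of_chain:
            raise AnnotationError("model carries no spoke annotation")
        by_spoke: Dict[Tuple[int, str], List[str]] = {}
        for chain, asg in model.annotation.spoke_of_chain.items():
            by_spoke.setdefault((asg.spoke, asg.component), []).append(chain)
        points = []
        for selectors in self.centroids:
            atoms: List[AtomRecord] = []
            for sel in selectors:
                for spoke in self.spokes:
                    chains = by_spoke.get((spoke, sel.component), [])
                    for chain in chains:
                        atoms.extend(
                            select_atoms(
                                model,
                                chain_id=chain,
                                residue_number=sel.residue_number,
                                residue_name=sel.residue_name,
                            )
                        )
            if len(atoms) < 3:
                raise DegenerateConfigurationError(
                    f"anchor centroid resolves to {len(atoms)} atoms (< 3)"
                )
            points.append(center_of_mass(atoms, weighting="mass"))
        return np.asarray(points)


def fit_helical_axis(model: StructureModel, anchors: Optional[AnchorSpec] = None) -> HelicalAxis:
    """Total-least-squares line through the four anchor centroids.

    The origin is the centroid mean; the direction is the leading right
    singular vector of the centred centroid cloud, oriented from the GCP
    base centroids toward the gamma-layer centroids.  The azimuth reference
    is set from the spoke-1 gamma-tubulin centre when annotated.
    """
    anchors = anchors or AnchorSpec()
    pts = anchors.resolve(model)
    uniq = np.unique(np.round(pts, 6), axis=0)
    spread = 0.0
    if len(uniq) >= 2:
        diffs = pts[:, None, :] - pts[None, :, :]
        spread = float(np.sqrt((diffs**2).sum(-1)).max())
    if len(uniq) < 2 or spread < 1.0:
        raise DegenerateConfigurationError(
            f"axis fit degenerate: {len(uniq)} distinct centroids, spread {spread:.2f} A"
        )
    origin = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - origin)
    direction = vt[0]
    gamma_mean = pts[list(anchors.gamma_layer_centroids)].mean(axis=0)
    base_mean = pts[list(anchors.base_centroids)].mean(axis=0)
    if (gamma_mean - base_mean) @ direction < 0:
        direction = -direction
    reference = None
    try:
        g1 = _gamma_com(model, 1)
        ref = g1 - origin
        ref = ref - (ref @ direction) * direction
        if np.linalg.norm(ref) > 1e-9:
            reference = ref
    except AnnotationError:
        pass
    return HelicalAxis(origin, direction, reference)


# ---------------------------------------------------------------------------
# spoke geometry
# ---------------------------------------------------------------------------

def _gamma_com(model: StructureModel, spoke: int, weighting: str = "mass") -> np.ndarray:
    if model.annotation is None:
        raise AnnotationError("model carries no spoke annotation")
    chains = [
        c
        for c, asg in model.annotation.spoke_of_chain.items()
        if asg.spoke == spoke and asg.component == "gamma_tubulin"
    ]
    if not chains:
        raise AnnotationError(f"no gamma-tubulin chain annotated for spoke {spoke}")
    atoms = select_atoms(model, chain_id=chains)
    return center_of_mass(atoms, weighting=weighting)


def _annotated_spokes(model: StructureModel) -> List[int]:
    return sorted(
        {
            a.spoke
            for a in model.annotation.spoke_of_chain.values()
            if a.component == "gamma_tubulin"
        }
    )


@dataclass
class SpokeGeometry:
    """Cylindrical coordinates of gamma-tubulin centres per spoke.

    Increments are defined for spokes 2..n only (vs the previous spoke);
    rotation increments are wrapped to (-180, 180] degrees.
    """

    spokes: np.ndarray
    radius: np.ndarray
    azimuth_deg: np.ndarray
    height: np.ndarray
    pitch_increment: np.ndarray       # NaN for spoke 1
    rotation_increment: np.ndarray    # NaN for spoke 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spoke": self.spokes,
                "radius_A": self.radius,
                "azimuth_deg": self.azimuth_deg,
                "height_A": self.height,
                "pitch_A": self.pitch_increment,
                "rotation_deg": self.rotation_increment,
            }
        )


def spoke_geometry(model: StructureModel, axis: HelicalAxis) -> SpokeGeometry:
    spokes = _annotated_spokes(model)
    if not spokes:
        raise AnnotationError("no gamma-tubulin spokes annotated")
    coms = np.array([_gamma_com(model, s) for s in spokes])
    radius, azim, height = axis.cylindrical(coms)
    pitch = np.full(len(spokes), np.nan)
    rot = np.full(len(spokes), np.nan)
    for k in range(1, len(spokes)):
        pitch[k] = height[k] - height[k - 1]
        d = azim[k] - azim[k - 1]
        rot[k] = (d + 180.0) % 360.0 - 180.0
    return SpokeGeometry(np.asarray(spokes), radius, azim, height, pitch, rot)


def closure_separation(
    model: StructureModel,
    axis: Optional[HelicalAxis] = None,
    spoke_a: int = 1,
    spoke_b: int = 14,
    weighting: str = "mass",
) -> float:
    """In-plane gamma-tubulin separation of two spokes (Angstrom).

    The two centres of mass are projected onto the plane normal to the
    helical axis.  When no axis is given it is fitted, per the ring-axis
    convention, on the hypothetical fully closed reference built from the
    model (the axis of the closed conformation serves all further analyses).
    """
    if axis is None:
        axis = fit_helical_axis(build_closed_reference(model))
    pa = _gamma_com(model, spoke_a, weighting)
    pb = _gamma_com(model, spoke_b, weighting)
    qa, qb = axis.in_plane(np.vstack([pa, pb]))
    return float(np.linalg.norm(qa - qb))


# ---------------------------------------------------------------------------
# closed reference
# ---------------------------------------------------------------------------

def _spoke_chain_roles(model: StructureModel, spoke: int) -> Dict[str, str]:
    """chain -> role ("gamma_tubulin" or "gcp") for one spoke."""
    roles = {}
    for c, asg in model.annotation.spoke_of_chain.items():
        if asg.spoke == spoke:
            roles[c] = "gamma_tubulin" if asg.component == "gamma_tubulin" else "gcp"
    return roles


def _paired_coordinates(
    model: StructureModel, template: StructureModel, spoke: int
) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Coordinates of atoms shared (by role/residue/name) between model and template."""
    m_roles = _spoke_chain_roles(model, spoke)
    t_roles = _spoke_chain_roles(template, spoke)
    if not t_roles:
        raise AnnotationError(f"spoke {spoke} missing in template")
    if not m_roles:
        raise AnnotationError(f"spoke {spoke} missing in model")
    t_index = {}
    for k, a in enumerate(template.atoms):
        role = t_roles.get(a.chain_id)
        if role is not None:
            t_index[(role, a.residue_number, a.name)] = k
    X, Y, idx = [], [], []
    for k, a in enumerate(model.atoms):
        role = m_roles.get(a.chain_id)
        if role is None:
            continue
        j = t_index.get((role, a.residue_number, a.name))
        if j is not None:
            X.append(a.position)
            Y.append(template.atoms[j].position)
        idx.append(k)
    if len(X) < 3:
        raise DegenerateConfigurationError(
            f"spoke {spoke}: fewer than 3 atoms shared with the template"
        )
    return np.asarray(X), np.asarray(Y), idx


def build_closed_reference(
    model: StructureModel,
    closed_template: Optional[Union[StructureModel, RingParams]] = None,
) -> StructureModel:
    """Re-place each spoke of the model at its fully closed template position.

    Every spoke subunit (gamma-tubulin plus GCP markers) is rigid-body
    superposed onto the corresponding spoke of the closed template, so the
    internal geometry of each subunit is untouched.  The default template is
    the analytic closed ring (13-protofilament-compatible helix with spoke
    14 above spoke 1).
    """
    if closed_template is None or isinstance(closed_template, RingParams):
        rp = closed_template or RingParams(closure=1.0)
        if rp.closure != 1.0:
            raise ValueError("closed template requires closure = 1")
        closed_template = make_ring(rp).model
    positions = model.positions.copy()
    spokes = _annotated_spokes(model)
    for spoke in spokes:
        X, Y, idx = _paired_coordinates(model, closed_template, spoke)
        transform, _ = superpose_points(X, Y)
        positions[idx] = transform.apply(positions[idx])
    return model.with_positions(positions)


def distance_to_reference(
    model: StructureModel,
    reference: StructureModel,
    alignment_spokes: Sequence[int] = tuple(range(3, 10)),
    weighting: str = "mass",
) -> pd.Series:
    """Per-spoke gamma-tubulin displacement vs a reference conformation.

    The model is first rigid-body aligned onto the reference using the
    gamma-tubulin and GCP markers of ``alignment_spokes`` (default 3-9);
    the returned values are then 3D Euclidean distances between matched
    gamma-tubulin centres of mass, indexed by spoke.
    """
    X_all, Y_all = [], []
    for spoke in alignment_spokes:
        X, Y, _ = _paired_coordinates(model, reference, spoke)
        X_all.append(X)
        Y_all.append(Y)
    transform, _ = superpose_points(np.vstack(X_all), np.vstack(Y_all))
    aligned = model.transformed(transform)
    spokes = _annotated_spokes(model)
    dists = {}
    for spoke in spokes:
        d = _gamma_com(aligned, spoke, weighting) - _gamma_com(reference, spoke, weighting)
        dists[spoke] = float(np.linalg.norm(d))
    return pd.Series(dists, name="dist_to_reference_A")


# ---------------------------------------------------------------------------
# model-vs-map correlation
# ---------------------------------------------------------------------------

def _near_atom_mask(map_: DensityMap, positions: np.ndarray, radius: float) -> np.ndarray:
    mask = np.zeros(map_.shape, dtype=bool)
    lo = map_.origin
    v = map_.voxel_size
    axes = [map_.voxel_centers_axis(d) for d in range(3)]
    r2 = radius * radius
    for p in positions:
        rng = []
        for d in range(3):
            i0 = max(0, int(math.floor((p[d] - radius - lo[d]) / v)))
            i1 = min(map_.shape[d], int(math.ceil((p[d] + radius - lo[d]) / v)) + 1)
            if i0 >= i1:
                break
            rng.append((i0, i1))
        else:
            dx = axes[0][rng[0][0]:rng[0][1]] - p[0]
            dy = axes[1][rng[1][0]:rng[1][1]] - p[1]
            dz = axes[2][rng[2][0]:rng[2][1]] - p[2]
            d2 = (
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            )
            mask[rng[0][0]:rng[0][1], rng[1][0]:rng[1][1], rng[2][0]:rng[2][1]] |= d2 <= r2
    return mask


def model_map_correlation(model: StructureModel, map_: DensityMap, sigma: float) -> float:
    """Pearson correlation between a map and the model's simulated density.

    The density is simulated on the map's own grid (Gaussian width ``sigma``,
    mass-weighted) and the correlation is evaluated over voxels within
    3 sigma of any atom.
    """
    from .synthetic_assembly import EmptyMapError

    hi = map_.origin + np.array(map_.shape) * map_.voxel_size
    try:
        sim = synthesize_density(model, map_.voxel_size, sigma, box=(map_.origin, hi))
    except EmptyMapError as exc:
        raise EmptyMaskError(str(exc)) from exc
    if sim.shape != map_.shape:
        # guard against rounding in the box -> shape conversion
        s = tuple(min(a, b) for a, b in zip(sim.shape, map_.shape))
        sim_grid = sim.grid[: s[0], : s[1], : s[2]]
        map_grid = map_.grid[: s[0], : s[1], : s[2]]
        mask = _near_atom_mask(DensityMap(map_grid, map_.voxel_size, map_.origin),
                               model.positions, 3.0 * sigma)
    else:
        sim_grid, map_grid = sim.grid, map_.grid
        mask = _near_atom_mask(map_, model.positions, 3.0 * sigma)
    if not mask.any():
        raise EmptyMaskError("no voxels within 3 sigma of any atom")
    a = np.asarray(sim_grid, dtype=float)[mask]
    b = np.asarray(map_grid, dtype=float)[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise EmptyMaskError("zero variance inside the correlation mask")
    return float((a @ b) / denom)
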