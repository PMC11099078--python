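"""Synthetic gamma-TuRC / microtubule assemblies with known ground truth.

Every downstream stage (ring geometry, protofilament lattice building, seam
register analysis, protofilament counting, minus-end profile statistics) is
exercised on the objects built here, so the generators emit their ground
truth (axis, per-spoke coordinates, seam interface, enrichment factor)
alongside the models.

Geometry conventions
--------------------
* The helical axis is z; the minus end is at low z and spoke/protofilament
  indices increase with height (spoke 1 is the lowest spoke of the spiral).
* A protofilament lattice with ``n_pf`` protofilaments, monomer repeat ``a``
  (41 Angstrom) and start number 3 closes exactly when the lateral rise is
  ``3 a / n_pf`` — 9.4615 Angstrom for 13 protofilaments, i.e. the canonical
  13-protofilament microtubule rise at two-decimal rounding.
* The seam is the one lateral interface where the alpha/beta register of the
  two walls differs by one monomer (heterotypic contacts); all other
  interfaces are homotypic (B-lattice).
* Each tubulin monomer is represented by a centre marker atom ``CA`` plus two
  lateral contact markers ``CE``/``CW`` placed so that, in the unperturbed
  lattice, facing contact markers of adjacent protofilaments sit exactly
  ``contact_gap`` apart at matching height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np

from .model_io import (
    AtomRecord,
    PfAssignment,
    SpokeAssignment,
    SpokeMap,
    StructureModel,
)
from .profile_analysis import Profile, ProfileSet

CARBON_MASS = 12.011
MONOMER_REPEAT_A = 41.0
LATERAL_SPACING_A = 52.0       # inter-protofilament chord at the wall mid-plane
DEFAULT_CONTACT_GAP_A = 5.0

#: per-spoke GCP identity of the vertebrate ring (spokes 1-8 alternate
#: GCP2/GCP3; the terminal arc carries GCP4/5/4/6 followed by a GCP2/GCP3 pair)
SPOKE_COMPONENTS: Dict[int, str] = {
    1: "gcp2", 2: "gcp3", 3: "gcp2", 4: "gcp3", 5: "gcp2", 6: "gcp3",
    7: "gcp2", 8: "gcp3", 9: "gcp4", 10: "gcp5", 11: "gcp4", 12: "gcp6",
    13: "gcp2", 14: "gcp3",
}

#: anchor residues used for axis definition, per GCP type: (upper, lower)
GCP_ANCHORS: Dict[str, Tuple[Tuple[int, str], Tuple[int, str]]] = {
    "gcp2": ((369, "SER"), (216, "LEU")),
    "gcp3": ((408, "PRO"), (249, "LEU")),
    "gcp4": ((166, "PRO"), (1, "MET")),
    "gcp5": ((451, "GLU"), (266, "VAL")),
    "gcp6": ((445, "TYR"), (280, "LEU")),
}

GAMMA_ANCHOR_UPPER = (145, "THR")
GAMMA_ANCHOR_LOWER = (152, "TYR")

_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _unit(phi: float) -> np.ndarray:
    return np.array([math.cos(phi), math.sin(phi), 0.0])


def _tangent(phi: float) -> np.ndarray:
    return np.array([-math.sin(phi), math.cos(phi), 0.0])


def default_mt_radius(n_pf: int, lateral_spacing: float = LATERAL_SPACING_A) -> float:
    """Wall radius keeping the inter-protofilament chord at ``lateral_spacing``."""
    return lateral_spacing / (2.0 * math.sin(math.pi / n_pf))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class LatticeParams:
    """Microtubule wall lattice parameters.

    ``lateral_rise`` and ``twist`` are derived, not free: the lattice closes
    exactly because n_pf * lateral_rise = start_number * monomer_repeat.
    """

    n_pf: int = 13
    monomer_repeat: float = MONOMER_REPEAT_A
    start_number: int = 3
    radius: Optional[float] = None
    seam_index: Optional[int] = None        # interface (seam_index, seam_index+1 cyclic)
    n_layers: int = 8
    contact_gap: float = DEFAULT_CONTACT_GAP_A
    skew_deg_per_layer: Optional[float] = None

    def __post_init__(self):
        if self.n_pf < 8:
            raise ValueError("n_pf must be >= 8")
        if self.start_number % 2 != 1:
            raise ValueError("start_number must be odd for a single-seam lattice")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.radius is None:
            self.radius = default_mt_radius(self.n_pf)
        if self.seam_index is None:
            self.seam_index = self.n_pf
        if not 1 <= self.seam_index <= self.n_pf:
            raise ValueError("seam_index must be in 1..n_pf")
        if self.skew_deg_per_layer is None:
            # 13-pf walls are unskewed; other pf numbers carry a gentle
            # supertwist so projections show Moire transitions
            self.skew_deg_per_layer = 0.3 * (13 - self.n_pf)

    @property
    def lateral_rise(self) -> float:
        return self.start_number * self.monomer_repeat / self.n_pf

    @property
    def twist_deg(self) -> float:
        return 360.0 / self.n_pf

    @property
    def contact_offset(self) -> float:
        """Tangential offset of the CE/CW contact markers from the monomer centre."""
        chord = 2.0 * self.radius * math.sin(math.pi / self.n_pf)
        return (chord - self.contact_gap) / (2.0 * math.cos(math.pi / self.n_pf))


@dataclass
class RingParams:
    """14-spoke ring interpolating between open and closed templates.

    ``closure`` = 0 is the open spiral (spokes 1/14 separated in-plane by
    ``open_separation``); ``closure`` = 1 is the microtubule-compatible
    helix in which spoke 14 sits exactly above spoke 1.
    """

    n_spokes: int = 14
    closure: float = 1.0
    open_separation: float = 47.0
    pitch: float = 3.0 * MONOMER_REPEAT_A / 13.0
    radius_profile: Optional[Sequence[float]] = None
    perturbation_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.closure <= 1.0:
            raise ValueError("closure must be within [0, 1]")
        if self.n_spokes != 14:
            raise ValueError("the ring template has 14 spokes")
        if self.radius_profile is None:
            self.radius_profile = [default_mt_radius(13)] * self.n_spokes
        if len(self.radius_profile) != self.n_spokes:
            raise ValueError("radius_profile must have one entry per spoke")


@dataclass
class SyntheticProfileParams:
    """Synthetic minus-end fluorescence line profiles."""

    n_filaments: int = 69
    length_um: float = 8.0
    step_um: float = 0.13
    enrichment: float = 3.0
    end_window_um: float = 0.6
    noise_sigma: float = 0.3
    anchor_um: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be positive")


# ---------------------------------------------------------------------------
# density map container
# ---------------------------------------------------------------------------

class EmptyMapError(ValueError):
    pass


@dataclass
class DensityMap:
    """3D scalar grid with voxel size and origin (Angstrom), indexed [ix, iy, iz]."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("density grid must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.grid.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def to_mrc(self, path: Union[str, Path]) -> None:
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(self.grid, dtype=np.float32))
        nx, ny, nz = self.grid.shape
        ccp4.grid.unit_cell = gemmi.UnitCell(
            nx * self.voxel_size, ny * self.voxel_size, nz * self.voxel_size,
            90.0, 90.0, 90.0,
        )
        ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
        ccp4.update_ccp4_header()
        for word, value in zip((50, 51, 52), self.origin):
            ccp4.set_header_float(word, float(value))
        ccp4.write_ccp4_map(str(path))

    @classmethod
    def from_mrc(cls, path: Union[str, Path]) -> "DensityMap":
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
        grid = np.array(ccp4.grid, copy=True, dtype=np.float64)
        cell = ccp4.grid.unit_cell
        voxel = cell.a / grid.shape[0]
        origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
        return cls(grid, voxel, origin)


# ---------------------------------------------------------------------------
# lattice generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLattice:
    """Generated lattice with its ground truth."""

    model: StructureModel
    params: LatticeParams
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    subunit_centers: Dict[Tuple[int, int], np.ndarray]   # (pf, layer) -> true centre
    seam_interface: Tuple[int, int]
    seed: int
    perturbation_sigma: float


def _lattice_species(params: LatticeParams, pf: int, layer: int) -> str:
    # register offset of one monomer beyond the seam interface makes exactly
    # that interface heterotypic (the cyclic closure interface is handled by
    # the odd start number)
    shift = 1 if (params.seam_index < params.n_pf and pf > params.seam_index) else 0
    return "alpha" if (layer - 1 + shift) % 2 == 0 else "beta"


def make_mt_lattice(
    params: Optional[LatticeParams] = None,
    perturbation_sigma: float = 0.0,
    seed: int = 0,
    phase_deg: float = 0.0,
    z0: float = 0.0,
) -> SyntheticLattice:
    """Build an N-protofilament wall of alpha/beta marker subunits with a seam.

    Subunit (pf i, layer j) sits at azimuth ``(i-1)*twist + (j-1)*skew``
    (plus ``phase_deg``), height ``(i-1)*lateral_rise + (j-1)*monomer_repeat``
    (plus ``z0``) and the wall radius.  ``perturbation_sigma`` adds a rigid
    Gaussian offset per subunit, seeded.
    """
    params = params or LatticeParams()
    rng = np.random.default_rng(seed)
    atoms: List[AtomRecord] = []
    pf_map: Dict[str, PfAssignment] = {}
    centers: Dict[Tuple[int, int], np.ndarray] = {}
    t_off = params.contact_offset
    half_rise = 0.5 * params.lateral_rise
    for i in range(1, params.n_pf + 1):
        chain = _CHAIN_LETTERS[i - 1]
        pf_map[chain] = PfAssignment(pf=i)
        for j in range(1, params.n_layers + 1):
            phi = math.radians(
                phase_deg + (i - 1) * params.twist_deg + (j - 1) * params.skew_deg_per_layer
            )
            z = z0 + (i - 1) * params.lateral_rise + (j - 1) * params.monomer_repeat
            center = params.radius * _unit(phi) + np.array([0.0, 0.0, z])
            noise = rng.normal(0.0, perturbation_sigma, 3) if perturbation_sigma > 0 else np.zeros(3)
            center_n = center + noise
            centers[(i, j)] = center_n
            tau = _tangent(phi)
            species = _lattice_species(params, i, j)
            resname = "ATB" if species == "alpha" else "BTB"
            east = center_n + t_off * tau + np.array([0.0, 0.0, half_rise])
            west = center_n - t_off * tau - np.array([0.0, 0.0, half_rise])
            for name, pos in (("CA", center_n), ("CE", east), ("CW", west)):
                atoms.append(
                    AtomRecord("C", name, resname, j, chain, pos, CARBON_MASS)
                )
    model = StructureModel(atoms, SpokeMap(pf_of_chain=pf_map))
    seam = (params.seam_index, params.seam_index % params.n_pf + 1)
    return SyntheticLattice(
        model=model,
        params=params,
        axis_origin=np.array([0.0, 0.0, z0]),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        subunit_centers=centers,
        seam_interface=seam,
        seed=seed,
        perturbation_sigma=perturbation_sigma,
    )


def displace_protofilament(
    lattice: SyntheticLattice,
    pf: int,
    radial: float = 0.0,
    axial: float = 0.0,
) -> SyntheticLattice:
    """Return a copy with one protofilament rigidly displaced (radially/axially)."""
    chain = _CHAIN_LETTERS[pf - 1]
    phi = math.radians((pf - 1) * lattice.params.twist_deg)
    delta = radial * _unit(phi) + np.array([0.0, 0.0, axial])
    pos = lattice.model.positions
    for k, a in enumerate(lattice.model.atoms):
        if a.chain_id == chain:
            pos[k] = pos[k] + delta
    model = lattice.model.with_positions(pos)
    centers = {
        key: (c + delta if key[0] == pf else c)
        for key, c in lattice.subunit_centers.items()
    }
    return SyntheticLattice(
        model, lattice.params, lattice.axis_origin, lattice.axis_direction,
        centers, lattice.seam_interface, lattice.seed, lattice.perturbation_sigma,
    )


# ---------------------------------------------------------------------------
# ring generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRing:
    model: StructureModel
    params: RingParams
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    azimuth_reference: np.ndarray
    gamma_centers: np.ndarray          # (14, 3) true gamma-tubulin centres
    spoke_azimuth_deg: np.ndarray      # (14,)


_GAMMA_UPPER_LOCAL = np.array([2.0, 1.0, 5.0])    # (radial, tangential, axial)
_GCP_RADIUS = 80.0
_GCP_DROP = 45.0
_GCP_A1_LOCAL = np.array([1.0, -2.0, -10.0])
_GCP_A2_LOCAL = np.array([-1.0, 2.0, -25.0])


def _local(phi: float, local: np.ndarray) -> np.ndarray:
    return local[0] * _unit(phi) + local[1] * _tangent(phi) + local[2] * np.array([0.0, 0.0, 1.0])


def _ring_template_positions(params: RingParams) -> Tuple[np.ndarray, np.ndarray]:
    """(open, closed) gamma-centre positions, shape (14, 3) each."""
    n = params.n_spokes
    radii = np.asarray(params.radius_profile, dtype=float)
    closed = np.zeros((n, 3))
    opened = np.zeros((n, 3))
    # in-plane angular gap of the open spiral fixing the spoke 1-14 separation
    delta = 2.0 * math.asin(min(1.0, params.open_separation / (2.0 * radii[0])))
    theta_closed = 2.0 * math.pi / (n - 1)
    theta_open = (2.0 * math.pi - delta) / (n - 1)
    for k in range(n):
        closed[k] = radii[0] * _unit(k * theta_closed) + np.array([0.0, 0.0, k * params.pitch])
        opened[k] = radii[k] * _unit(k * theta_open) + np.array([0.0, 0.0, k * params.pitch])
    # closed template: spoke 14 exactly above spoke 1 in-plane
    closed[n - 1][:2] = closed[0][:2]
    return opened, closed


def make_ring(params: Optional[RingParams] = None) -> SyntheticRing:
    """Build a 14-spoke ring interpolated between open and closed templates.

    Per-spoke positions interpolate linearly in Cartesian coordinates, so the
    in-plane spoke 1-14 separation equals ``(1 - closure) * open_separation``
    exactly.  Each spoke carries a gamma-tubulin marker chain (upper case)
    and a GCP marker chain (lower case) with the axis anchor residues.
    """
    params = params or RingParams()
    rng = np.random.default_rng(params.seed)
    opened, closed = _ring_template_positions(params)
    c = params.closure
    gamma_centers = (1.0 - c) * opened + c * closed

    atoms: List[AtomRecord] = []
    spoke_map: Dict[str, SpokeAssignment] = {}
    radii0 = float(np.asarray(params.radius_profile, dtype=float)[0])
    azimuths = np.zeros(params.n_spokes)
    actual_centers = np.zeros_like(gamma_centers)
    for k in range(params.n_spokes):
        spoke = k + 1
        g_chain = _CHAIN_LETTERS[k]
        p_chain = _CHAIN_LETTERS[k].lower()
        comp = SPOKE_COMPONENTS[spoke]
        spoke_map[g_chain] = SpokeAssignment(spoke, "gamma_tubulin")
        spoke_map[p_chain] = SpokeAssignment(spoke, comp)
        center = gamma_centers[k].copy()
        if params.perturbation_sigma > 0:
            center = center + rng.normal(0.0, params.perturbation_sigma, 3)
        actual_centers[k] = center
        phi = math.atan2(center[1], center[0])
        azimuths[k] = math.degrees(phi)
        up = GAMMA_ANCHOR_UPPER
        lo = GAMMA_ANCHOR_LOWER
        atoms.append(AtomRecord("C", "CA", "GTB", 1, g_chain, center, CARBON_MASS))
        atoms.append(AtomRecord("C", "CA", up[1], up[0], g_chain,
                                center + _local(phi, _GAMMA_UPPER_LOCAL), CARBON_MASS))
        atoms.append(AtomRecord("C", "CA", lo[1], lo[0], g_chain,
                                center - _local(phi, _GAMMA_UPPER_LOCAL), CARBON_MASS))
        # GCP body at a fixed spoke-local offset so every spoke is an exact
        # rigid copy (required for exact per-subunit superposition)
        gcp_local = np.array([_GCP_RADIUS - radii0, 0.0, -_GCP_DROP])
        gcp_center = center + _local(phi, gcp_local)
        (a1_num, a1_name), (a2_num, a2_name) = GCP_ANCHORS[comp]
        atoms.append(AtomRecord("C", "CA", "GCB", 2, p_chain, gcp_center, CARBON_MASS))
        atoms.append(AtomRecord("C", "CA", a1_name, a1_num, p_chain,
                                gcp_center + _local(phi, _GCP_A1_LOCAL), CARBON_MASS))
        atoms.append(AtomRecord("C", "CA", a2_name, a2_num, p_chain,
                                gcp_center + _local(phi, _GCP_A2_LOCAL), CARBON_MASS))
    model = StructureModel(atoms, SpokeMap(spoke_of_chain=spoke_map))
    return SyntheticRing(
        model=model,
        params=params,
        axis_origin=np.array([0.0, 0.0, 0.0]),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        azimuth_reference=np.array([1.0, 0.0, 0.0]),
        gamma_centers=actual_centers,
        spoke_azimuth_deg=azimuths,
    )


def displace_spoke_gamma(ring: SyntheticRing, spoke: int, delta: np.ndarray) -> SyntheticRing:
    """Copy of the ring with one spoke's gamma-tubulin chain rigidly displaced."""
    chain = _CHAIN_LETTERS[spoke - 1]
    delta = np.asarray(delta, dtype=float)
    pos = ring.model.positions
    for k, a in enumerate(ring.model.atoms):
        if a.chain_id == chain:
            pos[k] = pos[k] + delta
    model = ring.model.with_positions(pos)
    centers = ring.gamma_centers.copy()
    centers[spoke - 1] += delta
    return SyntheticRing(
        model, ring.params, ring.axis_origin, ring.axis_direction,
        ring.azimuth_reference, centers, ring.spoke_azimuth_deg,
    )


def make_capped_assembly(
    lattice_params: Optional[LatticeParams] = None,
    ring_params: Optional[RingParams] = None,
    seed: int = 0,
    perturbation_sigma: float = 0.0,
) -> Tuple[SyntheticLattice, SyntheticRing]:
    """Ring plus emanating lattice in register: pf i sits above spoke i+1.

    With a fully closed ring the gamma-tubulin of spoke i+1 lies directly
    below the first alpha-tubulin of protofilament i (one monomer repeat
    lower), so all gamma-alpha lateral offsets vanish by construction.
    """
    lattice_params = lattice_params or LatticeParams()
    ring_params = ring_params or RingParams(closure=1.0)
    ring = make_ring(ring_params)
    lattice = make_mt_lattice(
        lattice_params,
        perturbation_sigma=perturbation_sigma,
        seed=seed,
        phase_deg=lattice_params.twist_deg,         # pf i over spoke i+1
        z0=ring_params.pitch + lattice_params.monomer_repeat,
    )
    return lattice, ring


#: default protofilament -> spoke correspondence for capped assemblies
def default_spoke_correspondence(n_pf: int = 13) -> Dict[int, int]:
    return {i: i + 1 for i in range(1, n_pf + 1)}


# ---------------------------------------------------------------------------
# density synthesis and projection
# ---------------------------------------------------------------------------

def synthesize_density(
    model: StructureModel,
    voxel_size: float,
    sigma: float,
    box: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    pad: Optional[float] = None,
    cutoff_sigmas: float = 6.0,
) -> DensityMap:
    """Sum of isotropic Gaussians (peak amplitude = atomic mass) on a grid.

    The Gaussians are unnormalized (molmap convention): the map integral is
    ``sum_i m_i (2 pi)^{3/2} sigma^3``.  ``box`` fixes the extents (min, max
    corners in Angstrom); by default the model is padded by ``pad`` (4 sigma).
    """
    if len(model) == 0:
        raise EmptyMapError("cannot synthesize a map from an empty model")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos = model.positions
    masses = model.masses
    if box is None:
        p = 4.0 * sigma if pad is None else pad
        lo = pos.min(axis=0) - p
        hi = pos.max(axis=0) + p
    else:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    inside = np.all((pos >= lo - 4 * sigma) & (pos <= hi + 4 * sigma), axis=1)
    if not inside.any():
        raise EmptyMapError("box excludes all atoms")
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    grid = np.zeros(shape, dtype=np.float64)
    axes = [lo[d] + voxel_size * np.arange(shape[d]) for d in range(3)]
    cut = cutoff_sigmas * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for p_atom, m in zip(pos[inside], masses[inside]):
        sl, gs = [], []
        for d in range(3):
            i0 = max(0, int(np.floor((p_atom[d] - cut - lo[d]) / voxel_size)))
            i1 = min(shape[d], int(np.ceil((p_atom[d] + cut - lo[d]) / voxel_size)) + 1)
            if i0 >= i1:
                break
            x = axes[d][i0:i1] - p_atom[d]
            sl.append(slice(i0, i1))
            gs.append(np.exp(-x * x * inv2s2))
        else:
            grid[sl[0], sl[1], sl[2]] += m * (
                gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
            )
    return DensityMap(grid, voxel_size, lo)


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def project_image(
    model_or_map: Union[StructureModel, DensityMap],
    view_axis: str = "y",
    pixel_size: float = 2.54,
    sigma: float = 6.0,
    box: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    depth_blur: float = 0.0,
) -> np.ndarray:
    """Line-integral projection along ``view_axis``.

    For a map: sum of voxel values along the axis times the voxel size.
    For a model: analytic 2D Gaussian splat with the same total (the line
    integral of each 3D Gaussian is ``m sqrt(2 pi) sigma`` at its footprint).
    Image rows run along the remaining axis of highest index (z for the
    default side view), columns along the other.

    ``depth_blur`` > 0 widens each atom's footprint linearly with its depth
    along the view axis (up to ``1 + depth_blur`` times ``sigma``),
    emulating the defocus gradient that renders the far wall of a filament
    blurrier than the near wall in micrographs; the per-atom integral is
    preserved.
    """
    ax = _AXIS_INDEX[view_axis]
    if isinstance(model_or_map, DensityMap):
        # summing over the view axis leaves (lower, higher) remaining axes;
        # transpose so rows run along the higher axis (z for side views)
        return np.asarray(
            model_or_map.grid.sum(axis=ax).T * model_or_map.voxel_size, dtype=float
        )

    model = model_or_map
    if len(model) == 0:
        raise EmptyMapError("cannot project an empty model")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    keep = [d for d in range(3) if d != ax]
    row_axis, col_axis = keep[1], keep[0]     # rows along the higher axis (z side-on)
    pos = model.positions
    masses = model.masses
    if box is None:
        p = 4.0 * sigma
        lo = pos.min(axis=0) - p
        hi = pos.max(axis=0) + p
    else:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    nrow = max(1, int(np.ceil((hi[row_axis] - lo[row_axis]) / pixel_size)))
    ncol = max(1, int(np.ceil((hi[col_axis] - lo[col_axis]) / pixel_size)))
    img = np.zeros((nrow, ncol))
    rows = lo[row_axis] + pixel_size * np.arange(nrow)
    cols = lo[col_axis] + pixel_size * np.arange(ncol)
    depth = pos[:, ax]
    d_lo, d_hi = depth.min(), depth.max()
    d_span = max(d_hi - d_lo, 1e-9)
    for p_atom, m, dep in zip(pos, masses, depth):
        s = sigma * (1.0 + depth_blur * (dep - d_lo) / d_span)
        cut = 6.0 * s
        inv2s2 = 1.0 / (2.0 * s * s)
        # line integral of the 3D Gaussian, then unit-integral 2D footprint
        amp = m * math.sqrt(2.0 * math.pi) * sigma * (sigma / s) ** 2
        r0 = max(0, int(np.floor((p_atom[row_axis] - cut - lo[row_axis]) / pixel_size)))
        r1 = min(nrow, int(np.ceil((p_atom[row_axis] + cut - lo[row_axis]) / pixel_size)) + 1)
        c0 = max(0, int(np.floor((p_atom[col_axis] - cut - lo[col_axis]) / pixel_size)))
        c1 = min(ncol, int(np.ceil((p_atom[col_axis] + cut - lo[col_axis]) / pixel_size)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        gr = np.exp(-((rows[r0:r1] - p_atom[row_axis]) ** 2) * inv2s2)
        gc = np.exp(-((cols[c0:c1] - p_atom[col_axis]) ** 2) * inv2s2)
        img[r0:r1, c0:c1] += amp * gr[:, None] * gc[None, :]
    return img


# ---------------------------------------------------------------------------
# fluorescence profiles
# ---------------------------------------------------------------------------

def make_fluorescence_profiles(params: Optional[SyntheticProfileParams] = None) -> ProfileSet:
    """Per-filament three-channel intensity traces with a minus-end enrichment.

    The probe channel is a unit lattice baseline scaled by ``enrichment``
    within ``end_window_um`` of the minus-end anchor, plus Gaussian noise;
    the gamma-TuRC channel is a Gaussian peak at the anchor; the microtubule
    channel is flat.  Ground-truth enrichment and anchors ride along in the
    returned :class:`ProfileSet`.
    """
    params = params or SyntheticProfileParams()
    rng = np.random.default_rng(params.seed)
    n_samples = int(math.floor(params.length_um / params.step_um)) + 1
    positions = params.step_um * np.arange(n_samples)
    profiles: List[Profile] = []
    for i in range(params.n_filaments):
        replicate = i % params.n_replicates + 1
        in_window = np.abs(positions - params.anchor_um) <= params.end_window_um
        probe = np.where(in_window, params.enrichment, 1.0).astype(float)
        if params.noise_sigma > 0:
            probe = probe + rng.normal(0.0, params.noise_sigma, n_samples)
        turc = np.exp(-((positions - params.anchor_um) ** 2) / (2 * 0.2**2))
        if params.noise_sigma > 0:
            turc = turc + rng.normal(0.0, 0.2 * params.noise_sigma, n_samples)
        mt = np.ones(n_samples)
        if params.noise_sigma > 0:
            mt = mt + rng.normal(0.0, 0.2 * params.noise_sigma, n_samples)
        profiles.append(
            Profile(
                filament_id=f"mt{i + 1:03d}",
                positions_um=positions,
                mt=mt,
                turc=turc,
                probe=probe,
                replicate=replicate,
                anchor_um=params.anchor_um,
            )
        )
    return ProfileSet(
        profiles=profiles,
        step_um=params.step_um,
        true_enrichment=params.enrichment,
        end_window_um=params.end_window_um,
    )
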