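"""Protofilament-wise model building for the capped microtubule minus end.

The minus-end wall is modelled in three steps, each implemented here as an
independent operator:

1. :func:`dock_rigid_body` — local rigid-body search maximizing the
   model-vs-map cross-correlation over a translation/rotation grid, with
   quadratic sub-grid refinement on the translation axes;
2. :func:`optimize_contact_rotation` — each protofilament is rotated about
   its own axis to minimize the summed lateral contact-pair distance to its
   already placed neighbour, swept until convergence;
3. :func:`axial_register` — the position along the protofilament's own axis
   is scanned against the density; the cross-correlation profile shows one
   peak per tubulin register and is resolved by simultaneous multi-Gaussian
   fitting, the chosen shift being the mean of the highest-amplitude peak
   (a ``nearest`` mode instead picks the peak closest to the docked
   position).

:func:`lattice_metrics` then reports the per-protofilament distance from the
microtubule axis (fitted through per-layer alpha-tubulin anchor centroids)
and the lateral gamma-tubulin/alpha-tubulin offsets against the ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .model_io import (
    AnnotationError,
    AtomRecord,
    RigidTransform,
    StructureModel,
    center_of_mass,
    select_atoms,
)
from .ring_geometry import HelicalAxis, model_map_correlation
from .synthetic_assembly import DensityMap


class NoFitError(RuntimeError):
    pass


class RegistrationFailure(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# lattice container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSpec:
    """Atoms defining the lateral inter-protofilament contact.

    ``east`` faces the next protofilament (ascending index), ``west`` the
    previous one.  Defaults are the synthetic contact markers; for atomistic
    tubulin models use the canonical contact residues (beta-tubulin Tyr283
    facing Ala56) via the residue fields.
    """

    east_name: str = "CE"
    west_name: str = "CW"
    east_residue: Optional[Tuple[int, str]] = None   # e.g. (283, "TYR")
    west_residue: Optional[Tuple[int, str]] = None   # e.g. (56, "ALA")


class LatticeModel:
    """Ordered protofilaments of alpha/beta subunits over a StructureModel.

    Subunits are indexed by (pf, layer) with layers counted from the minus
    end; the protofilament annotation comes from the model's SpokeMap
    (chain-level pf assignment, species/layer at chain or residue level).
    """

    def __init__(
        self,
        model: StructureModel,
        mt_axis: Optional[HelicalAxis] = None,
        spoke_correspondence: Optional[Dict[int, int]] = None,
        monomer_repeat: Optional[float] = None,
        lateral_rise: Optional[float] = None,
    ):
        if model.annotation is None or not model.annotation.pf_of_chain:
            raise AnnotationError("model carries no protofilament annotation")
        self.model = model
        self.mt_axis = mt_axis or HelicalAxis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        self.spoke_correspondence = spoke_correspondence
        self.monomer_repeat = monomer_repeat
        self.lateral_rise = lateral_rise
        self._index()

    def _index(self) -> None:
        subunits: Dict[Tuple[int, int], List[int]] = {}
        species: Dict[Tuple[int, int], str] = {}
        ann = self.model.annotation
        for k, a in enumerate(self.model.atoms):
            asg = ann.pf_of_chain.get(a.chain_id)
            if asg is None:
                continue
            layer = asg.layer if asg.layer is not None else a.residue_number
            sp = asg.species
            if sp is None:
                if a.residue_name == "ATB":
                    sp = "alpha"
                elif a.residue_name == "BTB":
                    sp = "beta"
                else:
                    raise AnnotationError(
                        f"chain {a.chain_id}: species neither annotated nor encoded "
                        f"in residue name {a.residue_name!r}"
                    )
            key = (asg.pf, layer)
            subunits.setdefault(key, []).append(k)
            species[key] = sp
        self.subunits = subunits
        self.species = species
        self.pf_indices = sorted({pf for pf, _ in subunits})
        self.layers_of: Dict[int, List[int]] = {}
        for pf, layer in subunits:
            self.layers_of.setdefault(pf, []).append(layer)
        for pf in self.layers_of:
            self.layers_of[pf].sort()

    @property
    def n_pf(self) -> int:
        return len(self.pf_indices)

    def replaced(self, model: StructureModel) -> "LatticeModel":
        return LatticeModel(
            model, self.mt_axis, self.spoke_correspondence,
            self.monomer_repeat, self.lateral_rise,
        )

    def subunit_atoms(self, pf: int, layer: int) -> List[AtomRecord]:
        return [self.model.atoms[k] for k in self.subunits[(pf, layer)]]

    def subunit_center(self, pf: int, layer: int) -> np.ndarray:
        atoms = self.subunit_atoms(pf, layer)
        markers = [a for a in atoms if a.name == "CA"]
        return center_of_mass(markers or atoms, weighting="mass")

    def subunit_height(self, pf: int, layer: int) -> float:
        c = self.subunit_center(pf, layer) - self.mt_axis.origin
        return float(c @ self.mt_axis.direction)

    def pf_atom_indices(self, pf: int) -> List[int]:
        out = []
        for (p, layer), idx in self.subunits.items():
            if p == pf:
                out.extend(idx)
        return sorted(out)

    def pf_model(self, pf: int) -> StructureModel:
        return self.model.subset([self.model.atoms[k] for k in self.pf_atom_indices(pf)])

    def pf_axis_point(self, pf: int) -> np.ndarray:
        centers = np.array([self.subunit_center(pf, j) for j in self.layers_of[pf]])
        return centers.mean(axis=0)

    def contact_atom(self, pf: int, layer: int, spec: ContactSpec, side: str) -> Optional[AtomRecord]:
        atoms = self.subunit_atoms(pf, layer)
        if side == "east":
            name, residue = spec.east_name, spec.east_residue
        else:
            name, residue = spec.west_name, spec.west_residue
        if residue is not None:
            num, rname = residue
            hits = [a for a in atoms if a.residue_number == num and a.residue_name == rname]
        else:
            hits = [a for a in atoms if a.name == name]
        return hits[0] if hits else None

    def interfaces(self) -> List[Tuple[int, int]]:
        pfs = self.pf_indices
        return [(pfs[k], pfs[(k + 1) % len(pfs)]) for k in range(len(pfs))]

    def estimated_monomer_repeat(self) -> float:
        if self.monomer_repeat is not None:
            return self.monomer_repeat
        gaps = []
        for pf in self.pf_indices:
            h = [self.subunit_height(pf, j) for j in self.layers_of[pf]]
            gaps.extend(np.diff(h))
        return float(np.median(gaps))


# ---------------------------------------------------------------------------
# rigid-body docking
# ---------------------------------------------------------------------------

def _quadratic_refine(f_m: float, f_0: float, f_p: float, step: float) -> float:
    """Vertex offset of a parabola through three equally spaced samples."""
    denom = f_m - 2.0 * f_0 + f_p
    if denom <= 1e-15:      # not locally convex: keep the grid point
        return 0.0
    return float(np.clip(0.5 * step * (f_m - f_p) / denom, -step, step))


def dock_rigid_body(
    subunit: StructureModel,
    map_: DensityMap,
    initial_pose: Optional[RigidTransform] = None,
    translation_range: float = 3.0,
    translation_step: float = 1.0,
    rotation_range: float = 6.0,
    rotation_step: float = 2.0,
    rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
    sigma: float = 6.0,
    cc_floor: float = 0.2,
) -> Tuple[RigidTransform, float]:
    """Local rigid-body fit of a subunit into a density map.

    The pose grid covers translations of ±``translation_range`` per axis
    and rotations of ±``rotation_range`` about ``rotation_axis`` through the
    subunit's centre of mass; the best grid pose is refined by quadratic
    interpolation along each translation axis.  Deterministic for fixed
    inputs; raises :class:`NoFitError` when the best correlation is below
    ``cc_floor``.
    """
    if translation_range <= 0 or translation_step <= 0:
        raise ValueError("translation search range and step must be positive")
    initial_pose = initial_pose or RigidTransform.identity()
    base = subunit.transformed(initial_pose)
    com = center_of_mass(base.atoms)
    n_t = int(round(translation_range / translation_step))
    t_vals = translation_step * np.arange(-n_t, n_t + 1)
    if rotation_range > 0 and rotation_step > 0:
        n_r = int(round(rotation_range / rotation_step))
        r_vals = rotation_step * np.arange(-n_r, n_r + 1)
    else:
        r_vals = np.array([0.0])

    from .ring_geometry import EmptyMaskError

    def cc_of(shift: np.ndarray, angle: float) -> float:
        T = RigidTransform.identity() if angle == 0 else RigidTransform.about_axis(
            rotation_axis, angle, com
        )
        moved = base.transformed(T).with_positions(
            base.transformed(T).positions + shift
        )
        try:
            return model_map_correlation(moved, map_, sigma)
        except EmptyMaskError:
            return -1.0          # pose entirely outside the map

    best = (-2.0, np.zeros(3), 0.0)
    cc_cache: Dict[Tuple[float, float, float, float], float] = {}
    for angle in r_vals:
        for dx in t_vals:
            for dy in t_vals:
                for dz in t_vals:
                    shift = np.array([dx, dy, dz])
                    cc = cc_of(shift, angle)
                    cc_cache[(dx, dy, dz, angle)] = cc
                    if cc > best[0]:
                        best = (cc, shift, angle)
    cc_best, shift_best, ang_best = best
    if cc_best < cc_floor:
        raise NoFitError(f"best correlation {cc_best:.3f} below floor {cc_floor}")
    # quadratic sub-grid refinement along each translation axis
    refined = shift_best.astype(float).copy()
    for d in range(3):
        lo = shift_best.copy(); lo[d] -= translation_step
        hi = shift_best.copy(); hi[d] += translation_step
        key_lo = (lo[0], lo[1], lo[2], ang_best)
        key_hi = (hi[0], hi[1], hi[2], ang_best)
        f_lo = cc_cache.get(key_lo, cc_of(lo, ang_best))
        f_hi = cc_cache.get(key_hi, cc_of(hi, ang_best))
        refined[d] += _quadratic_refine(-f_lo, -cc_best, -f_hi, translation_step)
    rot = RigidTransform.about_axis(rotation_axis, ang_best, com)
    shift_T = RigidTransform(np.eye(3), refined)
    pose = shift_T.compose(rot).compose(initial_pose)
    cc_final = model_map_correlation(subunit.transformed(pose), map_, sigma)
    if cc_final < cc_best - 1e-9:      # refinement must not make things worse
        pose = RigidTransform(np.eye(3), shift_best).compose(rot).compose(initial_pose)
        cc_final = cc_best
    return pose, float(cc_final)


# ---------------------------------------------------------------------------
# contact rotation
# ---------------------------------------------------------------------------

def _contact_positions(
    lattice: LatticeModel, pf: int, spec: ContactSpec, side: str
) -> np.ndarray:
    """(n, 3) contact-atom positions of one protofilament side, layer order."""
    out = []
    for layer in lattice.layers_of[pf]:
        atom = lattice.contact_atom(pf, layer, spec, side)
        if atom is not None:
            out.append(atom.position)
    if not out:
        raise AnnotationError(f"pf {pf}: no {side} contact atoms resolvable")
    return np.asarray(out)


def _facing_pair_distance(east: np.ndarray, west: np.ndarray,
                          facing_cut: float = 20.5) -> float:
    """Mean nearest east-west distance over facing layers.

    Layers without a facing partner (nearest west farther than half a
    monomer repeat, as at the top of the cyclic closure interface) are
    excluded; if nothing faces, the overall minimum is returned.
    """
    d = np.linalg.norm(east[:, None, :] - west[None, :, :], axis=2).min(axis=1)
    facing = d[d <= facing_cut]
    return float(facing.mean()) if len(facing) else float(d.min())


def interface_contact_distance(
    lattice: LatticeModel, pf_a: int, pf_b: int, spec: Optional[ContactSpec] = None
) -> float:
    """Mean east(a)-to-nearest-west(b) contact distance over facing layers."""
    spec = spec or ContactSpec()
    east = _contact_positions(lattice, pf_a, spec, "east")
    west = _contact_positions(lattice, pf_b, spec, "west")
    return _facing_pair_distance(east, west)


def _rotate_about(points: np.ndarray, direction: np.ndarray, center: np.ndarray,
                  angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * direction).as_matrix()
    return (points - center) @ R.T + center


def optimize_contact_rotation(
    lattice: LatticeModel,
    contacts: Optional[ContactSpec] = None,
    tol_deg: float = 0.01,
    max_sweeps: int = 100,
    coarse_step_deg: float = 1.0,
) -> Tuple[LatticeModel, Dict[int, float]]:
    """Rotate each protofilament about its own axis to restore lateral contacts.

    Sweeps ascend the protofilament index; on the first sweep each
    protofilament minimizes its contact distance to the already placed
    lower-index neighbour, thereafter to both cyclic neighbours.  Iteration
    stops when no protofilament moves by more than ``tol_deg`` in a sweep;
    ties break toward the smallest rotation magnitude.  Returns the rotated
    lattice and the total applied angle per protofilament.
    """
    contacts = contacts or ContactSpec()
    if lattice.n_pf < 2:
        raise ValueError("contact optimization needs >= 2 protofilaments")
    direction = lattice.mt_axis.direction / np.linalg.norm(lattice.mt_axis.direction)
    pfs = lattice.pf_indices
    east = {pf: _contact_positions(lattice, pf, contacts, "east") for pf in pfs}
    west = {pf: _contact_positions(lattice, pf, contacts, "west") for pf in pfs}
    centers = {pf: lattice.pf_axis_point(pf) for pf in pfs}
    total_angle = {pf: 0.0 for pf in pfs}

    pair_dist = _facing_pair_distance

    def objective(pf: int, neighbors: List[int], angle: float) -> float:
        e = _rotate_about(east[pf], direction, centers[pf], angle) if angle else east[pf]
        w = _rotate_about(west[pf], direction, centers[pf], angle) if angle else west[pf]
        total = 0.0
        for nb in neighbors:
            k_pf, k_nb = pfs.index(pf), pfs.index(nb)
            if (k_pf + 1) % len(pfs) == k_nb:      # nb succeeds pf
                total += pair_dist(e, west[nb])
            else:                                   # nb precedes pf
                total += pair_dist(east[nb], w)
        return total

    for sweep in range(max_sweeps):
        moved = 0.0
        for k, pf in enumerate(pfs):
            prev_pf, next_pf = pfs[k - 1], pfs[(k + 1) % len(pfs)]
            if sweep == 0:
                neighbors = [prev_pf] if k > 0 else []
            else:
                neighbors = [prev_pf, next_pf]
            if not neighbors:
                continue
            coarse = np.arange(-180.0, 180.0, coarse_step_deg)
            vals = np.array([objective(pf, neighbors, a) for a in coarse])
            order = np.lexsort((np.abs(coarse), np.round(vals, 9)))
            a0 = float(coarse[order[0]])
            res = optimize.minimize_scalar(
                lambda a: objective(pf, neighbors, a),
                bounds=(a0 - 1.5 * coarse_step_deg, a0 + 1.5 * coarse_step_deg),
                method="bounded",
                options={"xatol": tol_deg / 20.0},
            )
            best_angle = float(res.x)
            if objective(pf, neighbors, 0.0) <= res.fun:
                best_angle = 0.0
            if best_angle != 0.0:
                east[pf] = _rotate_about(east[pf], direction, centers[pf], best_angle)
                west[pf] = _rotate_about(west[pf], direction, centers[pf], best_angle)
                total_angle[pf] += best_angle
            moved = max(moved, abs(best_angle))
        # converge well inside tol so accumulated angles settle at the register
        if sweep > 0 and moved <= 0.1 * tol_deg:
            break
    else:
        raise ConvergenceError(
            f"contact rotation did not converge within {max_sweeps} sweeps "
            f"(last sweep moved {moved:.4f} deg)"
        )
    # apply the accumulated rotations to the full model once
    pos = lattice.model.positions
    for pf in pfs:
        if total_angle[pf] != 0.0:
            idx = lattice.pf_atom_indices(pf)
            pos[idx] = _rotate_about(pos[idx], direction, centers[pf], total_angle[pf])
    return lattice.replaced(lattice.model.with_positions(pos)), total_angle


# ---------------------------------------------------------------------------
# axial registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPeak:
    mean: float
    sigma: float
    amplitude: float


@dataclass
class RegistrationProfile:
    shifts: np.ndarray
    cc: np.ndarray
    gaussians: List[GaussianPeak]
    baseline: float
    chosen_shift: float
    mode: str = "max_amplitude"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shift_A": self.shifts, "cc": self.cc})


def _gauss_sum(x: np.ndarray, params: np.ndarray, baseline: float) -> np.ndarray:
    y = np.full_like(x, baseline, dtype=float)
    for k in range(0, len(params), 3):
        amp, mu, sig = params[k : k + 3]
        y = y + amp * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))
    return y


def fit_gaussian_mixture(
    x: np.ndarray, y: np.ndarray, peak_positions: Sequence[float],
    init_sigma: float = 8.0,
) -> Tuple[List[GaussianPeak], float]:
    """Simultaneous least-squares fit of K Gaussians plus a constant baseline."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    base0 = float(np.min(y))
    p0 = [base0]
    for mu in peak_positions:
        amp0 = float(np.interp(mu, x, y) - base0)
        p0.extend([max(amp0, 1e-3), float(mu), init_sigma])
    p0 = np.asarray(p0)

    def resid(p):
        return _gauss_sum(x, p[1:], p[0]) - y

    n_peaks = len(peak_positions)
    lo = [-np.inf] + [0.0, x.min(), 0.5] * n_peaks
    hi = [np.inf] + [np.inf, x.max(), (x.max() - x.min())] * n_peaks
    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RegistrationFailure(
            f"Gaussian fit did not converge (residual {np.linalg.norm(sol.fun):.3g})"
        )
    baseline = float(sol.x[0])
    # parameters are stored (amp, mu, sig) per peak after the baseline
    peaks = [
        GaussianPeak(mean=float(sol.x[k + 1]), sigma=float(sol.x[k + 2]),
                     amplitude=float(sol.x[k]))
        for k in range(1, len(sol.x), 3)
    ]
    return peaks, baseline


def axial_register(
    pf: StructureModel,
    map_: DensityMap,
    axis: HelicalAxis,
    shift_range: float = 60.0,
    step: float = 1.0,
    sigma: float = 6.0,
    cc_floor: float = 0.1,
    mode: str = "max_amplitude",
    dock_shift: float = 0.0,
) -> RegistrationProfile:
    """Axial registration of a protofilament by multi-Gaussian CC fitting.

    The protofilament is displaced along ``axis`` over ±``shift_range`` and
    the model-vs-map correlation recorded at each step; local maxima above
    half the global maximum seed simultaneous Gaussian fits.  The chosen
    shift is the mean of the highest-amplitude Gaussian (``max_amplitude``)
    or of the Gaussian nearest ``dock_shift`` (``nearest``).
    """
    if shift_range < 41.0:
        raise ValueError("shift range must cover at least one monomer repeat (41 A)")
    shifts = np.arange(-shift_range, shift_range + 0.5 * step, step)
    d = axis.direction
    base_pos = pf.positions
    cc = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        cc[i] = model_map_correlation(pf.with_positions(base_pos + s * d), map_, sigma)
    top = cc.max()
    if top < cc_floor:
        raise RegistrationFailure(f"no correlation above floor {cc_floor}")
    height = 0.5 * top if top > 0 else top - 0.5 * abs(top)
    idx, _ = signal.find_peaks(cc, height=height)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(cc))])
    peaks, baseline = fit_gaussian_mixture(shifts, cc, shifts[idx], init_sigma=8.0)
    if mode == "max_amplitude":
        chosen = max(peaks, key=lambda g: g.amplitude)
    elif mode == "nearest":
        chosen = min(peaks, key=lambda g: abs(g.mean - dock_shift))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RegistrationProfile(shifts, cc, peaks, baseline, float(chosen.mean), mode)


# ---------------------------------------------------------------------------
# microtubule metrics
# ---------------------------------------------------------------------------

def mt_axis_from_layers(
    lattice: LatticeModel,
    anchor_residue: Tuple[int, str] = (15, "GLN"),
) -> HelicalAxis:
    """Total-least-squares MT axis through per-layer anchor centroids.

    The anchor defaults to alpha-tubulin Gln15; marker lattices without that
    residue fall back to the subunit centre markers.
    """
    layers = sorted({layer for _, layer in lattice.subunits})
    centroids = []
    for layer in layers:
        pts = []
        for pf in lattice.pf_indices:
            if layer not in lattice.layers_of[pf]:
                continue
            atoms = lattice.subunit_atoms(pf, layer)
            hits = [
                a for a in atoms
                if a.residue_number == anchor_residue[0] and a.residue_name == anchor_residue[1]
            ]
            if not hits:
                hits = [a for a in atoms if a.name == "CA"] or atoms
            pts.append(center_of_mass(hits))
        if pts:
            centroids.append(np.mean(pts, axis=0))
    centroids = np.asarray(centroids)
    if len(centroids) < 2:
        raise AnnotationError("need >= 2 layers to fit the MT axis")
    origin = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - origin)
    direction = vt[0]
    if (centroids[-1] - centroids[0]) @ direction < 0:
        direction = -direction
    ref = lattice.subunit_center(lattice.pf_indices[0], layers[0]) - origin
    ref = ref - (ref @ direction) * direction
    reference = ref if np.linalg.norm(ref) > 1e-9 else None
    return HelicalAxis(origin, direction, reference)


@dataclass
class LatticeMetrics:
    radii: pd.Series                 # by pf, Angstrom from the MT axis
    gamma_alpha_offsets: pd.Series   # by spoke, in-plane Angstrom
    axis: HelicalAxis

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"radius_A": self.radii})
        df.index.name = "pf"
        return df


def lattice_metrics(
    lattice: LatticeModel,
    ring: Optional[StructureModel] = None,
    anchor_residue: Tuple[int, str] = (15, "GLN"),
    axis: Optional[HelicalAxis] = None,
) -> LatticeMetrics:
    """Per-protofilament radius and gamma-alpha lateral offsets (Fig-style).

    The radius is the mean in-plane distance of a protofilament's subunit
    centres from the MT axis.  When a ring model with spoke annotation is
    given, the in-plane offset between each spoke's gamma-tubulin centre of
    mass and the first alpha-tubulin of its corresponding protofilament is
    reported (requires ``lattice.spoke_correspondence``).  ``axis`` fixes
    the MT axis instead of fitting it from the (possibly perturbed) layers.
    """
    if axis is None:
        axis = mt_axis_from_layers(lattice, anchor_residue)
    radii = {}
    for pf in lattice.pf_indices:
        centers = np.array([lattice.subunit_center(pf, j) for j in lattice.layers_of[pf]])
        r, _, _ = axis.cylindrical(centers)
        radii[pf] = float(np.mean(r))
    offsets = {}
    if ring is not None:
        from .ring_geometry import _gamma_com
        corr = lattice.spoke_correspondence
        if corr is None:
            raise AnnotationError("lattice carries no pf -> spoke correspondence")
        for pf in lattice.pf_indices:
            alphas = [
                j for j in lattice.layers_of[pf] if lattice.species[(pf, j)] == "alpha"
            ]
            if not alphas:
                raise AnnotationError(f"pf {pf}: no alpha-tubulin layer annotated")
            first_alpha = lattice.subunit_center(pf, min(alphas))
            spoke = corr[pf]
            gamma = _gamma_com(ring, spoke)
            pa, pb = axis.in_plane(np.vstack([first_alpha, gamma]))
            offsets[spoke] = float(np.linalg.norm(pa - pb))
    return LatticeMetrics(
        pd.Series(radii, name="radius_A"),
        pd.Series(offsets, name="gamma_alpha_offset_A"),
        axis,
    )
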