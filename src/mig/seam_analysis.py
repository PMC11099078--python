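"""Lateral contact classification, seam location and seam-formation register.

A 13-protofilament B-lattice microtubule has homotypic (alpha-alpha /
beta-beta) lateral contacts at every interface except one, the seam, where
the alpha/beta register of the two walls differs by one monomer.  At a
capped minus end the wall can be irregular: protofilaments may lack lateral
contacts altogether (gaps), and the seam position is then predicted from
which protofilament is isolated plus the axial movements needed to reach a
seam-compatible register.

Register arithmetic
-------------------
Axial positions are reduced to per-protofilament residuals after removing
the helical ramp (one lateral rise per protofilament, monomer repeat within
a protofilament).  Relative to a neighbour, the homotypic register repeats
every dimer (two monomer repeats) and the heterotypic (seam) register sits
one monomer away — except across the cyclic closure interface of an
odd-start lattice, where three monomers of built-in offset swap the two
registers.  This parity bookkeeping is what makes the two seam options of a
given protofilament generally require different movements (they differ by
about one monomer repeat, not by a common value modulo 41 Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model_io import AnnotationError
from .protofilament_lattice import ContactSpec, LatticeModel, _contact_positions


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contact classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LateralContact:
    interface: Tuple[int, int]      # (pf i, pf i+1 cyclic)
    type: str                       # "homotypic" | "heterotypic" | "gap"
    contact_distance: float         # minimal contact-pair distance, Angstrom
    gap_distance: float             # distance minus threshold (gaps only, else 0)
    axial_offset: float             # signed height difference of the facing pair


def classify_lateral_contacts(
    lattice: LatticeModel,
    threshold: float = 12.0,
    contacts: Optional[ContactSpec] = None,
) -> List[LateralContact]:
    """Classify every cyclic lateral interface of the lattice.

    The minimal contact-pair distance over facing subunit layers decides gap
    status; the species of the closest facing pair decides homotypic vs
    heterotypic.  The signed axial offset (height of the higher-index
    partner minus the lower) is recorded for the pitch estimate.
    """
    contacts = contacts or ContactSpec()
    out = []
    for pf_a, pf_b in lattice.interfaces():
        layers_a = lattice.layers_of[pf_a]
        layers_b = lattice.layers_of[pf_b]
        east = _contact_positions(lattice, pf_a, contacts, "east")
        west = _contact_positions(lattice, pf_b, contacts, "west")
        d = np.linalg.norm(east[:, None, :] - west[None, :, :], axis=2)
        ia, ib = np.unravel_index(int(np.argmin(d)), d.shape)
        la, lb = layers_a[ia], layers_b[ib]
        dist = float(d[ia, ib])
        sp_a = lattice.species[(pf_a, la)]
        sp_b = lattice.species[(pf_b, lb)]
        h_a = lattice.subunit_height(pf_a, la)
        h_b = lattice.subunit_height(pf_b, lb)
        if dist > threshold:
            ctype, gap = "gap", dist - threshold
        else:
            ctype, gap = ("homotypic" if sp_a == sp_b else "heterotypic"), 0.0
        out.append(LateralContact((pf_a, pf_b), ctype, dist, gap, h_b - h_a))
    return out


def contacts_frame(contacts: List[LateralContact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pf_a": c.interface[0],
                "pf_b": c.interface[1],
                "type": c.type,
                "contact_distance_A": c.contact_distance,
                "gap_distance_A": c.gap_distance,
                "axial_offset_A": c.axial_offset,
            }
            for c in contacts
        ]
    )


def minus_end_pitch(
    lattice: LatticeModel,
    threshold: float = 12.0,
    contacts: Optional[ContactSpec] = None,
) -> float:
    """Median axial offset per lateral step over non-gap interfaces.

    This is the lattice's effective helical pitch per protofilament at the
    minus end; an ideal 13-protofilament lattice gives the canonical
    9.4615 Angstrom lateral rise.
    """
    cls = classify_lateral_contacts(lattice, threshold, contacts)
    offsets = [c.axial_offset for c in cls if c.type != "gap"]
    if len(offsets) < 3:
        raise ParameterError("need >= 3 non-gap interfaces for a pitch estimate")
    return float(np.median(offsets))


# ---------------------------------------------------------------------------
# register residuals and seam displacements
# ---------------------------------------------------------------------------

def _species_parity(lattice: LatticeModel, pf: int) -> int:
    """Parity of the alpha/beta register at layer numbering origin."""
    j0 = lattice.layers_of[pf][0]
    sp = lattice.species[(pf, j0)]
    return (0 if sp == "alpha" else 1) ^ ((j0 - 1) % 2)


def _interface_parity(lattice: LatticeModel, pf_a: int, pf_b: int,
                      start_number: int) -> int:
    """0: homotypic register at zero relative residual; 1: registers swapped."""
    q_a = _species_parity(lattice, pf_a)
    q_b = _species_parity(lattice, pf_b)
    wrap = start_number if lattice.pf_indices.index(pf_b) < lattice.pf_indices.index(pf_a) else 0
    return (q_b + wrap - q_a) % 2


def register_residuals(
    lattice: LatticeModel,
    lateral_rise: Optional[float] = None,
    exclude: Tuple[int, ...] = (),
) -> pd.Series:
    """Axial residual of each protofilament vs the regular helical ramp.

    Per protofilament the layer heights are collapsed to a base height
    (median of height minus (layer-1) * monomer repeat); the linear ramp of
    one lateral rise per protofilament index is removed and the offset fixed
    so the median residual over non-excluded protofilaments is zero.
    """
    a = lattice.estimated_monomer_repeat()
    rho = lateral_rise
    if rho is None:
        rho = lattice.lateral_rise
    if rho is None:
        rho = minus_end_pitch(lattice)
    base = {}
    for pf in lattice.pf_indices:
        vals = [
            lattice.subunit_height(pf, j) - (j - 1) * a for j in lattice.layers_of[pf]
        ]
        base[pf] = float(np.median(vals))
    ramp = {pf: (k) * rho for k, pf in enumerate(lattice.pf_indices)}
    raw = {pf: base[pf] - ramp[pf] for pf in lattice.pf_indices}
    ref = [v for pf, v in raw.items() if pf not in exclude]
    c = float(np.median(ref))
    return pd.Series({pf: raw[pf] - c for pf in lattice.pf_indices}, name="residual_A")


def _min_mod(value: float, period: float) -> float:
    """Representative of value modulo period with the smallest magnitude."""
    return float(value - period * np.round(value / period))


@dataclass
class SeamReport:
    focus_pf: int
    focus_spoke: Optional[int]
    #: per neighbour pf: required |axial movement| of the focus pf to reach
    #: the seam-compatible register at that interface (Angstrom)
    required_movement: Dict[int, float]
    #: signed version of the same movements (positive = toward plus end)
    signed_movement: Dict[int, float]
    #: other protofilaments out of regular register: pf -> |movement| needed
    prerequisite_movements: Dict[int, float]
    prerequisite_signed: Dict[int, float]
    monomer_repeat: float
    lateral_rise: float


def seam_displacements(
    lattice: LatticeModel,
    focus_pf: int,
    lateral_rise: Optional[float] = None,
    prerequisite_tol: float = 2.0,
) -> SeamReport:
    """Axial movements needed for the focus protofilament to form a seam.

    For each cyclic neighbour, the minimal absolute axial displacement that
    brings the pair to the heterotypic (seam) register is computed modulo
    the dimer repeat, with the regular distal lattice defining the register
    and interface parity handling the closure interface.  Protofilaments
    (other than the focus) whose own residual deviates from the regular
    register by more than ``prerequisite_tol`` are listed as prerequisite
    movements.
    """
    if focus_pf not in lattice.pf_indices:
        raise ParameterError(f"focus pf {focus_pf} not in lattice")
    a = lattice.estimated_monomer_repeat()
    res = register_residuals(lattice, lateral_rise, exclude=(focus_pf,))
    rho = lateral_rise if lateral_rise is not None else (
        lattice.lateral_rise if lattice.lateral_rise is not None else minus_end_pitch(lattice)
    )
    start = int(round(len(lattice.pf_indices) * rho / a))
    pfs = lattice.pf_indices
    k = pfs.index(focus_pf)
    prev_pf, next_pf = pfs[k - 1], pfs[(k + 1) % len(pfs)]
    dimer = 2.0 * a
    required, signed = {}, {}
    for nb, ordered in ((prev_pf, (prev_pf, focus_pf)), (next_pf, (focus_pf, next_pf))):
        parity = _interface_parity(lattice, ordered[0], ordered[1], start)
        target = (1 - parity) * a     # heterotypic register offset, mod dimer
        # a neighbour far off the regular register is assumed to make its own
        # (separately listed) prerequisite movement first: snap it to register
        nb_res = res[nb]
        nb_off = _min_mod(nb_res, dimer)
        if abs(nb_off) > prerequisite_tol:
            nb_res = nb_res - nb_off
        rel = res[focus_pf] - nb_res
        delta = _min_mod(target - rel, dimer)
        signed[nb] = delta
        required[nb] = abs(delta)
    prereq, prereq_signed = {}, {}
    for pf in pfs:
        if pf == focus_pf:
            continue
        off = _min_mod(res[pf], dimer)
        if abs(off) > prerequisite_tol:
            prereq[pf] = abs(off)
            prereq_signed[pf] = -off
    corr = lattice.spoke_correspondence or {}
    return SeamReport(
        focus_pf=focus_pf,
        focus_spoke=corr.get(focus_pf),
        required_movement=required,
        signed_movement=signed,
        prerequisite_movements=prereq,
        prerequisite_signed=prereq_signed,
        monomer_repeat=a,
        lateral_rise=rho,
    )


# ---------------------------------------------------------------------------
# seam prediction
# ---------------------------------------------------------------------------

@dataclass
class SeamPrediction:
    status: str                              # "seam" | "candidates" | "ambiguous"
    interfaces: List[Tuple[int, int]] = field(default_factory=list)
    isolated_pf: Optional[int] = None


def predict_seam(
    contacts: List[LateralContact],
    lattice: Optional[LatticeModel] = None,
) -> SeamPrediction:
    """Locate the seam, or predict where it will form.

    One heterotypic interface in an otherwise homotypic ring is the seam.
    A protofilament flanked by gaps on both sides in an otherwise homotypic
    ring yields both flanking interfaces as candidates, ranked by the
    required seam-formation movement when a lattice is supplied.  Multiple
    disconnected gap regions (or several heterotypic interfaces) give an
    explicit ambiguous status.
    """
    het = [c for c in contacts if c.type == "heterotypic"]
    gaps = [c for c in contacts if c.type == "gap"]
    if len(het) == 1 and not gaps:
        return SeamPrediction("seam", [het[0].interface])
    if het:
        return SeamPrediction("ambiguous", [c.interface for c in het + gaps])
    if gaps:
        # which pfs are flanked by gaps on both sides?
        gap_ifaces = {c.interface for c in gaps}
        isolated = []
        for c in contacts:
            pf = c.interface[1]
            left = c.interface
            right = next(
                (d.interface for d in contacts if d.interface[0] == pf), None
            )
            if right is not None and left in gap_ifaces and right in gap_ifaces:
                isolated.append((pf, left, right))
        if len(isolated) == 1:
            pf, left, right = isolated[0]
            ifaces = [left, right]
            if lattice is not None:
                report = seam_displacements(lattice, pf)
                ifaces.sort(
                    key=lambda i: report.required_movement[i[0] if i[0] != pf else i[1]]
                )
            return SeamPrediction("candidates", ifaces, isolated_pf=pf)
        return SeamPrediction("ambiguous", sorted(gap_ifaces))
    return SeamPrediction("ambiguous", [])
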