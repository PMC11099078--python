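"""Atomic model IO, selections, centers of mass and rigid-body superposition.

Every geometric stage of the package operates on :class:`StructureModel`, an
ordered list of atom records with an optional spoke/protofilament annotation
(:class:`SpokeMap`).  Coordinates are Angstrom everywhere; quantities compared
against nanometre figures are converted only at report time.

File parsing and writing is delegated to :mod:`gemmi` (PDB and mmCIF).
Hydrogens, B+ alternate locations and zero-occupancy atoms are dropped on
read, since cryo-EM depositions rarely define them consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
import yaml


class FormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class AnnotationError(KeyError):
    """Raised when a spoke/protofilament annotation does not match the model."""


class EmptySelectionError(ValueError):
    """Raised when an operation requires a non-empty atom selection."""


class DegenerateConfigurationError(ValueError):
    """Raised when a geometric fit is underdetermined (collinear/too few points)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, naming, residue identity and position in Angstrom."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    mass: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "position", pos)
        if not self.mass > 0:
            raise ValueError(f"atomic mass must be positive, got {self.mass}")
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class SpokeAssignment:
    spoke: int           # 1..14
    component: str       # "gamma_tubulin" or "gcp2".."gcp6"

    def __post_init__(self):
        if not 1 <= self.spoke <= 14:
            raise ValueError(f"spoke index must be in 1..14, got {self.spoke}")


@dataclass(frozen=True)
class PfAssignment:
    """Protofilament assignment of a chain.

    ``species``/``layer`` may be None, in which case they are carried by the
    chain's residues instead (residue name ``ATB``/``BTB`` for alpha/beta,
    residue number = layer index counting from the minus end).
    """

    pf: int
    species: Optional[str] = None    # "alpha" | "beta" | None
    layer: Optional[int] = None      # >= 1, minus end first

    def __post_init__(self):
        if self.pf < 1:
            raise ValueError("protofilament index must be >= 1")
        if self.species not in (None, "alpha", "beta"):
            raise ValueError(f"species must be alpha/beta, got {self.species}")
        if self.layer is not None and self.layer < 1:
            raise ValueError("layer index must be >= 1")


@dataclass
class SpokeMap:
    """Chain-level annotation: which chain is which spoke / protofilament."""

    spoke_of_chain: Dict[str, SpokeAssignment] = field(default_factory=dict)
    pf_of_chain: Dict[str, PfAssignment] = field(default_factory=dict)

    def chains(self) -> set:
        return set(self.spoke_of_chain) | set(self.pf_of_chain)

    def validate_against(self, chain_ids: Iterable[str]) -> None:
        present = set(chain_ids)
        missing = sorted(self.chains() - present)
        if missing:
            raise AnnotationError(
                f"annotation references chains absent from the model: {missing}"
            )

    # -- YAML sidecar -------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SpokeMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SpokeMap":
        spokes = {
            str(cid): SpokeAssignment(int(d["spoke"]), str(d["component"]))
            for cid, d in (raw.get("spokes") or {}).items()
        }
        pfs = {
            str(cid): PfAssignment(
                int(d["pf"]),
                d.get("species"),
                int(d["layer"]) if d.get("layer") is not None else None,
            )
            for cid, d in (raw.get("protofilaments") or {}).items()
        }
        return cls(spokes, pfs)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.spoke_of_chain:
            out["spokes"] = {
                c: {"spoke": a.spoke, "component": a.component}
                for c, a in self.spoke_of_chain.items()
            }
        if self.pf_of_chain:
            out["protofilaments"] = {
                c: {"pf": a.pf, "species": a.species, "layer": a.layer}
                for c, a in self.pf_of_chain.items()
            }
        return out

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class StructureModel:
    """Ordered atoms plus optional spoke/protofilament annotation."""

    atoms: List[AtomRecord]
    annotation: Optional[SpokeMap] = None

    def __post_init__(self):
        if self.annotation is not None:
            self.annotation.validate_against(self.chain_ids())
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> List[str]:
        out, seen = [], set()
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.add(a.chain_id)
                out.append(a.chain_id)
        return out

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        new_pos = transform.apply(self.positions)
        atoms = [a.moved_to(p) for a, p in zip(self.atoms, new_pos)]
        return StructureModel(atoms, self.annotation)

    def with_positions(self, positions: np.ndarray) -> "StructureModel":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions shape mismatch")
        atoms = [a.moved_to(p) for a, p in zip(self.atoms, positions)]
        return StructureModel(atoms, self.annotation)

    def select(self, **kwargs) -> List[AtomRecord]:
        return select_atoms(self, **kwargs)

    def subset(self, atoms: Sequence[AtomRecord]) -> "StructureModel":
        """New model from a selection, keeping only annotation for present chains."""
        ann = None
        if self.annotation is not None:
            chains = {a.chain_id for a in atoms}
            ann = SpokeMap(
                {c: v for c, v in self.annotation.spoke_of_chain.items() if c in chains},
                {c: v for c, v in self.annotation.pf_of_chain.items() if c in chains},
            )
        return StructureModel(list(atoms), ann)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-9 or not np.allclose(
            R @ R.T, np.eye(3), atol=1e-9
        ):
            raise ValueError("rotation must be proper orthonormal (det=+1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(
        cls, axis: np.ndarray, angle_deg: float, center: np.ndarray = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rotation by angle_deg about a line through ``center`` along ``axis``."""
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        center = np.asarray(center, dtype=float)
        return cls(R, center - R @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _element_mass(symbol: str) -> float:
    el = gemmi.Element(symbol)
    if el.weight <= 0:
        return 12.011  # fall back to carbon for unknown markers
    return float(el.weight)


def read_structure(
    path: Union[str, Path],
    format: Optional[str] = None,
    annotation: Optional[Union[SpokeMap, str, Path]] = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are retained except hydrogens,
    alternate locations beyond 'A', and zero-occupancy atoms.  ``annotation``
    may be a :class:`SpokeMap` or a path to its YAML sidecar; referenced
    chains are verified to exist.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad input
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")

    atoms: List[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                if at.is_hydrogen():
                    continue
                if at.altloc not in ("", "\0", "A"):
                    continue
                if at.occ == 0:
                    continue
                atoms.append(
                    AtomRecord(
                        element=at.element.name,
                        name=at.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        mass=_element_mass(at.element.name),
                    )
                )
    if not atoms:
        raise FormatError(f"{path} contains no coordinate records")
    if annotation is not None and not isinstance(annotation, SpokeMap):
        annotation = SpokeMap.from_yaml(annotation)
    return StructureModel(atoms, annotation)


def write_structure(model: StructureModel, path: Union[str, Path]) -> None:
    """Write a model to PDB (or mmCIF when the suffix is .cif/.mmcif)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    md = gemmi.Model("1")
    chains: Dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_number or chain[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "A"
            chain.add_residue(res)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = 1.0
        chain[-1].add_atom(at)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def _matches(value, clause) -> bool:
    if clause is None:
        return True
    if isinstance(clause, (list, tuple, set, frozenset)):
        return value in clause
    return value == clause


def select_atoms(
    model: StructureModel,
    chain_id=None,
    residue_number=None,
    residue_name=None,
    name=None,
    element=None,
) -> List[AtomRecord]:
    """Atoms matching the conjunction of all given clauses, in model order.

    Each clause is a scalar or a collection of admissible values; an empty
    selection is a valid result.
    """
    return [
        a
        for a in model.atoms
        if _matches(a.chain_id, chain_id)
        and _matches(a.residue_number, residue_number)
        and _matches(a.residue_name, residue_name)
        and _matches(a.name, name)
        and _matches(a.element, element)
    ]


def center_of_mass(atoms: Sequence[AtomRecord], weighting: str = "mass") -> np.ndarray:
    """Weighted centroid of a selection; ``weighting`` is "mass" or "geometric"."""
    if len(atoms) == 0:
        raise EmptySelectionError("center_of_mass of an empty selection")
    pos = np.array([a.position for a in atoms], dtype=float)
    if weighting == "mass":
        w = np.array([a.mass for a in atoms], dtype=float)
    elif weighting == "geometric":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (w[:, None] * pos).sum(axis=0) / w.sum()


def superpose(
    mobile: Sequence[AtomRecord],
    reference: Sequence[AtomRecord],
    pairing: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    ``pairing`` lists (mobile_index, reference_index) pairs; by default the
    two selections are paired index by index.  Returns the proper rigid
    transform minimizing the summed squared pair distances, and the RMSD at
    the optimum.  Reflections are rejected by flipping the sign of the
    smallest singular vector when needed.
    """
    if pairing is None:
        if len(mobile) != len(reference):
            raise ValueError("unpaired superposition needs equal-length selections")
        pairing = [(i, i) for i in range(len(mobile))]
    if len(pairing) < 3:
        raise DegenerateConfigurationError("superposition needs >= 3 paired atoms")
    X = np.array([mobile[i].position for i, _ in pairing], dtype=float)
    Y = np.array([reference[j].position for _, j in pairing], dtype=float)
    return superpose_points(X, Y)


def superpose_points(X: np.ndarray, Y: np.ndarray) -> Tuple[RigidTransform, float]:
    """Kabsch superposition of point set X onto Y (rows paired)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise DegenerateConfigurationError("need >= 3 paired 3D points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinearity check: rank of the centred cloud
    sv = np.linalg.svd(X0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("paired points are (near-)collinear")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    resid = transform.apply(X) - Y
    rmsd = float(np.sqrt((resid**2).sum() / X.shape[0]))
    return transform, rmsd
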