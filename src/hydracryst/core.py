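"""Core structure model, PDB input/output and periodic geometry.

The analysis pipeline works on a deliberately small structure model: a flat,
ordered list of atoms plus an optional orthorhombic periodic box.  Crystal
cells handled here are rectangular (all angles 90 deg), which is all the
tetragonal / orthorhombic systems studied need.  Trajectories are sequences
of coordinate frames sharing one topology; multi-model PDB is the mandatory
interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Box",
    "Structure",
    "Trajectory",
    "WATER_RESNAMES",
    "ION_RESNAMES",
    "MAIN_CHAIN_ATOMS",
    "HYDROPHOBIC_RESIDUES",
    "STANDARD_AMINO_ACIDS",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "classify_atoms",
    "class_array",
    "min_image_displacement",
    "min_image_distance",
]

# Residue-name vocabularies used for atom classification.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "H2O", "DOD"})
ION_RESNAMES = frozenset(
    {"CL", "NA", "K", "MG", "CA", "ZN", "BR", "IOD", "CS", "LI", "RB", "F"}
)
# Backbone atoms and the hydrogens bonded to them (amide H, N-terminal
# H1/H2/H3, alpha hydrogens including glycine's HA2/HA3).
MAIN_CHAIN_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)
# Default binary hydrophobicity split (Kyte-Doolittle-style); every other
# standard amino acid is treated as hydrophilic.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY"}
)

WATER_CLASS = "water"
ION_CLASS = "ion"
MAIN_CHAIN_CLASS = "main_chain"
HYDROPHILIC_CLASS = "side_chain_hydrophilic"
HYDROPHOBIC_CLASS = "side_chain_hydrophobic"
ATOM_CLASSES = (
    WATER_CLASS,
    ION_CLASS,
    MAIN_CHAIN_CLASS,
    HYDROPHILIC_CLASS,
    HYDROPHOBIC_CLASS,
)
PROTEIN_CLASSES = (MAIN_CHAIN_CLASS, HYDROPHILIC_CLASS, HYDROPHOBIC_CLASS)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Atom:
    """One atom record: identity, residue membership and Cartesian position (A)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class Box:
    """Rectangular periodic cell defined by its three edge lengths (A)."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        lengths = tuple(float(x) for x in self.lengths)
        if len(lengths) != 3 or any(x <= 0 for x in lengths):
            raise ValueError(f"box lengths must be three positive numbers, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.array))


@dataclass
class Structure:
    """An ordered collection of atoms, optionally inside a periodic box."""

    atoms: list[Atom]
    box: Box | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, coords: np.ndarray, box: Box | None = None) -> "Structure":
        """Same topology with replaced coordinates (and optionally box)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, box=box if box is not None else self.box,
                         metadata=dict(self.metadata))

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """Frames sharing one topology; each frame is (coords (N,3), Box or None)."""

    topology: Structure
    frames: list[tuple[np.ndarray, Box | None]]

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        for i, (coords, _) in enumerate(self.frames):
            if np.asarray(coords).shape != (n, 3):
                raise ValueError(f"frame {i}: expected ({n}, 3) coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        coords, box = self.frames[i]
        return self.topology.with_positions(coords, box=box)

    def iter_frames(self) -> Iterator[Structure]:
        for i in range(len(self.frames)):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# PDB input / output (via gemmi)
# ---------------------------------------------------------------------------

def _is_orthorhombic(cell: gemmi.UnitCell) -> bool:
    return all(abs(a - 90.0) < 1e-3 for a in (cell.alpha, cell.beta, cell.gamma))


def _select_altloc(group: list[gemmi.Atom], policy: str) -> gemmi.Atom:
    if policy == "first":
        return group[0]
    if policy != "highest_occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    # Highest occupancy wins; ties broken by altloc identifier order so that
    # parsing is deterministic ('A' beats 'B' at equal occupancy).
    return sorted(group, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def _model_atoms(model: gemmi.Model, policy: str) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for at in residue:
                groups.setdefault(at.name, []).append(at)
            for name, group in groups.items():
                at = _select_altloc(group, policy) if len(group) > 1 else group[0]
                element = at.element.name.upper() if at.element else ""
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=name,
                        element=element,
                        residue_name=residue.name.strip(),
                        residue_id=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
    return atoms


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    return st


def _box_from_cell(st: gemmi.Structure) -> Box | None:
    cell = st.cell
    if cell.a > 1.0 and cell.b > 1.0 and cell.c > 1.0:
        if not _is_orthorhombic(cell):
            logger.warning("non-orthorhombic cell in %s ignored (angles %.1f %.1f %.1f)",
                           st.name, cell.alpha, cell.beta, cell.gamma)
            return None
        return Box((cell.a, cell.b, cell.c))
    return None


def read_structure(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    All ATOM/HETATM records of the first model are kept.  Where a residue
    carries alternate locations of the same atom, the chosen policy keeps one:
    ``highest_occupancy`` (default; occupancy ties broken by altloc letter) or
    ``first``.  A CRYST1 record with 90 deg angles populates the box.
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    atoms = _model_atoms(st[0], altloc_policy)
    if not atoms:
        raise PDBParseError(f"{path}: file contains no atoms")
    metadata = {"entry_id": st.name.strip().upper()}
    if st.resolution:
        metadata["resolution"] = float(st.resolution)
    if st.spacegroup_hm:
        metadata["spacegroup"] = st.spacegroup_hm.replace(" ", "")
    return Structure(atoms=atoms, box=_box_from_cell(st), metadata=metadata)


def read_trajectory(path: str | Path, altloc_policy: str = "highest_occupancy") -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    The first MODEL defines the topology; every model must contain the same
    number of atoms.  The (single) CRYST1 box applies to all frames.
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    box = _box_from_cell(st)
    topo_atoms = _model_atoms(st[0], altloc_policy)
    if not topo_atoms:
        raise PDBParseError(f"{path}: file contains no atoms")
    topology = Structure(atoms=topo_atoms, box=box)
    frames: list[tuple[np.ndarray, Box | None]] = []
    for model in st:
        atoms = _model_atoms(model, altloc_policy)
        if len(atoms) != len(topo_atoms):
            raise PDBParseError(
                f"{path}: model has {len(atoms)} atoms, topology has {len(topo_atoms)}"
            )
        frames.append((np.array([a.position for a in atoms]), box))
    return Trajectory(topology=topology, frames=frames)


def _to_gemmi_model(s: Structure, coords: np.ndarray | None = None,
                    model_num: int = 1) -> gemmi.Model:
    model = gemmi.Model(model_num)
    pos = coords if coords is not None else s.positions
    chain = None
    residue = None
    last_key = None
    for i, a in enumerate(s.atoms):
        if chain is None or chain.name != a.chain_id:
            chain = gemmi.Chain(a.chain_id)
            model.add_chain(chain)
            chain = model[-1]
            last_key = None
        key = (a.residue_id, a.residue_name)
        if key != last_key:
            residue = gemmi.Residue()
            residue.name = a.residue_name
            residue.seqid = gemmi.SeqId(a.residue_id, " ")
            chain.add_residue(residue)
            residue = chain[-1]
            last_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element if a.element else a.name[:1])
        at.pos = gemmi.Position(*pos[i])
        at.occ = a.occupancy
        at.altloc = a.altloc or "\x00"
        # PDB serial field wraps modulo 100000 for very large systems.
        at.serial = a.serial % 100000
        residue.add_atom(at)
    return model


def _to_gemmi_structure(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(s.metadata.get("entry_id", "XXXX"))
    if s.box is not None:
        a, b, c = s.box.lengths
        st.cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    st.spacegroup_hm = s.metadata.get("spacegroup", "P 1")
    return st


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as PDB text (CRYST1 with 90 deg angles if a box is set)."""
    if not s.atoms:
        raise ValueError("refusing to write an empty structure")
    st = _to_gemmi_structure(s)
    st.add_model(_to_gemmi_model(s))
    st.write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    if not traj.frames:
        raise ValueError("refusing to write an empty trajectory")
    st = _to_gemmi_structure(traj.frame(0))
    for k in range(len(traj.frames)):
        coords, _ = traj.frames[k]
        st.add_model(_to_gemmi_model(traj.topology, coords=coords, model_num=k + 1))
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Atom classification
# ---------------------------------------------------------------------------

def classify_atoms(
    s: Structure,
    hydrophobic_set: Sequence[str] | frozenset[str] = HYDROPHOBIC_RESIDUES,
    unknown_fallback: str = HYDROPHILIC_CLASS,
) -> dict[int, str]:
    """Assign every atom to exactly one class, keyed by atom serial.

    Classes: ``water``, ``ion``, ``main_chain``, ``side_chain_hydrophilic``,
    ``side_chain_hydrophobic``.  Backbone atoms (N, CA, C, O, OXT and their
    hydrogens) of any amino acid are ``main_chain``; remaining protein atoms
    follow the residue's membership in ``hydrophobic_set``.  Residue names
    outside the known vocabulary fall back to ``unknown_fallback`` with a
    logged warning.
    """
    if unknown_fallback not in (HYDROPHILIC_CLASS, HYDROPHOBIC_CLASS):
        raise ValueError(f"unknown_fallback must be a side-chain class, got {unknown_fallback!r}")
    hydrophobic = {r.upper() for r in hydrophobic_set}
    labels: dict[int, str] = {}
    warned: set[str] = set()
    for a in s.atoms:
        res = a.residue_name.upper()
        if res in WATER_RESNAMES:
            labels[a.serial] = WATER_CLASS
        elif res in ION_RESNAMES and res not in STANDARD_AMINO_ACIDS:
            labels[a.serial] = ION_CLASS
        else:
            if res not in STANDARD_AMINO_ACIDS and res not in warned:
                logger.warning("unknown residue %s classified as %s", res, unknown_fallback)
                warned.add(res)
            if a.name.upper() in MAIN_CHAIN_ATOMS:
                labels[a.serial] = MAIN_CHAIN_CLASS
            elif res in hydrophobic:
                labels[a.serial] = HYDROPHOBIC_CLASS
            elif res in STANDARD_AMINO_ACIDS:
                labels[a.serial] = HYDROPHILIC_CLASS
            else:
                labels[a.serial] = unknown_fallback
    return labels


def class_array(s: Structure, classes: Mapping[int, str]) -> np.ndarray:
    """Class labels as an array aligned with the structure's atom order."""
    return np.array([classes[a.serial] for a in s.atoms], dtype=object)


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def min_image_displacement(p: np.ndarray, q: np.ndarray, box: Box | None) -> np.ndarray:
    """Displacement q - p under the minimum image convention (vectorised)."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if box is not None:
        L = box.array
        d = d - L * np.round(d / L)
    return d


def min_image_distance(p: np.ndarray, q: np.ndarray, box: Box | None) -> float | np.ndarray:
    """Minimum-image distance between two points (or arrays of points)."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_positions(coords: np.ndarray, box: Box) -> np.ndarray:
    """Wrap coordinates into [0, L) on each axis."""
    return np.mod(coords, box.array)
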