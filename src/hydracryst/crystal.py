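"""Crystal system construction: symmetry expansion, hydration, neutralisation.

Builds the crystalline simulation system from an asymmetric unit: apply the
space-group operators to fill the unit cell, insert rigid three-site waters
by rejection sampling until a target hydration level h (g water / g protein)
is reached, and add counterions until the formal charge is zero.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np

from hydracryst.core import (
    Atom,
    Box,
    ION_RESNAMES,
    STANDARD_AMINO_ACIDS,
    Structure,
    WATER_RESNAMES,
    min_image_distance,
)
from hydracryst.watermodel import random_water_sites

logger = logging.getLogger(__name__)

WATER_MOLAR_MASS = 18.015  # g/mol

# Average atomic masses (Da) for the elements that occur in protein systems.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "CL": 35.45, "NA": 22.990, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "ZN": 65.38, "BR": 79.904, "F": 18.998,
}

# Residue-level formal charges at neutral pH; histidine neutral by default.
DEFAULT_CHARGE_RULES = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0,
    "N_TERMINUS": +1, "C_TERMINUS": -1,
}


class SpaceGroupError(ValueError):
    """Raised for an unsupported space-group name."""


class CapacityError(RuntimeError):
    """Raised when rejection sampling cannot place all requested molecules."""

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


@dataclass(frozen=True)
class SpaceGroupOps:
    """Symmetry operators acting on fractional coordinates: x' = R x + t."""

    name: str
    operators: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __len__(self) -> int:
        return len(self.operators)


def _op(rot, trans) -> tuple[np.ndarray, np.ndarray]:
    return (np.asarray(rot, dtype=float), np.asarray(trans, dtype=float))


# P4_1 operators in the international-tables setting:
# (x,y,z), (-x,-y,z+1/2), (-y,x,z+1/4), (y,-x,z+3/4).
_SPACE_GROUPS = {
    "P1": SpaceGroupOps("P1", (_op(np.eye(3), [0, 0, 0]),)),
    "P41": SpaceGroupOps(
        "P41",
        (
            _op(np.eye(3), [0, 0, 0]),
            _op([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], [0, 0, 0.5]),
            _op([[0, -1, 0], [1, 0, 0], [0, 0, 1]], [0, 0, 0.25]),
            _op([[0, 1, 0], [-1, 0, 0], [0, 0, 1]], [0, 0, 0.75]),
        ),
    ),
}


def space_group(name: str) -> SpaceGroupOps:
    """Look up a supported space group by name (``P1`` or ``P41``)."""
    key = name.upper().replace(" ", "").replace("_", "")
    if key not in _SPACE_GROUPS:
        raise SpaceGroupError(
            f"unsupported space group {name!r}; supported: {sorted(_SPACE_GROUPS)}"
        )
    return _SPACE_GROUPS[key]


@dataclass(frozen=True)
class HydrationSpec:
    """Target hydration level and the water count it implies."""

    h: float
    protein_mass: float
    water_mass: float = WATER_MOLAR_MASS
    n_waters: int = field(init=False)

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"hydration level must be >= 0, got {self.h}")
        if self.protein_mass <= 0:
            raise ValueError("protein mass must be positive")
        object.__setattr__(
            self, "n_waters", int(round(self.h * self.protein_mass / self.water_mass))
        )


def water_count_for_h(h: float, protein_mass: float) -> int:
    """Number of waters for hydration level h (g water / g protein)."""
    return HydrationSpec(h=h, protein_mass=protein_mass).n_waters


def structure_mass(s: Structure, subset: str = "protein") -> float:
    """Summed atomic mass (Da) of the protein, water or all atoms."""
    total = 0.0
    for a in s.atoms:
        res = a.residue_name.upper()
        is_water = res in WATER_RESNAMES
        is_ion = res in ION_RESNAMES and res not in STANDARD_AMINO_ACIDS
        if subset == "protein" and (is_water or is_ion):
            continue
        if subset == "water" and not is_water:
            continue
        el = a.element.upper()
        if el not in ATOMIC_MASSES:
            raise ValueError(f"no mass tabulated for element {el!r} (atom {a.serial})")
        total += ATOMIC_MASSES[el]
    return total


def realized_h(s: Structure) -> float:
    """Hydration level implied by the structure's water and protein masses."""
    return structure_mass(s, "water") / structure_mass(s, "protein")


# ---------------------------------------------------------------------------
# Symmetry expansion
# ---------------------------------------------------------------------------

def _molecule_groups(s: Structure) -> list[np.ndarray]:
    """Atom-index groups treated as rigid molecules for wrapping.

    Protein chains wrap as one molecule; waters, ions and other HETATM
    residues wrap per residue.
    """
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(s.atoms):
        res = a.residue_name.upper()
        if res in STANDARD_AMINO_ACIDS:
            key = ("chain", a.chain_id)
        else:
            key = ("res", a.chain_id, a.residue_id, res)
        groups.setdefault(key, []).append(i)
    return [np.asarray(ix) for ix in groups.values()]


_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def apply_space_group(asym: Structure, ops: SpaceGroupOps | str, cell: Box) -> Structure:
    """Expand an asymmetric unit into the unit cell.

    Each operator is applied in fractional coordinates; each molecule of each
    copy is then wrapped into [0, 1)^3 by its centroid, so molecules are never
    split across the cell boundary.  Copies receive distinct chain ids and
    consecutive serials.
    """
    if isinstance(ops, str):
        ops = space_group(ops)
    if not asym.atoms:
        raise ValueError("asymmetric unit is empty")
    L = cell.array
    frac = asym.positions / L
    groups = _molecule_groups(asym)
    orig_chains = asym.chain_ids()

    out_atoms: list[Atom] = []
    serial = 1
    chain_cursor = 0
    used: set[str] = set()
    for k, (rot, trans) in enumerate(ops.operators):
        new_frac = frac @ rot.T + trans
        for ix in groups:
            centroid = new_frac[ix].mean(axis=0)
            new_frac[ix] -= np.floor(centroid)
        coords = new_frac * L
        # map original chain ids to fresh ids for this copy
        chain_map: dict[str, str] = {}
        for cid in orig_chains:
            if k == 0:
                new_cid = cid
            else:
                while _CHAIN_ALPHABET[chain_cursor % len(_CHAIN_ALPHABET)] in used:
                    chain_cursor += 1
                new_cid = _CHAIN_ALPHABET[chain_cursor % len(_CHAIN_ALPHABET)]
                chain_cursor += 1
            chain_map[cid] = new_cid
            used.add(new_cid)
        for i, a in enumerate(asym.atoms):
            out_atoms.append(
                Atom(
                    serial=serial,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_id=a.residue_id,
                    chain_id=chain_map[a.chain_id],
                    position=coords[i],
                    occupancy=a.occupancy,
                    altloc=a.altloc,
                )
            )
            serial += 1
    meta = dict(asym.metadata)
    meta["spacegroup"] = ops.name
    return Structure(atoms=out_atoms, box=cell, metadata=meta)


# ---------------------------------------------------------------------------
# Water insertion and neutralisation
# ---------------------------------------------------------------------------

def _existing_clash_sites(s: Structure) -> np.ndarray:
    """Positions of heavy atoms (non-hydrogen) that inserted sites must avoid."""
    heavy = [a.position for a in s.atoms if not a.is_hydrogen]
    return np.array(heavy) if heavy else np.zeros((0, 3))


def _sample_positions(
    s: Structure,
    n: int,
    clash_cutoff: float,
    rng: np.random.Generator,
    max_attempts: int,
    what: str,
) -> np.ndarray:
    """Rejection-sample n non-clashing points in the box (minimum image)."""
    box = s.box
    L = box.array
    sites = _existing_clash_sites(s)
    placed: list[np.ndarray] = []
    for i in range(n):
        for _ in range(max_attempts):
            p = rng.random(3) * L
            ok = True
            if len(sites):
                if np.min(min_image_distance(p, sites, box)) < clash_cutoff:
                    ok = False
            if ok and placed:
                if np.min(min_image_distance(p, np.array(placed), box)) < clash_cutoff:
                    ok = False
            if ok:
                placed.append(p)
                break
        else:
            raise CapacityError(
                f"placed only {i} of {n} {what} after {max_attempts} attempts each",
                placed=i,
            )
    return np.array(placed) if placed else np.zeros((0, 3))


def _next_free(s: Structure, extra: int = 0) -> tuple[int, int]:
    serial = max((a.serial for a in s.atoms), default=0) + 1 + extra
    resid = max((a.residue_id for a in s.atoms if a.chain_id == "W"), default=0) + 1
    return serial, resid


def insert_waters(
    s: Structure,
    n: int,
    clash_cutoff: float = 2.4,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> Structure:
    """Insert n rigid three-site waters at random non-clashing positions.

    Oxygen positions are sampled uniformly in the box and rejected while any
    existing heavy atom or previously placed oxygen lies within
    ``clash_cutoff`` (default 2.4 A, just below the water-water O...O
    hydrogen-bond distance) under the minimum image convention.  Orientations
    are uniform random rotations.  Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("water count must be >= 0")
    if s.box is None:
        raise ValueError("water insertion requires a periodic box")
    if n == 0:
        return s
    rng = np.random.default_rng(seed)
    oxygens = _sample_positions(s, n, clash_cutoff, rng, max_attempts, "waters")
    serial, resid = _next_free(s)
    atoms = list(s.atoms)
    for i in range(n):
        sites = random_water_sites(oxygens[i], rng)
        for name, el, pos in zip(("O", "H1", "H2"), ("O", "H", "H"), sites):
            atoms.append(
                Atom(serial=serial, name=name, element=el, residue_name="HOH",
                     residue_id=resid + i, chain_id="W", position=pos)
            )
            serial += 1
    return Structure(atoms=atoms, box=s.box, metadata=dict(s.metadata))


def _protein_chain_residues(s: Structure) -> dict[str, list[tuple[int, str]]]:
    chains: dict[str, list[tuple[int, str]]] = {}
    for a in s.atoms:
        res = a.residue_name.upper()
        if res in STANDARD_AMINO_ACIDS:
            key = (a.residue_id, res)
            lst = chains.setdefault(a.chain_id, [])
            if not lst or lst[-1] != key:
                lst.append(key)
    return chains


def formal_charge(s: Structure, charge_rules: dict | None = None) -> int:
    """Net formal charge from residue-level rules plus charged termini.

    Counts existing counterions (Na+, K+, Cl-, ...) as well, so the function
    reports the charge of the whole system.
    """
    rules = dict(DEFAULT_CHARGE_RULES)
    if charge_rules:
        rules.update({k.upper(): v for k, v in charge_rules.items()})
    for key, val in rules.items():
        if not float(val).is_integer():
            raise ValueError(f"charge rule {key}={val} is not an integer")
    total = 0
    for cid, residues in _protein_chain_residues(s).items():
        total += rules["N_TERMINUS"] + rules["C_TERMINUS"]
        for _, res in residues:
            total += int(rules.get(res, 0))
    ion_charges = {"CL": -1, "BR": -1, "IOD": -1, "F": -1,
                   "NA": +1, "K": +1, "LI": +1, "CS": +1, "RB": +1,
                   "MG": +2, "CA": +2, "ZN": +2}
    seen_ion_residues: set[tuple[str, int]] = set()
    for a in s.atoms:
        res = a.residue_name.upper()
        if res in ION_RESNAMES and res not in STANDARD_AMINO_ACIDS:
            key = (a.chain_id, a.residue_id)
            if key not in seen_ion_residues:
                seen_ion_residues.add(key)
                total += ion_charges.get(res, 0)
    return total


def neutralize(
    s: Structure,
    charge_rules: dict | None = None,
    clash_cutoff: float = 2.4,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> Structure:
    """Add counterions at random non-clashing positions until net charge is 0.

    Positive systems receive Cl-, negative systems Na+.  Idempotent: a
    neutral system is returned unchanged.
    """
    net = formal_charge(s, charge_rules)
    if net == 0:
        return s
    if s.box is None:
        raise ValueError("ion placement requires a periodic box")
    n_ions = abs(net)
    name = "CL" if net > 0 else "NA"
    element = "CL" if net > 0 else "NA"
    rng = np.random.default_rng(seed)
    positions = _sample_positions(s, n_ions, clash_cutoff, rng, max_attempts, "ions")
    serial = max(a.serial for a in s.atoms) + 1
    resid = max((a.residue_id for a in s.atoms if a.chain_id == "I"), default=0) + 1
    atoms = list(s.atoms)
    for i in range(n_ions):
        atoms.append(
            Atom(serial=serial + i, name=name, element=element, residue_name=name,
                 residue_id=resid + i, chain_id="I", position=positions[i])
        )
    logger.info("added %d %s ions to neutralise net charge %+d", n_ions, name, net)
    return Structure(atoms=atoms, box=s.box, metadata=dict(s.metadata))


def build_crystal_system(
    asym: Structure,
    spacegroup_name: str,
    cell: Box,
    h: float,
    seed: int = 0,
    clash_cutoff: float = 2.4,
    charge_rules: dict | None = None,
) -> tuple[Structure, dict]:
    """Full build: symmetry expansion, hydration to level h, neutralisation.

    Crystal waters already present in the asymmetric unit are expanded with it
    and count toward the target water number.  Returns the built structure and
    a report dict (water counts, realised h, ion count, net charge, cell).
    """
    expanded = apply_space_group(asym, spacegroup_name, cell)
    protein_mass = structure_mass(expanded, "protein")
    target = water_count_for_h(h, protein_mass)
    existing = sum(
        1 for a in expanded.atoms
        if a.residue_name.upper() in WATER_RESNAMES and a.name.upper().startswith("O")
    )
    to_add = max(target - existing, 0)
    hydrated = insert_waters(expanded, to_add, clash_cutoff=clash_cutoff, seed=seed)
    net = formal_charge(hydrated, charge_rules)
    final = neutralize(hydrated, charge_rules, clash_cutoff=clash_cutoff, seed=seed + 1)
    report = {
        "n_waters_target": target,
        "n_waters_existing": existing,
        "n_waters_added": to_add,
        "realized_h": realized_h(final),
        "net_charge_before_ions": net,
        "n_ions": abs(net),
        "ion_species": "CL" if net > 0 else ("NA" if net < 0 else None),
        "cell_lengths": list(cell.lengths),
        "n_atoms": len(final.atoms),
    }
    return final, report
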