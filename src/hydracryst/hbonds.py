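"""Geometric hydrogen-bond detection, per-water statistics and ring motifs.

A donor-H / acceptor pair is hydrogen-bonded when the donor-heavy-atom to
acceptor distance is strictly below a cutoff (default 3.5 A) and the
D-H...A angle lies in [120 deg, 180 deg].  Geometry is reported as
(r, theta) where r is the hydrogen-to-acceptor distance and theta is
180 deg minus the D-H...A angle, so theta = 0 is a perfectly linear bond.

Donors are O-H and N-H groups (water and protein); acceptors are water
oxygens, protein oxygens, and protein nitrogens without attached hydrogens.
Bonds involving nitrogen at either end are flagged so that O-H...O-only
statistics can be extracted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from hydracryst.core import (
    Box,
    ION_CLASS,
    MAIN_CHAIN_CLASS,
    PROTEIN_CLASSES,
    Structure,
    Trajectory,
    WATER_CLASS,
    class_array,
    min_image_displacement,
    min_image_distance,
    wrap_positions,
)

logger = logging.getLogger(__name__)

COVALENT_H_CUTOFF = 1.2  # A: fallback distance for assigning H to its heavy atom


class NoHydrogensError(ValueError):
    """The structure carries no hydrogens, so bonds cannot be assessed."""


class DegenerateGeometryError(ValueError):
    """Coincident points make the bond geometry undefined."""


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: D...A distance gate and angular tolerance.

    ``theta_max`` is the largest accepted deviation from linearity, so the
    default 60 deg admits D-H...A angles from 120 deg to 180 deg inclusive.
    """

    d_oo_max: float = 3.5
    theta_max: float = 60.0

    def __post_init__(self) -> None:
        if self.d_oo_max <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.theta_max <= 90:
            raise ValueError("theta_max must lie in (0, 90]")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (ids are atom serials)."""

    donor_atom: int
    hydrogen: int
    acceptor_atom: int
    r: float          # H...acceptor distance, A
    theta: float      # 180 deg - (D-H...A angle), degrees
    d_da: float       # donor heavy atom ... acceptor distance, A
    donor_class: str
    acceptor_class: str
    n_mediated: bool  # True when donor or acceptor heavy atom is nitrogen


@dataclass(frozen=True)
class HBondSummary:
    """Mean hydrogen bonds per water, decomposed by partner class."""

    n_frames: int
    n_waters: int
    total: float
    water_water: float
    water_protein: float
    water_main_chain: float
    water_side_chain: float


def hb_geometry(
    donor_heavy: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    box: Box | None = None,
) -> tuple[float, float]:
    """(r, theta) for one donor-H/acceptor arrangement.

    r is the minimum-image H...acceptor distance; theta is 180 deg minus the
    angle at the hydrogen between H->donor and H->acceptor.
    """
    hd = min_image_displacement(hydrogen, donor_heavy, box)
    ha = min_image_displacement(hydrogen, acceptor, box)
    nhd = np.linalg.norm(hd)
    nha = np.linalg.norm(ha)
    if nhd < 1e-9 or nha < 1e-9:
        raise DegenerateGeometryError("coincident atoms in hydrogen-bond geometry")
    cosang = np.clip(np.dot(hd, ha) / (nhd * nha), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return float(nha), float(180.0 - angle)


# ---------------------------------------------------------------------------
# Donor / acceptor tables
# ---------------------------------------------------------------------------

@dataclass
class DonorAcceptorTable:
    """Indices (into the structure's atom order) of donors and acceptors."""

    donors: list[tuple[int, int]]       # (heavy index, hydrogen index)
    acceptors: list[int]
    water_oxygen: dict[int, int]        # atom index -> its water oxygen index
    heavy_of_h: dict[int, int]


def _template_heavy(h_name: str, heavies_by_name: dict[str, int],
                    is_water: bool) -> int | None:
    """Residue-template hydrogen assignment by PDB naming conventions.

    Water hydrogens belong to the residue's oxygen.  Protein hydrogen names
    carry the parent heavy atom's remoteness code (HB2 -> CB, HG1 -> OG1 or
    CG1, HD21 -> ND2 ...); backbone H/H1/H2/H3/HN belong to N.
    """
    name = h_name.upper()
    if is_water:
        for o_name in ("O", "OW", "OH2"):
            if o_name in heavies_by_name:
                return heavies_by_name[o_name]
        return None
    if name in ("H", "HN", "H1", "H2", "H3"):
        return heavies_by_name.get("N")
    stem = name[1:]
    while stem:
        for el in ("N", "O", "C", "S"):
            hit = heavies_by_name.get(el + stem)
            if hit is not None:
                return hit
        stem = stem[:-1]
    return None


def build_donor_acceptor_table(frame: Structure, classes_arr: np.ndarray) -> DonorAcceptorTable:
    """Identify donor O-H/N-H groups and acceptor O/N atoms.

    Hydrogens are assigned to their covalent heavy atom by residue-template
    naming first; hydrogens whose name matches no template fall back to the
    nearest same-residue heavy atom within a 1.2 A covalent-distance gate
    (PDB inputs carry no bond records).
    """
    atoms = frame.atoms
    pos = frame.positions
    by_residue: dict[tuple, list[int]] = defaultdict(list)
    for i, a in enumerate(atoms):
        by_residue[(a.chain_id, a.residue_id, a.residue_name)].append(i)

    n_hydrogens = sum(1 for a in atoms if a.is_hydrogen)
    if n_hydrogens == 0:
        raise NoHydrogensError(
            "structure has no hydrogens: hydrogen bonds cannot be evaluated"
        )

    heavy_of_h: dict[int, int] = {}
    h_of_heavy: dict[int, list[int]] = defaultdict(list)
    for (_, _, resname), members in by_residue.items():
        heavies = [i for i in members if not atoms[i].is_hydrogen]
        if not heavies:
            continue
        heavies_by_name = {atoms[i].name.upper(): i for i in heavies}
        is_water = classes_arr[members[0]] == WATER_CLASS
        for i in members:
            if not atoms[i].is_hydrogen:
                continue
            j = _template_heavy(atoms[i].name, heavies_by_name, is_water)
            if j is None:
                d = np.linalg.norm(pos[heavies] - pos[i], axis=1)
                if d.min() <= COVALENT_H_CUTOFF:
                    j = heavies[int(np.argmin(d))]
            if j is not None:
                heavy_of_h[i] = j
                h_of_heavy[j].append(i)

    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    water_oxygen: dict[int, int] = {}
    for i, a in enumerate(atoms):
        cls = classes_arr[i]
        if cls == ION_CLASS:
            continue
        el = a.element.upper()
        if cls == WATER_CLASS:
            if el == "O":
                acceptors.append(i)
                water_oxygen[i] = i
                for h in h_of_heavy.get(i, []):
                    donors.append((i, h))
                    water_oxygen[h] = i
            elif el == "H" and i in heavy_of_h:
                water_oxygen[i] = heavy_of_h[i]
        elif cls in PROTEIN_CLASSES:
            if el == "O":
                acceptors.append(i)
                for h in h_of_heavy.get(i, []):
                    donors.append((i, h))
            elif el == "N":
                hs = h_of_heavy.get(i, [])
                if hs:
                    for h in hs:
                        donors.append((i, h))
                else:
                    acceptors.append(i)
    return DonorAcceptorTable(
        donors=donors, acceptors=acceptors,
        water_oxygen=water_oxygen, heavy_of_h=heavy_of_h,
    )


# ---------------------------------------------------------------------------
# Bond detection
# ---------------------------------------------------------------------------

def _acceptor_neighbors(
    donor_heavy_pos: np.ndarray,
    acceptor_pos: np.ndarray,
    box: Box | None,
    cutoff: float,
) -> list[list[int]]:
    """For each donor heavy atom, indices of acceptors within the cutoff."""
    if len(acceptor_pos) == 0:
        return [[] for _ in range(len(donor_heavy_pos))]
    if box is not None:
        tree = cKDTree(wrap_positions(acceptor_pos, box), boxsize=box.array)
        query = wrap_positions(donor_heavy_pos, box)
    else:
        tree = cKDTree(acceptor_pos)
        query = donor_heavy_pos
    return tree.query_ball_point(query, cutoff)


def find_hbonds(
    frame: Structure,
    classes: dict[int, str],
    crit: HBondCriterion = HBondCriterion(),
    table: DonorAcceptorTable | None = None,
) -> list[HBond]:
    """All hydrogen bonds in one frame under the geometric criterion.

    The distance gate (strictly < ``crit.d_oo_max``) applies to the donor
    heavy atom ... acceptor separation; the angular gate (theta <=
    ``crit.theta_max``, inclusive) to the D-H...A arrangement.  Each
    (donor hydrogen, acceptor) pair is reported at most once.  Neighbour
    search is used internally but the result equals all-pairs evaluation.
    """
    classes_arr = class_array(frame, classes)
    if table is None:
        table = build_donor_acceptor_table(frame, classes_arr)
    atoms = frame.atoms
    pos = frame.positions
    box = frame.box

    donor_heavy = np.array([d for d, _ in table.donors], dtype=int)
    if len(donor_heavy) == 0 or len(table.acceptors) == 0:
        return []
    acceptors = np.asarray(table.acceptors, dtype=int)
    neighbor_lists = _acceptor_neighbors(pos[donor_heavy], pos[acceptors], box,
                                         crit.d_oo_max)
    bonds: list[HBond] = []
    for (d_idx, h_idx), neigh in zip(table.donors, neighbor_lists):
        d_res = (atoms[d_idx].chain_id, atoms[d_idx].residue_id)
        for k in neigh:
            a_idx = int(acceptors[k])
            if a_idx == d_idx:
                continue
            if (atoms[a_idx].chain_id, atoms[a_idx].residue_id) == d_res:
                continue  # no intra-residue bonds (covers intra-water)
            d_da = float(min_image_distance(pos[d_idx], pos[a_idx], box))
            if not d_da < crit.d_oo_max:
                continue  # boundary is exclusive
            r, theta = hb_geometry(pos[d_idx], pos[h_idx], pos[a_idx], box)
            if theta <= crit.theta_max:  # boundary inclusive (angle >= 120 deg)
                bonds.append(
                    HBond(
                        donor_atom=atoms[d_idx].serial,
                        hydrogen=atoms[h_idx].serial,
                        acceptor_atom=atoms[a_idx].serial,
                        r=r,
                        theta=theta,
                        d_da=d_da,
                        donor_class=str(classes_arr[d_idx]),
                        acceptor_class=str(classes_arr[a_idx]),
                        n_mediated=(atoms[d_idx].element.upper() == "N"
                                    or atoms[a_idx].element.upper() == "N"),
                    )
                )
    return bonds


def per_water_counts(
    traj: Trajectory,
    classes: dict[int, str],
    crit: HBondCriterion = HBondCriterion(),
) -> HBondSummary:
    """Mean bonds per water over frames, split by partner class.

    A water participates in a bond whether it donates or accepts; a
    water-water bond therefore contributes one bond to each of the two
    molecules.  Partner decomposition satisfies water_water + water_protein
    = total and water_main_chain + water_side_chain = water_protein.
    Frames are averaged per-frame first, then over frames.
    """
    topo_classes = class_array(traj.topology, classes)
    water_mols = {
        i for i, a in enumerate(traj.topology.atoms)
        if topo_classes[i] == WATER_CLASS and a.element.upper() == "O"
    }
    n_waters = len(water_mols)
    if n_waters == 0:
        raise ValueError("trajectory contains no water molecules")
    serial_to_index = {a.serial: i for i, a in enumerate(traj.topology.atoms)}

    frame_means = np.zeros((len(traj.frames), 4))  # total, ww, wmc, wsc
    for fi, frame in enumerate(traj.iter_frames()):
        table = build_donor_acceptor_table(frame, topo_classes)
        bonds = find_hbonds(frame, classes, crit, table=table)
        counts = np.zeros(4)
        for b in bonds:
            di = serial_to_index[b.donor_atom]
            ai = serial_to_index[b.acceptor_atom]
            for this, other, other_cls in ((di, ai, b.acceptor_class),
                                           (ai, di, b.donor_class)):
                mol = table.water_oxygen.get(this)
                if mol is None:
                    continue
                counts[0] += 1
                if other_cls == WATER_CLASS:
                    counts[1] += 1
                elif other_cls == MAIN_CHAIN_CLASS:
                    counts[2] += 1
                elif other_cls in PROTEIN_CLASSES:
                    counts[3] += 1
        frame_means[fi] = counts / n_waters
    mean = frame_means.mean(axis=0)
    return HBondSummary(
        n_frames=len(traj.frames),
        n_waters=n_waters,
        total=float(mean[0]),
        water_water=float(mean[1]),
        water_protein=float(mean[2] + mean[3]),
        water_main_chain=float(mean[2]),
        water_side_chain=float(mean[3]),
    )


# ---------------------------------------------------------------------------
# Water network and ring perception
# ---------------------------------------------------------------------------

def water_network(bonds: list[HBond], water_oxygen_of_serial: dict[int, int]) -> nx.Graph:
    """Undirected simple graph of water molecules linked by water-water bonds.

    Nodes are water-oxygen atom serials; parallel bonds (double donation or
    donor/acceptor in both directions) collapse to one edge.  Bonds with a
    non-water partner are ignored.
    """
    g = nx.Graph()
    for b in bonds:
        u = water_oxygen_of_serial.get(b.donor_atom)
        v = water_oxygen_of_serial.get(b.acceptor_atom)
        if u is None or v is None or u == v:
            continue
        g.add_edge(u, v)
    return g


def water_network_from_frame(
    frame: Structure,
    classes: dict[int, str],
    crit: HBondCriterion = HBondCriterion(),
) -> nx.Graph:
    """Convenience: detect bonds in a frame and build the water network."""
    classes_arr = class_array(frame, classes)
    table = build_donor_acceptor_table(frame, classes_arr)
    bonds = find_hbonds(frame, classes, crit, table=table)
    serial_map = {
        frame.atoms[i].serial: frame.atoms[j].serial
        for i, j in table.water_oxygen.items()
    }
    return water_network(bonds, serial_map)


def find_rings(g: nx.Graph, max_size: int = 6) -> list[list]:
    """Minimal rings (smallest set of smallest rings flavour) up to max_size.

    For every edge, the smallest cycle through that edge is found by
    breadth-first search with the edge removed; rings are deduplicated by
    their node set, so each ring appears once regardless of rotation or
    reflection.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    rings: dict[frozenset, list] = {}
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        try:
            path = nx.shortest_path(g, u, v)
        except nx.NetworkXNoPath:
            path = None
        finally:
            g.add_edge(u, v)
        if path is not None and len(path) <= max_size:
            rings.setdefault(frozenset(path), path)
    return list(rings.values())


def rings_near_class(
    rings: list[list],
    frame: Structure,
    classes: dict[int, str],
    target_class: str,
    cutoff: float = 4.0,
) -> list[list]:
    """Rings with at least one member oxygen within ``cutoff`` of the class.

    The default 4 A cutoff is the hydration-shell distance used for
    surface-proximity queries.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    classes_arr = class_array(frame, classes)
    known = set(classes_arr)
    if target_class not in known:
        raise ValueError(f"no atoms of class {target_class!r} in frame "
                         f"(present: {sorted(known)})")
    pos = frame.positions
    target_pos = pos[[i for i in range(len(frame.atoms)) if classes_arr[i] == target_class]]
    serial_to_index = {a.serial: i for i, a in enumerate(frame.atoms)}
    kept = []
    for ring in rings:
        member_pos = pos[[serial_to_index[s] for s in ring]]
        dmin = np.inf
        for p in member_pos:
            dmin = min(dmin, float(np.min(min_image_distance(p, target_pos, frame.box))))
        if dmin <= cutoff:
            kept.append(ring)
    return kept
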