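"""Hydration profiles, (r, theta) geometry maps, trends and contact maps.

Surface-distance profiles count water oxygens by their minimum distance to
protein atoms (hydrogens included), per atom class.  Geometry maps histogram
the hydrogen-to-acceptor distance r against the deviation-from-linearity
angle theta for donor-H/acceptor pairs.  Scoring admits every donor-H of
every proximal pair (donor heavy atom within the interoxygen gate of the
acceptor) at any angle, so mis-oriented hydrogens of near-neighbour pairs
populate the non-bonded region at r > 3 A and large theta, while bond
counting applies the strict angular criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hydracryst.core import (
    Box,
    HYDROPHILIC_CLASS,
    HYDROPHOBIC_CLASS,
    MAIN_CHAIN_CLASS,
    PROTEIN_CLASSES,
    STANDARD_AMINO_ACIDS,
    Structure,
    Trajectory,
    WATER_CLASS,
    class_array,
    min_image_displacement,
    min_image_distance,
)
from hydracryst.hbonds import (
    HBondCriterion,
    build_donor_acceptor_table,
    hb_geometry,
)

logger = logging.getLogger(__name__)

SCORING_GATE = 3.5  # A: donor-heavy...acceptor proximity gate for geometry maps

PROFILE_CLASSES = ("main_chain", "hydrophilic", "hydrophobic", "whole_surface")
_CLASS_SELECTORS = {
    "main_chain": (MAIN_CHAIN_CLASS,),
    "hydrophilic": (HYDROPHILIC_CLASS,),
    "hydrophobic": (HYDROPHOBIC_CLASS,),
    "whole_surface": PROTEIN_CLASSES,
}

WATER_WATER = "water-water"
WATER_PROTEIN = "water-protein"
PAIR_CLASSES = (WATER_WATER, WATER_PROTEIN)


@dataclass
class HydrationProfile:
    """Mean water count per protein copy vs distance to the surface."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]     # per profile class
    h: float | None = None
    n_frames: int = 1
    n_proteins: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, cnt in self.counts.items():
            for c, v in zip(self.bin_centers, cnt):
                rows.append({"h": self.h, "class": cls, "bin_center": c, "value": v})
        return pd.DataFrame(rows)


@dataclass
class GeometryMap:
    """2D histogram of (r, theta) for scored donor-H/acceptor pairs."""

    r_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray
    pair_class: str
    normalization: str = "raw"        # "raw" or "frame_averaged"
    spill: int = 0                    # geometries outside the histogram range

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        rr, tt = np.meshgrid(self.r_centers, self.theta_centers, indexing="ij")
        return pd.DataFrame({"r": rr.ravel(), "theta": tt.ravel(),
                             "count": self.counts.ravel()})


def default_bins() -> tuple[np.ndarray, np.ndarray]:
    """Default (r, theta) bin edges: 1.2-4.0 A by 0.1 A, 0-90 deg by 5 deg."""
    return (np.round(np.arange(1.2, 4.0 + 1e-9, 0.1), 10),
            np.arange(0.0, 90.0 + 1e-9, 5.0))


@dataclass(frozen=True)
class ProfilePeaks:
    """Characteristic surface distances read off hydration profiles."""

    d_hb: float = 1.8    # A, hydrogen-bond distance
    d_vdw: float = 2.5   # A, van der Waals contact distance

    def __post_init__(self) -> None:
        if not self.d_hb < self.d_vdw:
            raise ValueError("hydrogen-bond distance must be below the VDW distance")


@dataclass
class ContactMap:
    """Boolean residue-residue contact matrix between two chains."""

    chain_a: str
    chain_b: str
    residues_a: list[int]
    residues_b: list[int]
    matrix: np.ndarray
    cutoff: float


# ---------------------------------------------------------------------------
# Surface-distance profiles
# ---------------------------------------------------------------------------

def _min_distances(points: np.ndarray, targets: np.ndarray, box: Box | None,
                   chunk: int = 256) -> np.ndarray:
    """Minimum minimum-image distance from each point to the target set."""
    out = np.full(len(points), np.inf)
    if len(targets) == 0:
        return out
    for start in range(0, len(points), chunk):
        block = points[start:start + chunk]
        d = min_image_displacement(block[:, None, :], targets[None, :, :], box)
        out[start:start + chunk] = np.sqrt((d * d).sum(axis=-1)).min(axis=1)
    return out


def _count_protein_chains(frame: Structure) -> int:
    chains = {
        a.chain_id for a in frame.atoms
        if a.residue_name.upper() in STANDARD_AMINO_ACIDS
    }
    return max(len(chains), 1)


def surface_distance_profile(
    traj: Trajectory,
    classes: dict[int, str],
    bin_width: float = 0.1,
    r_max: float = 6.0,
    h: float | None = None,
) -> HydrationProfile:
    """Histogram of water oxygens vs distance to the protein surface.

    For each class the distance is the minimum to atoms of that class only
    (hydrogens included); ``whole_surface`` uses all protein atoms.  Each
    water oxygen contributes once per class histogram.  Counts are averaged
    over frames and divided by the number of protein chains.
    """
    if r_max <= 0 or bin_width <= 0:
        raise ValueError("bin_width and r_max must be positive")
    topo_classes = class_array(traj.topology, classes)
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    o_idx = np.array(
        [i for i, a in enumerate(traj.topology.atoms)
         if topo_classes[i] == WATER_CLASS and a.element.upper() == "O"],
        dtype=int,
    )
    sel_idx = {
        name: np.array([i for i in range(len(traj.topology.atoms))
                        if topo_classes[i] in members], dtype=int)
        for name, members in _CLASS_SELECTORS.items()
    }
    if len(sel_idx["whole_surface"]) == 0:
        raise ValueError("trajectory contains no protein atoms")
    n_prot = _count_protein_chains(traj.topology)
    accum = {name: np.zeros(len(edges) - 1) for name in PROFILE_CLASSES}
    for coords, box in traj.frames:
        waters = coords[o_idx] if len(o_idx) else np.zeros((0, 3))
        for name, idx in sel_idx.items():
            d = _min_distances(waters, coords[idx], box)
            accum[name] += np.histogram(d, bins=edges)[0]
    n_frames = max(len(traj.frames), 1)
    counts = {name: acc / n_frames / n_prot for name, acc in accum.items()}
    return HydrationProfile(bin_edges=edges, counts=counts, h=h,
                            n_frames=len(traj.frames), n_proteins=n_prot)


# ---------------------------------------------------------------------------
# Geometry maps
# ---------------------------------------------------------------------------

def _pair_matches(donor_cls: str, acceptor_cls: str, pair_class: str) -> bool:
    d_water = donor_cls == WATER_CLASS
    a_water = acceptor_cls == WATER_CLASS
    d_prot = donor_cls in PROTEIN_CLASSES
    a_prot = acceptor_cls in PROTEIN_CLASSES
    if pair_class == WATER_WATER:
        return d_water and a_water
    if pair_class == WATER_PROTEIN:
        return (d_water and a_prot) or (d_prot and a_water)
    raise ValueError(f"unknown pair class {pair_class!r}; expected one of {PAIR_CLASSES}")


def geometry_map(
    traj: Trajectory,
    classes: dict[int, str],
    crit: HBondCriterion = HBondCriterion(),
    pair_class: str = WATER_WATER,
    bins: tuple[np.ndarray, np.ndarray] | None = None,
    oxygen_only: bool = True,
    scoring_gate: float = SCORING_GATE,
    donors: str = "any",
) -> GeometryMap:
    """Accumulate (r, theta) for all scored donor-H/acceptor pairs.

    Scoring admits every hydrogen of every donor whose heavy atom lies
    within ``scoring_gate`` (default 3.5 A, the interoxygen proximity gate)
    of an acceptor, regardless of angle; the angular bond criterion is not
    applied here, so non-bonded near neighbours populate the large-r /
    large-theta region.  With ``oxygen_only`` (default) only O-H...O
    arrangements are scored.  Out-of-range geometries are counted in the
    spill register.  ``donors`` may restrict scoring to water donor groups
    (``"water"``) as in database-style comparisons.
    """
    if donors not in ("any", "water"):
        raise ValueError(f"donors must be 'any' or 'water', got {donors!r}")
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}; expected one of {PAIR_CLASSES}")
    r_edges, theta_edges = bins if bins is not None else default_bins()
    counts = np.zeros((len(r_edges) - 1, len(theta_edges) - 1))
    spill = 0
    topo_classes = class_array(traj.topology, classes)
    atoms = traj.topology.atoms
    for frame in traj.iter_frames():
        table = build_donor_acceptor_table(frame, topo_classes)
        pos = frame.positions
        box = frame.box
        acceptors = np.asarray(table.acceptors, dtype=int)
        if len(acceptors) == 0 or len(table.donors) == 0:
            continue
        from hydracryst.hbonds import _acceptor_neighbors  # shared neighbour search
        d_idx = np.array([d for d, _ in table.donors], dtype=int)
        neigh = _acceptor_neighbors(pos[d_idx], pos[acceptors], box, scoring_gate)
        for (d_i, h_i), lst in zip(table.donors, neigh):
            if oxygen_only and atoms[d_i].element.upper() != "O":
                continue
            if donors == "water" and topo_classes[d_i] != WATER_CLASS:
                continue
            d_res = (atoms[d_i].chain_id, atoms[d_i].residue_id)
            for k in lst:
                a_i = int(acceptors[k])
                if a_i == d_i or (atoms[a_i].chain_id, atoms[a_i].residue_id) == d_res:
                    continue
                if oxygen_only and atoms[a_i].element.upper() != "O":
                    continue
                if not _pair_matches(topo_classes[d_i], topo_classes[a_i], pair_class):
                    continue
                if not min_image_distance(pos[d_i], pos[a_i], box) < scoring_gate:
                    continue
                r, theta = hb_geometry(pos[d_i], pos[h_i], pos[a_i], box)
                ri = np.searchsorted(r_edges, r, side="right") - 1
                ti = np.searchsorted(theta_edges, theta, side="right") - 1
                if 0 <= ri < counts.shape[0] and 0 <= ti < counts.shape[1]:
                    counts[ri, ti] += 1
                else:
                    spill += 1
    return GeometryMap(r_edges=np.asarray(r_edges), theta_edges=np.asarray(theta_edges),
                       counts=counts, pair_class=pair_class, spill=spill)


def map_peak(m: GeometryMap) -> tuple[float, float]:
    """Centre (r*, theta*) of the maximal bin; ties go to smaller r, then theta."""
    if m.counts.sum() == 0:
        raise ValueError("geometry map is empty; no peak defined")
    flat = np.argmax(m.counts)  # argmax returns the first maximum in C order,
    ri, ti = np.unravel_index(flat, m.counts.shape)  # i.e. smallest r then theta
    return float(m.r_centers[ri]), float(m.theta_centers[ti])


# ---------------------------------------------------------------------------
# Hydration-level trends
# ---------------------------------------------------------------------------

def peak_trends(
    profiles: list[HydrationProfile],
    peaks: ProfilePeaks = ProfilePeaks(),
    classes: tuple[str, ...] = ("hydrophilic", "hydrophobic", "main_chain"),
) -> pd.DataFrame:
    """Profile values at the hydrogen-bond and VDW distances vs hydration level.

    Returns a long-format table ordered by h with columns
    (h, class, distance, value) where distance is ``"hb"`` or ``"vdw"``.
    """
    hs = [p.h for p in profiles]
    if any(h is None for h in hs):
        raise ValueError("every profile needs its hydration level h set")
    if len(set(hs)) != len(hs):
        raise ValueError("duplicated hydration levels in profile list")
    rows = []
    for p in sorted(profiles, key=lambda q: q.h):
        for dist_label, d in (("hb", peaks.d_hb), ("vdw", peaks.d_vdw)):
            idx = int(np.searchsorted(p.bin_edges, d, side="right") - 1)
            if not 0 <= idx < len(p.bin_edges) - 1:
                raise ValueError(f"distance {d} A outside profile range")
            for cls in classes:
                rows.append({"h": p.h, "class": cls, "distance": dist_label,
                             "value": float(p.counts[cls][idx])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein-protein contact maps
# ---------------------------------------------------------------------------

def contact_map(frame: Structure, chain_a: str, chain_b: str,
                cutoff: float = 4.5) -> ContactMap:
    """Residue-residue heavy-atom contact map between two protein chains.

    An entry is True when the minimum heavy-atom minimum-image distance
    between the residue pair is below the cutoff (default 4.5 A).
    """
    if chain_a == chain_b:
        raise ValueError("contact map requires two distinct chains")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def residues_of(cid: str) -> dict[int, list[int]]:
        res: dict[int, list[int]] = {}
        for i, a in enumerate(frame.atoms):
            if a.chain_id == cid and not a.is_hydrogen \
                    and a.residue_name.upper() in STANDARD_AMINO_ACIDS:
                res.setdefault(a.residue_id, []).append(i)
        return res

    res_a = residues_of(chain_a)
    res_b = residues_of(chain_b)
    if not res_a or not res_b:
        raise ValueError(f"chain {chain_a if not res_a else chain_b!r} has no protein atoms")
    pos = frame.positions
    ids_a = sorted(res_a)
    ids_b = sorted(res_b)
    matrix = np.zeros((len(ids_a), len(ids_b)), dtype=bool)
    for i, ra in enumerate(ids_a):
        pa = pos[res_a[ra]]
        for j, rb in enumerate(ids_b):
            d = min_image_displacement(pa[:, None, :], pos[res_b[rb]][None, :, :],
                                       frame.box)
            matrix[i, j] = bool(np.sqrt((d * d).sum(axis=-1)).min() < cutoff)
    return ContactMap(chain_a=chain_a, chain_b=chain_b, residues_a=ids_a,
                      residues_b=ids_b, matrix=matrix, cutoff=cutoff)
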