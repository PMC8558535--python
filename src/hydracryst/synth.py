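"""Synthetic inputs: ideal lattices, ring/surface fixtures, bulk-water MC.

Everything the analysis pipeline consumes can be generated here without
downloads: an ice-rule diamond lattice that realises the bulk-water limit of
four hydrogen bonds per molecule, planar water rings, toy protein-surface
slabs with waters at prescribed surface distances, hydrogen-containing
fixture entry sets, and an equilibrated rigid-water Monte Carlo sampler
standing in for bulk-water simulation at 300 K.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from hydracryst.core import Atom, Box, Structure, Trajectory, write_structure
from hydracryst.watermodel import (
    AVOGADRO,
    KB_KCAL,
    COULOMB_K,
    WaterModelParams,
    axis_angle_matrix,
    random_rotation_matrix,
    water_template,
)

logger = logging.getLogger(__name__)

ICE_OO_DISTANCE = 2.76  # A, nearest-neighbour O-O spacing of the ideal lattice


def _water_atoms(oxygen_sites: np.ndarray, hydrogen_sites: np.ndarray,
                 start_serial: int = 1, chain_id: str = "W") -> list[Atom]:
    """Assemble HOH residues from per-molecule O and (2) H positions."""
    atoms: list[Atom] = []
    serial = start_serial
    for i, o in enumerate(oxygen_sites):
        h1, h2 = hydrogen_sites[i]
        for name, el, p in (("O", "O", o), ("H1", "H", h1), ("H2", "H", h2)):
            atoms.append(Atom(serial=serial, name=name, element=el,
                              residue_name="HOH", residue_id=i + 1,
                              chain_id=chain_id, position=np.asarray(p, dtype=float)))
            serial += 1
    return atoms


# ---------------------------------------------------------------------------
# Ice-rule lattice
# ---------------------------------------------------------------------------

def _diamond_oxygens(n_cells: int) -> tuple[np.ndarray, Box]:
    """Oxygen sites of a cubic-ice-like diamond lattice, periodic box."""
    a = 4.0 * ICE_OO_DISTANCE / math.sqrt(3.0)  # conventional cell edge
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    basis = np.vstack([fcc, fcc + 0.25])  # 8 atoms per conventional cell
    cells = np.array(
        [[i, j, k] for i in range(n_cells) for j in range(n_cells) for k in range(n_cells)]
    )
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) / n_cells
    box = Box((n_cells * a,) * 3)
    return frac * box.array, box


def _oo_bond_graph(oxygens: np.ndarray, box: Box) -> list[tuple[int, int]]:
    tree = cKDTree(np.mod(oxygens, box.array), boxsize=box.array)
    pairs = tree.query_pairs(ICE_OO_DISTANCE + 0.1)
    return sorted((min(u, v), max(u, v)) for u, v in pairs)


def _ice_rule_orientation(
    n: int, edges: list[tuple[int, int]], rng: np.random.Generator
) -> list[list[int]]:
    """Assign each O-O link one proton so every oxygen donates exactly twice.

    The O-O bond graph is 4-regular, so an Eulerian circuit exists; orienting
    every edge along the circuit gives each vertex out-degree two, which is
    exactly an ice-rule proton configuration.  The adjacency traversal order
    is shuffled with the supplied RNG, so different seeds give different
    (equally valid) proton configurations.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    for neighbors in adj.values():
        rng.shuffle(neighbors)
    # Hierholzer's algorithm on the multigraph (edge multiset tracked per pair)
    remaining = {}
    for u, v in edges:
        remaining[(u, v)] = remaining.get((u, v), 0) + 1

    def take(u, v):
        key = (min(u, v), max(u, v))
        if remaining.get(key, 0) > 0:
            remaining[key] -= 1
            return True
        return False

    stack = [0]
    circuit: list[int] = []
    cursor = {i: 0 for i in range(n)}
    while stack:
        u = stack[-1]
        advanced = False
        while cursor[u] < len(adj[u]):
            v = adj[u][cursor[u]]
            if take(u, v):
                stack.append(v)
                advanced = True
                break
            cursor[u] += 1
        if not advanced:
            circuit.append(stack.pop())
    donates: list[list[int]] = [[] for _ in range(n)]
    for a, b in zip(circuit, circuit[1:]):
        donates[a].append(b)
    return donates


def make_ice_lattice(
    n_cells_per_axis: int = 3,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    params: WaterModelParams | None = None,
) -> Structure:
    """Periodic cubic-ice-like water lattice obeying the ice rules.

    Oxygens sit on a diamond lattice with nearest O-O spacing 2.76 A inside
    a periodic box; each oxygen carries exactly two hydrogens, one per
    donated O-O link, placed on the (optionally jittered) O-O axis at the
    covalent O-H length.  With zero jitter every molecule donates two and
    accepts two hydrogen bonds -- the tetrahedral bulk limit.
    """
    if n_cells_per_axis < 2:
        raise ValueError("need at least 2 cells per axis for a periodic lattice")
    p = params or WaterModelParams()
    rng = np.random.default_rng(seed)
    oxy, box = _diamond_oxygens(n_cells_per_axis)
    edges = _oo_bond_graph(oxy, box)
    donates = _ice_rule_orientation(len(oxy), edges, rng)
    if jitter_sigma > 0:
        oxy = oxy + rng.normal(0.0, jitter_sigma, size=oxy.shape)
    L = box.array
    hydrogens = np.zeros((len(oxy), 2, 3))
    for i, targets in enumerate(donates):
        if len(targets) != 2:
            raise RuntimeError("ice-rule assignment failed (not 4-regular/connected?)")
        for k, j in enumerate(targets):
            d = oxy[j] - oxy[i]
            d -= L * np.round(d / L)
            hydrogens[i, k] = oxy[i] + p.oh_length * d / np.linalg.norm(d)
    return Structure(atoms=_water_atoms(oxy, hydrogens), box=box,
                     metadata={"fixture": "ice_lattice", "n_cells": n_cells_per_axis})


# ---------------------------------------------------------------------------
# Ring fixture
# ---------------------------------------------------------------------------

def make_ring_fixture(n_members: int = 5, o_o: float = 2.8,
                      params: WaterModelParams | None = None) -> Structure:
    """Planar regular water polygon whose hydrogen-bond cycle closes.

    Each water donates one hydrogen along the polygon edge to its successor;
    the second hydrogen points out of the ring plane so it creates no extra
    bonds.
    """
    if n_members < 3:
        raise ValueError("a ring needs at least 3 members")
    if o_o <= 0:
        raise ValueError("O-O spacing must be positive")
    p = params or WaterModelParams()
    R = o_o / (2.0 * math.sin(math.pi / n_members))  # circumradius
    angles = 2.0 * math.pi * np.arange(n_members) / n_members
    oxy = np.stack([R * np.cos(angles), R * np.sin(angles),
                    np.zeros(n_members)], axis=1)
    hydrogens = np.zeros((n_members, 2, 3))
    for i in range(n_members):
        j = (i + 1) % n_members
        edge = oxy[j] - oxy[i]
        hydrogens[i, 0] = oxy[i] + p.oh_length * edge / np.linalg.norm(edge)
        hydrogens[i, 1] = oxy[i] + np.array([0.0, 0.0, p.oh_length])
    return Structure(atoms=_water_atoms(oxy, hydrogens), box=None,
                     metadata={"fixture": f"ring_{n_members}"})


# ---------------------------------------------------------------------------
# Toy protein surface
# ---------------------------------------------------------------------------

HB_SURFACE_DISTANCE = 1.8   # A, water oxygen to donor hydrogen
VDW_SURFACE_DISTANCE = 2.5  # A, water oxygen to hydrophobic heavy atom


def make_toy_surface(n_waters_hb: int, n_waters_vdw: int, seed: int = 0,
                     spacing: float = 8.0) -> Structure:
    """Pseudo-protein slab with waters at prescribed surface distances.

    The slab is a lattice of minimal residues: serine-like sites expose a
    hydroxyl O-H pointing up (hydrophilic donor), leucine-like sites expose a
    bare CD1 carbon (hydrophobic).  ``n_waters_hb`` waters sit exactly 1.8 A
    above a hydroxyl hydrogen in accepting orientation; ``n_waters_vdw``
    waters sit exactly 2.5 A above a CD1.  Lateral spacing keeps every other
    protein atom farther away than the prescribed distance.
    """
    if n_waters_hb < 0 or n_waters_vdw < 0:
        raise ValueError("water counts must be >= 0")
    n_sites = n_waters_hb + n_waters_vdw
    side = max(int(math.ceil(math.sqrt(max(n_sites, 1)))), 2)
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    serial = 1
    resid = 1

    def add(name, el, res, pos, chain="P"):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=el, residue_name=res,
                          residue_id=resid, chain_id=chain,
                          position=np.asarray(pos, dtype=float)))
        serial += 1

    water_o: list[np.ndarray] = []
    water_h: list[tuple[np.ndarray, np.ndarray]] = []
    site = 0
    for gy in range(side):
        for gx in range(side):
            if site >= max(n_sites, side * side):
                break
            x, y = gx * spacing, gy * spacing
            is_hb = site < n_waters_hb
            res = "SER" if is_hb else "LEU"
            # buried backbone, well below the exposed side-chain atom
            add("N", "N", res, (x, y, -4.0))
            add("CA", "C", res, (x + 1.0, y, -4.0))
            add("C", "C", res, (x + 2.0, y, -4.0))
            add("O", "O", res, (x + 2.0, y + 1.0, -4.0))
            if is_hb:
                add("OG", "O", res, (x, y, 0.0))
                add("HG", "H", res, (x, y, 0.96))
                if site < n_waters_hb:
                    o = np.array([x, y, 0.96 + HB_SURFACE_DISTANCE])
                    water_o.append(o)
                    water_h.append(_accepting_hydrogens(o, rng))
            else:
                add("CD1", "C", res, (x, y, 0.0))
                if site - n_waters_hb < n_waters_vdw:
                    o = np.array([x, y, VDW_SURFACE_DISTANCE])
                    water_o.append(o)
                    water_h.append(_accepting_hydrogens(o, rng))
            resid += 1
            site += 1

    for i, o in enumerate(water_o):
        h1, h2 = water_h[i]
        for name, el, ppos in (("O", "O", o), ("H1", "H", h1), ("H2", "H", h2)):
            atoms.append(Atom(serial=serial, name=name, element=el,
                              residue_name="HOH", residue_id=i + 1,
                              chain_id="W", position=ppos))
            serial += 1
    return Structure(atoms=atoms, box=None,
                     metadata={"fixture": "toy_surface",
                               "n_waters_hb": n_waters_hb,
                               "n_waters_vdw": n_waters_vdw})


def _accepting_hydrogens(oxygen: np.ndarray, rng: np.random.Generator,
                         params: WaterModelParams | None = None):
    """Water hydrogens pointing away from the surface below (+z bisector)."""
    p = params or WaterModelParams()
    half = math.radians(p.hoh_angle) / 2
    h1 = oxygen + p.oh_length * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = oxygen + p.oh_length * np.array([-math.sin(half), 0.0, math.cos(half)])
    return h1, h2


# ---------------------------------------------------------------------------
# Rigid-water Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MCSettings:
    """Bulk-water Metropolis Monte Carlo settings.

    Defaults emulate the bulk reference system: 440 rigid waters at 300 K
    and 1.0 g/cm^3 in a cubic periodic box with a 10 A molecule-based
    cutoff (set on :class:`WaterModelParams`).
    """

    n_waters: int = 440
    temperature: float = 300.0
    density: float = 1.0
    translation_step: float = 0.18     # A, half-width of uniform displacement
    rotation_step: float = 18.0        # degrees, half-width of rotation
    n_sweeps: int = 200                # production sweeps
    equilibration_sweeps: int = 400
    sample_interval: int = 4           # sweeps between saved frames
    seed: int = 0
    auto_tune: bool = True

    def __post_init__(self) -> None:
        if self.n_waters <= 0:
            raise ValueError("n_waters must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def box_edge(self) -> float:
        """Cubic box edge (A) from molecule count and density."""
        mass_g = self.n_waters * 18.015 / AVOGADRO
        return (mass_g / self.density) ** (1.0 / 3.0) * 1e8


def _initial_configuration(settings: MCSettings, params: WaterModelParams,
                           rng: np.random.Generator) -> np.ndarray:
    n = settings.n_waters
    L = settings.box_edge
    m = int(math.ceil(n ** (1.0 / 3.0)))
    spacing = L / m
    template = water_template(params)
    R = np.zeros((n, 3, 3))
    k = 0
    for i in range(m):
        for j in range(m):
            for l in range(m):
                if k >= n:
                    break
                o = (np.array([i, j, l]) + 0.5) * spacing
                R[k] = template @ random_rotation_matrix(rng).T + o
                k += 1
    return R


def _molecule_energy(R: np.ndarray, sites_i: np.ndarray, i: int,
                     L: float, params: WaterModelParams,
                     charges_sq: np.ndarray) -> float:
    """Interaction energy of molecule i's sites with all other molecules.

    Molecule-based spherical cutoff on the O-O minimum-image distance; the
    whole partner molecule is shifted into the same periodic image as its
    oxygen, so rigid molecules are never split by the cutoff.
    """
    dO = R[:, 0, :] - sites_i[0]
    shift = L * np.round(dO / L)
    dO = dO - shift
    d2 = np.einsum("ij,ij->i", dO, dO)
    mask = d2 < params.cutoff ** 2
    mask[i] = False
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return 0.0
    Rj = R[idx] - shift[idx, None, :]
    diff = Rj[:, :, None, :] - sites_i[None, None, :, :]  # (M, site_j, site_i, 3)
    dist = np.sqrt(np.einsum("mjix,mjix->mji", diff, diff))
    e_coul = COULOMB_K * np.sum(charges_sq[None, :, :] / dist)
    doo = dist[:, 0, 0]
    sr6 = (params.sigma_oo / doo) ** 6
    e_lj = 4.0 * params.epsilon_oo * np.sum(sr6 * sr6 - sr6)
    return float(e_coul + e_lj)


def total_energy(R: np.ndarray, L: float, params: WaterModelParams) -> float:
    """Total potential energy (kcal/mol) of a configuration."""
    q = params.site_charges
    charges_sq = np.outer(q, q)
    return 0.5 * sum(
        _molecule_energy(R, R[i], i, L, params, charges_sq) for i in range(len(R))
    )


def mc_bulk_water(settings: MCSettings | None = None,
                  params: WaterModelParams | None = None,
                  extend_until_plateau: bool = False,
                  max_equilibration_sweeps: int | None = None) -> Trajectory:
    """Equilibrated bulk-water sample from rigid-water Metropolis MC.

    Single-molecule moves (random translation plus random rigid rotation
    about the oxygen) are accepted with the Metropolis rule at the set
    temperature.  Energy is Lennard-Jones (O-O) plus Coulomb over all site
    pairs with a molecule-based spherical cutoff.  Frames are recorded every
    ``sample_interval`` sweeps after equilibration; the run is reproducible
    for a fixed seed.  With ``extend_until_plateau`` the equilibration
    window grows in 100-sweep blocks (up to ``max_equilibration_sweeps``,
    default 3x the configured window) until the energy plateau test passes.
    Diagnostics (energy series, acceptance ratio, tuned step sizes, actual
    equilibration length) are stored in the returned trajectory's topology
    metadata under ``"mc_diagnostics"``.
    """
    settings = settings or MCSettings()
    params = params or WaterModelParams()
    L = settings.box_edge
    if params.cutoff > L / 2:
        raise ValueError(
            f"cutoff {params.cutoff} A exceeds half the box edge {L / 2:.2f} A; "
            "increase n_waters or reduce the cutoff"
        )
    rng = np.random.default_rng(settings.seed)
    R = _initial_configuration(settings, params, rng)
    n = settings.n_waters
    beta = 1.0 / (KB_KCAL * settings.temperature)
    q = params.site_charges
    charges_sq = np.outer(q, q)

    dt = settings.translation_step
    dr = math.radians(settings.rotation_step)
    energy = total_energy(R, L, params)
    energy_series = []
    accepted = attempted = 0
    tune_accepted = tune_attempted = 0

    frames: list[tuple[np.ndarray, Box | None]] = []
    box = Box((L, L, L))

    def one_sweep() -> None:
        nonlocal energy, accepted, attempted, tune_accepted, tune_attempted
        for _ in range(n):
            i = int(rng.integers(n))
            old_sites = R[i].copy()
            e_old = _molecule_energy(R, old_sites, i, L, params, charges_sq)
            new_sites = old_sites + rng.uniform(-dt, dt, 3)
            axis = rng.normal(size=3)
            rot = axis_angle_matrix(axis, rng.uniform(-dr, dr))
            new_sites = (new_sites - new_sites[0]) @ rot.T + new_sites[0]
            e_new = _molecule_energy(R, new_sites, i, L, params, charges_sq)
            dE = e_new - e_old
            attempted += 1
            tune_attempted += 1
            if dE <= 0 or rng.random() < math.exp(-beta * dE):
                # keep the molecule's oxygen inside the box
                wrap = L * np.floor(new_sites[0] / L)
                R[i] = new_sites - wrap
                energy += dE
                accepted += 1
                tune_accepted += 1
        energy_series.append(energy)

    eq_cap = (max_equilibration_sweeps
              if max_equilibration_sweeps is not None
              else 3 * settings.equilibration_sweeps)
    eq_target = settings.equilibration_sweeps
    sweep = 0
    while sweep < eq_target:
        one_sweep()
        sweep += 1
        if settings.auto_tune and sweep % 50 == 0:
            acc = tune_accepted / max(tune_attempted, 1)
            if acc < 0.35:
                dt *= 0.85
                dr *= 0.85
            elif acc > 0.55:
                dt *= 1.15
                dr = min(dr * 1.15, math.pi)
            tune_accepted = tune_attempted = 0
        if (extend_until_plateau and sweep == eq_target and eq_target < eq_cap
                and not equilibration_plateau(energy_series, sweep)):
            eq_target = min(eq_target + 100, eq_cap)
    eq_used = eq_target

    for prod_sweep in range(settings.n_sweeps):
        one_sweep()
        if (prod_sweep + 1) % settings.sample_interval == 0:
            frames.append((R.reshape(-1, 3).copy(), box))

    acceptance = accepted / max(attempted, 1)
    if not 0.05 < acceptance < 0.95:
        logger.warning("MC acceptance ratio %.3f outside (0.05, 0.95) "
                       "after auto-tuning", acceptance)
    topology = Structure(
        atoms=_water_atoms(R[:, 0, :], R[:, 1:, :]),
        box=box,
        metadata={
            "fixture": "mc_bulk_water",
            "mc_diagnostics": {
                "energy_series": [float(e) for e in energy_series],
                "acceptance": float(acceptance),
                "translation_step": float(dt),
                "rotation_step_deg": float(math.degrees(dr)),
                "box_edge": float(L),
                "equilibration_sweeps": eq_used,
            },
        },
    )
    return Trajectory(topology=topology, frames=frames)


def equilibration_plateau(energy_series: list[float],
                          equilibration_sweeps: int,
                          rel_tol: float = 0.01) -> bool:
    """True when the running mean has flattened over late equilibration.

    Compares the mean energy of the last two quarters of the equilibration
    window; a relative change below ``rel_tol`` counts as a plateau.
    """
    eq = np.asarray(energy_series[:equilibration_sweeps], dtype=float)
    if len(eq) < 8:
        raise ValueError("energy series too short for a plateau test")
    q3 = eq[len(eq) // 2: 3 * len(eq) // 4]
    q4 = eq[3 * len(eq) // 4:]
    denom = max(abs(q4.mean()), 1e-12)
    return bool(abs(q4.mean() - q3.mean()) / denom < rel_tol)


def oxygen_rdf(traj: Trajectory, r_max: float = 8.0, dr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """O-O radial distribution function g(r) averaged over frames."""
    topo = traj.topology
    o_idx = [i for i, a in enumerate(topo.atoms)
             if a.element.upper() == "O" and a.residue_name.upper() == "HOH"]
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    n = len(o_idx)
    volume = None
    for coords, box in traj.frames:
        L = box.array
        volume = box.volume
        pos = coords[o_idx]
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(min(r_max, float(L.min()) / 2 - 1e-9),
                                 output_type="ndarray")
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= L * np.round(d / L)
        hist += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
    hist /= max(len(traj.frames), 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers ** 2 * dr
    rho = n / volume
    g = hist / (shell * rho * n / 2.0)
    return centers, g


# ---------------------------------------------------------------------------
# Fixture entry sets (for the crystal-database module)
# ---------------------------------------------------------------------------

def make_fixture_entry_set(
    entries: list[tuple[str, str, float, Structure]],
    out_dir: str | Path,
) -> Path:
    """Write synthetic PDB entries plus a CSV manifest of their metadata.

    ``entries`` holds (entry_id, method, resolution, structure) tuples.
    Returns the manifest path; the manifest columns are entry_id, method,
    resolution, path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate entry ids in fixture specification")
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entry_id", "method", "resolution", "path"])
        for entry_id, method, resolution, structure in entries:
            path = out_dir / f"{entry_id}.pdb"
            write_structure(structure, path)
            writer.writerow([entry_id, method, f"{resolution:.2f}", path.name])
    return manifest
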