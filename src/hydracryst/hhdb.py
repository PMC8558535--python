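"""Hydrogen-bond geometry statistics from hydrogen-containing crystal entries.

Mirrors the database-style analysis of hydration water in experimentally
determined structures: filter entries by experimental method and resolution,
then accumulate O-H...O (r, theta) distributions for water donors against
water and protein acceptor oxygens, optionally including symmetry mates.
Waters modelled without hydrogens carry no orientational evidence and are
skipped (and counted), never given inferred hydrogens.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hydracryst.core import (
    Structure,
    Trajectory,
    classify_atoms,
    read_structure,
)
from hydracryst.crystal import apply_space_group, space_group
from hydracryst.hbonds import HBondCriterion
from hydracryst.hydration import (
    GeometryMap,
    PAIR_CLASSES,
    default_bins,
    geometry_map,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntryFilter:
    """Method/resolution gate for crystal entries.

    ``resolution_max`` keeps entries whose resolution number is <= the limit
    (i.e. data at least that good).
    """

    methods: frozenset[str] = frozenset({"neutron"})
    resolution_max: float = 2.0
    require_water_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.resolution_max <= 0:
            raise ValueError("resolution_max must be positive")
        object.__setattr__(self, "methods",
                           frozenset(m.lower() for m in self.methods))


def _has_water_hydrogens(entry: Structure) -> bool:
    water_res = {}
    for a in entry.atoms:
        if a.residue_name.upper() in ("HOH", "WAT", "DOD", "H2O", "SOL", "TIP3"):
            key = (a.chain_id, a.residue_id)
            water_res.setdefault(key, False)
            if a.is_hydrogen:
                water_res[key] = True
    return any(water_res.values())


def filter_entries(entries: list[Structure], f: EntryFilter = EntryFilter()) -> list[Structure]:
    """Entries passing the method/resolution filter.

    Entries missing method or resolution metadata are dropped with a logged
    reason; an empty input gives an empty output.
    """
    kept = []
    for e in entries:
        eid = e.metadata.get("entry_id", "?")
        method = e.metadata.get("method")
        resolution = e.metadata.get("resolution")
        if method is None or resolution is None:
            logger.info("entry %s dropped: missing method/resolution metadata", eid)
            continue
        if str(method).lower() not in f.methods:
            logger.info("entry %s dropped: method %s not in %s", eid, method,
                        sorted(f.methods))
            continue
        if float(resolution) > f.resolution_max:
            logger.info("entry %s dropped: resolution %.2f A worse than %.2f A",
                        eid, float(resolution), f.resolution_max)
            continue
        if f.require_water_hydrogens and not _has_water_hydrogens(e):
            logger.info("entry %s dropped: no water hydrogens modelled", eid)
            continue
        kept.append(e)
    return kept


def load_entry_set(manifest_path: str | Path) -> list[Structure]:
    """Load a directory of PDB entries described by a CSV manifest.

    Manifest columns: entry_id, method, resolution, path (relative to the
    manifest).  The metadata is attached to each structure.
    """
    manifest_path = Path(manifest_path)
    entries = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            s = read_structure(manifest_path.parent / row["path"])
            s.metadata.update(
                entry_id=row["entry_id"],
                method=row["method"],
                resolution=float(row["resolution"]),
            )
            entries.append(s)
    return entries


def _expand_entry(entry: Structure) -> Structure:
    """Apply the entry's space group (when known) to build the full cell."""
    sg_name = str(entry.metadata.get("spacegroup", "P1"))
    if entry.box is None:
        return entry
    try:
        ops = space_group(sg_name)
    except ValueError:
        logger.warning("entry %s: unsupported space group %s, treated as P1",
                       entry.metadata.get("entry_id", "?"), sg_name)
        return entry
    if len(ops) == 1:
        return entry
    return apply_space_group(entry, ops, entry.box)


def crystal_geometry_map(
    entries: list[Structure],
    crit: HBondCriterion = HBondCriterion(),
    bins: tuple[np.ndarray, np.ndarray] | None = None,
    expand_symmetry: bool = False,
) -> dict[str, GeometryMap]:
    """O-H...O geometry maps (water-water and water-protein) over entries.

    Each entry contributes the (r, theta) geometries of its water-donor O-H
    groups against water and protein acceptor oxygens within the scoring
    gate; maps are additive over entries and fully deterministic.  With
    ``expand_symmetry`` the unit-cell contents are generated from the
    entry's space group first, and the cell acts as a periodic box, so
    acceptor environments include symmetry mates.  Raises when no entry
    yields any scorable geometry.
    """
    r_edges, theta_edges = bins if bins is not None else default_bins()
    maps: dict[str, GeometryMap] = {
        pc: GeometryMap(r_edges=np.asarray(r_edges),
                        theta_edges=np.asarray(theta_edges),
                        counts=np.zeros((len(r_edges) - 1, len(theta_edges) - 1)),
                        pair_class=pc)
        for pc in PAIR_CLASSES
    }
    skipped_waterless = 0
    for entry in entries:
        if not _has_water_hydrogens(entry):
            skipped_waterless += 1
            logger.info("entry %s skipped: waters lack hydrogens",
                        entry.metadata.get("entry_id", "?"))
            continue
        frame = _expand_entry(entry) if expand_symmetry else entry
        if expand_symmetry and frame.box is None:
            frame = entry
        traj = Trajectory(topology=frame, frames=[(frame.positions, frame.box)])
        classes = classify_atoms(frame)
        for pc in PAIR_CLASSES:
            m = geometry_map(traj, classes, crit, pair_class=pc,
                             bins=(r_edges, theta_edges), oxygen_only=True,
                             donors="water")
            maps[pc].counts += m.counts
            maps[pc].spill += m.spill
    total = sum(m.counts.sum() for m in maps.values())
    if total == 0:
        raise ValueError(
            f"no scorable O-H...O geometry in any of {len(entries)} entries "
            f"({skipped_waterless} lacked water hydrogens)"
        )
    return maps
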