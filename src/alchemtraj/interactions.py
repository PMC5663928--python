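"""Geometric detection and occupancy of protein-ligand interactions.

A hydrogen bond requires a donor-hydrogen-acceptor angle of at least 120
degrees and a donor-to-acceptor heavy-atom distance of at most 3 A; a
hydrophobic contact requires two flagged atoms of different molecules
within 4 A; a water bridge is a single water simultaneously hydrogen-bonded
(in either donor/acceptor role) to a ligand atom and a protein atom in the
same frame.  Occupancy is the fraction of frames in which an interaction is
present, reported per atom pair or merged per residue pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import constants
from .core import Topology, Trajectory

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_hydrophobic",
    "occupancy_table",
]


@dataclass
class InteractionCriteria:
    hbond_min_angle: float = constants.HBOND_MIN_ANGLE_DEG  # degrees
    hbond_max_heavy_dist: float = constants.HBOND_MAX_HEAVY_DIST_A  # A
    hydrophobic_max_dist: float = constants.HYDROPHOBIC_MAX_DIST_A  # A

    def __post_init__(self) -> None:
        if not 0.0 < self.hbond_min_angle <= 180.0:
            raise ValueError("hbond_min_angle must lie in (0, 180]")
        if self.hbond_max_heavy_dist <= 0 or self.hydrophobic_max_dist <= 0:
            raise ValueError("distance cutoffs must be positive")


@dataclass
class InteractionRecord:
    kind: str  # hbond | water_bridge | hydrophobic
    partner_a: str
    partner_b: str
    bitmap: np.ndarray = field(repr=False, default=None)
    bridge_water: Optional[str] = None

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.bitmap))

    @property
    def n_frames(self) -> int:
        return int(self.bitmap.size)


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle(s) a-vertex-b in degrees; broadcast over leading axes of b."""
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.sum(v1 * v2, axis=-1) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: Optional[InteractionCriteria] = None,
) -> List[Tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the criteria.

    Both inter- and intramolecular pairs are evaluated; molecule filtering
    is applied by the callers that need it.  Acceptors covalently bonded to
    the donor's hydrogen (i.e. the donor itself) are excluded.
    """
    criteria = criteria or InteractionCriteria()
    frame = np.asarray(frame, dtype=float)
    acceptors = np.flatnonzero(topology.acceptor)
    if acceptors.size == 0:
        return []
    bh = topology.bonded_hydrogens
    out: List[Tuple[int, int, int]] = []
    for d in np.flatnonzero(topology.donor):
        d = int(d)
        hydrogens = bh[d]
        if not hydrogens:
            raise ValueError(
                f"donor atom {d} ({topology.atom_label(d)}) has no bonded hydrogen"
            )
        acc = acceptors[acceptors != d]
        if acc.size == 0:
            continue
        dist = np.linalg.norm(frame[acc] - frame[d], axis=1)
        close = acc[dist <= criteria.hbond_max_heavy_dist]
        for h in hydrogens:
            if close.size == 0:
                continue
            ang = _angle_deg(frame[d], frame[h], frame[close])
            for a in close[ang >= criteria.hbond_min_angle]:
                out.append((d, int(h), int(a)))
    return out


def _hbond_partner_map(
    hbonds: List[Tuple[int, int, int]], topology: Topology
) -> Dict[int, set]:
    """Map water resid -> set of non-water heavy atoms it H-bonds with."""
    partners: Dict[int, set] = {}
    cls = topology.molecule_class
    for d, _h, a in hbonds:
        for w, other in ((d, a), (a, d)):
            if cls[w] == "water" and cls[other] != "water":
                partners.setdefault(int(topology.resids[w]), set()).add(other)
    return partners


def detect_water_bridges(
    frame: np.ndarray,
    topology: Topology,
    criteria: Optional[InteractionCriteria] = None,
) -> List[Tuple[int, int, int]]:
    """Single-water bridges as (ligand atom, water resid, protein atom).

    A bridge requires one water residue H-bonded (either role) to at least
    one ligand atom and one protein atom in the same frame; multi-water
    chains are deliberately not reported.
    """
    hbonds = detect_hbonds(frame, topology, criteria)
    partners = _hbond_partner_map(hbonds, topology)
    cls = topology.molecule_class
    out: List[Tuple[int, int, int]] = []
    for water_resid in sorted(partners):
        lig = sorted(a for a in partners[water_resid] if cls[a] == "ligand")
        pro = sorted(a for a in partners[water_resid] if cls[a] == "protein")
        for la in lig:
            for pa in pro:
                out.append((la, water_resid, pa))
    return out


def detect_hydrophobic(
    frame: np.ndarray,
    topology: Topology,
    criteria: Optional[InteractionCriteria] = None,
) -> List[Tuple[int, int]]:
    """Flagged atom pairs of different molecule classes within the cutoff."""
    criteria = criteria or InteractionCriteria()
    frame = np.asarray(frame, dtype=float)
    idx = np.flatnonzero(topology.hydrophobic)
    out: List[Tuple[int, int]] = []
    cls = topology.molecule_class
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            if cls[i] == cls[j]:
                continue
            if np.linalg.norm(frame[i] - frame[j]) <= criteria.hydrophobic_max_dist:
                out.append((int(min(i, j)), int(max(i, j))))
    return out


def occupancy_table(
    traj: Trajectory,
    topology: Topology,
    criteria: Optional[InteractionCriteria] = None,
    grouping: str = "atom",
) -> List[InteractionRecord]:
    """Trajectory-level occupancy of ligand-protein interactions.

    Hydrogen-bond records cover direct ligand-protein bonds; water bridges
    and hydrophobic contacts are reported separately.  ``grouping="residue"``
    merges atom-level records of the same residue pair (presence bitmaps are
    OR'd).  Records are sorted by occupancy descending, ties broken
    lexicographically on the partner identifiers.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if grouping not in ("atom", "residue"):
        raise ValueError("grouping must be 'atom' or 'residue'")
    criteria = criteria or InteractionCriteria()
    cls = topology.molecule_class
    bitmaps: Dict[Tuple, np.ndarray] = {}
    labels: Dict[Tuple, Tuple[str, str, Optional[str]]] = {}

    def label(i: int) -> str:
        return (
            topology.atom_label(i) if grouping == "atom" else topology.residue_label(i)
        )

    def mark(key: Tuple, f: int, partner_a: str, partner_b: str, water=None) -> None:
        if key not in bitmaps:
            bitmaps[key] = np.zeros(traj.n_frames, dtype=bool)
            labels[key] = (partner_a, partner_b, water)
        bitmaps[key][f] = True

    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        for d, _h, a in detect_hbonds(frame, topology, criteria):
            if {cls[d], cls[a]} != {"ligand", "protein"}:
                continue
            lig, pro = (d, a) if cls[d] == "ligand" else (a, d)
            mark(("hbond", label(lig), label(pro)), f, label(lig), label(pro))
        for la, wres, pa in detect_water_bridges(frame, topology, criteria):
            water = f"W{wres}" if grouping == "atom" else None
            key = ("water_bridge", label(la), label(pa)) + ((water,) if water else ())
            mark(key, f, label(la), label(pa), water)
        for i, j in detect_hydrophobic(frame, topology, criteria):
            if {cls[i], cls[j]} != {"ligand", "protein"}:
                continue
            lig, pro = (i, j) if cls[i] == "ligand" else (j, i)
            mark(("hydrophobic", label(lig), label(pro)), f, label(lig), label(pro))

    records = [
        InteractionRecord(
            kind=key[0],
            partner_a=labels[key][0],
            partner_b=labels[key][1],
            bitmap=bm,
            bridge_water=labels[key][2],
        )
        for key, bm in bitmaps.items()
    ]
    records.sort(key=lambda r: (-r.occupancy, r.kind, r.partner_a, r.partner_b))
    return records


def records_to_rows(records: List[InteractionRecord]) -> List[dict]:
    """Flat rows (kind, partners, occupancy, n_frames) for TSV export."""
    return [
        {
            "kind": r.kind,
            "partner_a": r.partner_a,
            "partner_b": r.partner_b,
            "bridge_water": r.bridge_water or "",
            "occupancy": r.occupancy,
            "n_frames": r.n_frames,
            "conserved": r.occupancy >= 0.5,
        }
        for r in records
    ]
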