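"""Readers and writers for structures, trajectories, FEP tables and topologies.

Structure/trajectory formats (PDB fixed-column, XYZ, CHARMM-style DCD) are
handled by MDAnalysis; this module adds the package's containers on top,
plus a line-numbered pre-validation pass for PDB records so malformed input
fails with its location.  FEP energy-difference samples travel as a plain
TSV dialect with columns ``lambda_from  lambda_to  temperature_K
sample_kcal_mol``; the topology sidecar is a YAML document with one record
per atom (name, element, mass, resid, resname, segid, molecule,
donor/acceptor/hydrophobic flags) and a bond list.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .core import FepWindowSamples, KNOWN_ELEMENTS, Topology, Trajectory, classify_residue

__all__ = [
    "TrajectoryIOError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_fep_samples",
    "write_fep_samples",
    "read_topology",
    "write_topology",
]


class TrajectoryIOError(ValueError):
    """Parse or consistency failure in a structure/trajectory/sample file."""


#: standard atomic masses (amu) for the supported element set
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078, "Zn": 65.38,
    "Mn": 54.938, "Fe": 55.845, "Cu": 63.546, "Se": 78.971,
}

#: residue names treated as small-molecule ligands on read
LIGAND_RESNAMES = frozenset({"LIG", "INH", "UNL", "UNK", "DRG"})


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    return path.suffix.lstrip(".").lower()


def _validate_pdb_lines(path: Path) -> None:
    """Line-numbered sanity check of PDB ATOM/HETATM records."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TrajectoryIOError(
                    f"{path}:{lineno}: truncated ATOM record "
                    f"({len(line.rstrip())} columns, need >= 54)"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise TrajectoryIOError(
                        f"{path}:{lineno}: unparseable {what} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None


def _element_from_name(name: str) -> str:
    """Fallback element guess: leading alphabetic of the atom name."""
    two = "".join(c for c in name[:2] if c.isalpha()).capitalize()
    if two in KNOWN_ELEMENTS and two not in ("H",) and len(two) == 2:
        # two-letter match only when unambiguous (e.g. Cl, Na)
        if two in ("Cl", "Br", "Na", "Mg", "Ca", "Zn", "Mn", "Fe", "Cu", "Se"):
            return two
    for c in name:
        if c.isalpha():
            return c.upper()
    raise TrajectoryIOError(f"cannot infer element from atom name {name!r}")


def _topology_from_universe(u: "mda.Universe", path: Path) -> Topology:
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    if hasattr(atoms, "elements") and all(str(e).strip() for e in atoms.elements):
        elements = [str(e).strip().capitalize() for e in atoms.elements]
    else:
        elements = [_element_from_name(n) for n in names]
    unknown = [e for e in elements if e not in KNOWN_ELEMENTS]
    if unknown:
        raise TrajectoryIOError(f"{path}: unknown element(s) {sorted(set(unknown))}")
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    n = len(names)
    try:
        resnames = [str(r) for r in atoms.resnames]
        resids = np.asarray(atoms.resids, dtype=int)
    except Exception:  # format without residue records (e.g. XYZ)
        resnames = ["MOL"] * n
        resids = np.ones(n, dtype=int)
    molecule = [
        "ligand" if rn.upper() in LIGAND_RESNAMES else classify_residue(rn)
        for rn in resnames
    ]
    try:
        segids = [str(s) if str(s).strip() else "A" for s in atoms.segids]
    except Exception:
        segids = ["A"] * n
    return Topology(
        names=names,
        elements=elements,
        masses=masses,
        resids=resids,
        resnames=resnames,
        segids=segids,
        molecule_class=molecule,
    )


def read_structure(path, fmt: Optional[str] = None) -> Tuple[Trajectory, Topology]:
    """Read a single-frame PDB or XYZ structure.

    Returns a one-frame :class:`Trajectory` and a partial
    :class:`Topology` (identity columns filled; interaction flags left
    unset — supply or derive them separately).
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryIOError(f"no such file: {path}")
    fmt_ = _infer_format(path, fmt)
    if fmt_ not in ("pdb", "xyz"):
        raise TrajectoryIOError(f"unsupported structure format {fmt_!r}")
    if fmt_ == "pdb":
        _validate_pdb_lines(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise TrajectoryIOError(f"{path}: {exc}") from exc
    if fmt_ == "xyz":
        # XYZ carries element symbols in the name column
        top = _topology_from_universe(u, path)
    else:
        top = _topology_from_universe(u, path)
    coords = u.atoms.positions.astype(float)[None, :, :]
    return Trajectory(coords, np.array([0.0])), top


def write_structure(coords: np.ndarray, topology: Topology, path, fmt: Optional[str] = None) -> None:
    """Write one frame as PDB or XYZ (format from the file suffix)."""
    path = Path(path)
    fmt_ = _infer_format(path, fmt)
    if fmt_ not in ("pdb", "xyz"):
        raise TrajectoryIOError(f"unsupported structure format {fmt_!r}")
    u = _universe_from(topology, np.asarray(coords, dtype=float)[None, :, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _universe_from(topology: Topology, coords: np.ndarray, dt_ps: float = 1.0) -> "mda.Universe":
    """In-memory MDAnalysis Universe over our containers."""
    n = topology.n_atoms
    res_keys: List[Tuple[str, int, str]] = []
    res_lookup: dict = {}
    resindex = np.empty(n, dtype=int)
    for i in range(n):
        key = (topology.segids[i], int(topology.resids[i]), topology.resnames[i])
        if key not in res_lookup:
            res_lookup[key] = len(res_keys)
            res_keys.append(key)
        resindex[i] = res_lookup[key]
    seg_keys: List[str] = []
    segindex = []
    for segid, _, _ in res_keys:
        if segid not in seg_keys:
            seg_keys.append(segid)
        segindex.append(seg_keys.index(segid))
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(res_keys),
        n_segments=len(seg_keys),
        atom_resindex=resindex,
        residue_segindex=np.array(segindex),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("elements", topology.elements)
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("segids", seg_keys)
    u.load_new(coords.astype(np.float32), format=MemoryReader, dt=dt_ps)
    return u


def write_trajectory(
    traj: Trajectory, topology: Topology, path, fmt: Optional[str] = None
) -> None:
    """Write a multi-frame trajectory as XYZ (text) or DCD (CHARMM-style)."""
    path = Path(path)
    fmt_ = _infer_format(path, fmt)
    if fmt_ not in ("xyz", "dcd"):
        raise TrajectoryIOError(f"unsupported trajectory format {fmt_!r}")
    if traj.n_atoms != topology.n_atoms:
        raise TrajectoryIOError(
            f"trajectory has {traj.n_atoms} atoms but topology {topology.n_atoms}"
        )
    dt = float(traj.timestamps[1] - traj.timestamps[0]) if traj.n_frames > 1 else 1.0
    u = _universe_from(topology, traj.coordinates, dt_ps=dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, dt=dt) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def read_trajectory(
    path,
    topology: Topology,
    fmt: Optional[str] = None,
    interval_ps: Optional[float] = None,
    start_ps: Optional[float] = None,
) -> Trajectory:
    """Read an XYZ or DCD trajectory against a known topology.

    Timestamps come from the file header (DCD) unless ``interval_ps`` is
    supplied; XYZ has no time axis, so ``interval_ps`` defaults to 1 ps.
    ``start_ps`` shifts the first frame's timestamp (default: one interval,
    matching the span-start-exclusive sampling convention).
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryIOError(f"no such file: {path}")
    fmt_ = _infer_format(path, fmt)
    if fmt_ == "xyz":
        from MDAnalysis.coordinates.XYZ import XYZReader as Reader
    elif fmt_ == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        raise TrajectoryIOError(f"unsupported trajectory format {fmt_!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = Reader(str(path))
        try:
            if reader.n_atoms != topology.n_atoms:
                raise TrajectoryIOError(
                    f"{path}: atom count mismatch (file has {reader.n_atoms}, "
                    f"topology has {topology.n_atoms})"
                )
            frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
        finally:
            reader.close()
    n = frames.shape[0]
    if interval_ps is None:
        if fmt_ == "dcd":
            dt = float(reader.ts.dt) if reader.ts.dt else 1.0
        else:
            dt = 1.0
    else:
        dt = float(interval_ps)
    t0 = dt if start_ps is None else float(start_ps)
    timestamps = t0 + dt * np.arange(n)
    return Trajectory(frames, timestamps)


# ---------------------------------------------------------------------------
# FEP sample tables
# ---------------------------------------------------------------------------

_FEP_COLUMNS = ["lambda_from", "lambda_to", "temperature_K", "sample_kcal_mol"]


def write_fep_samples(windows: List[FepWindowSamples], path) -> None:
    frames = []
    for w in windows:
        frames.append(
            pd.DataFrame(
                {
                    "lambda_from": w.lambda_from,
                    "lambda_to": w.lambda_to,
                    "temperature_K": w.temperature,
                    "sample_kcal_mol": w.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_fep_samples(path) -> List[FepWindowSamples]:
    """Read the TSV sample dialect; one group per (from, to, T) in first-
    appearance order.  Bidirectional tables keep forward and reverse groups
    distinct because the (from, to) pair differs."""
    path = Path(path)
    if not path.exists():
        raise TrajectoryIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _FEP_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryIOError(f"{path}: missing column(s) {missing}")
    numeric = {}
    for col in _FEP_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise TrajectoryIOError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at data row {int(bad[0])}"
            )
        if vals.isna().any():
            raise TrajectoryIOError(
                f"{path}: empty cell in column {col!r} at data row "
                f"{int(vals.index[vals.isna()][0])}"
            )
        numeric[col] = vals.to_numpy()
    lf, lt = numeric["lambda_from"], numeric["lambda_to"]
    if np.any((lf < 0) | (lf > 1) | (lt < 0) | (lt > 1)):
        bad = int(np.argmax((lf < 0) | (lf > 1) | (lt < 0) | (lt > 1)))
        raise TrajectoryIOError(
            f"{path}: lambda outside [0, 1] at data row {bad}"
        )
    keys = list(zip(lf, lt, numeric["temperature_K"]))
    order: List[Tuple[float, float, float]] = []
    groups: dict = {}
    for i, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(numeric["sample_kcal_mol"][i])
    out = []
    for key in order:
        samples = np.array(groups[key])
        if samples.size == 0:
            raise TrajectoryIOError(f"{path}: empty sample group {key}")
        out.append(
            FepWindowSamples(
                lambda_from=float(key[0]),
                lambda_to=float(key[1]),
                temperature=float(key[2]),
                samples=samples,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Topology sidecar (YAML)
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, path) -> None:
    doc = {
        "atoms": [
            {
                "name": topology.names[i],
                "element": topology.elements[i],
                "mass": float(topology.masses[i]),
                "resid": int(topology.resids[i]),
                "resname": topology.resnames[i],
                "segid": topology.segids[i],
                "molecule": topology.molecule_class[i],
                "donor": bool(topology.donor[i]),
                "acceptor": bool(topology.acceptor[i]),
                "hydrophobic": bool(topology.hydrophobic[i]),
            }
            for i in range(topology.n_atoms)
        ],
        "bonds": [[int(i), int(j)] for i, j in topology.bonds],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology(path) -> Topology:
    path = Path(path)
    if not path.exists():
        raise TrajectoryIOError(f"no such file: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise TrajectoryIOError(f"{path}: topology sidecar must contain 'atoms'")
    atoms = doc["atoms"]
    try:
        return Topology(
            names=[a["name"] for a in atoms],
            elements=[a["element"] for a in atoms],
            masses=np.array([a["mass"] for a in atoms], dtype=float),
            resids=np.array([a["resid"] for a in atoms], dtype=int),
            resnames=[a["resname"] for a in atoms],
            segids=[a["segid"] for a in atoms],
            molecule_class=[a["molecule"] for a in atoms],
            bonds=[tuple(b) for b in doc.get("bonds", [])],
            donor=np.array([a.get("donor", False) for a in atoms]),
            acceptor=np.array([a.get("acceptor", False) for a in atoms]),
            hydrophobic=np.array([a.get("hydrophobic", False) for a in atoms]),
        )
    except (KeyError, TypeError) as exc:
        raise TrajectoryIOError(f"{path}: malformed atom record ({exc})") from exc
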