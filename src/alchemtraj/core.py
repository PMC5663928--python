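"""Core in-memory containers shared by all analysis stages.

A :class:`Trajectory` is a dense ``(n_frames, n_atoms, 3)`` coordinate array
in Angstrom with per-frame timestamps in picoseconds.  A :class:`Topology`
is a columnar per-atom record (element, mass, residue, interaction flags,
bonds) aligned to the trajectory atom order.  Atom chemistry is *explicit*:
donor/acceptor/hydrophobic flags live in the topology (with a helper that
derives conventional defaults) rather than being re-inferred downstream, so
geometric detections are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "Topology",
    "FepWindowSamples",
    "derive_default_flags",
    "KNOWN_ELEMENTS",
]

#: Elements the I/O layer accepts (common organic/biochemical set).
KNOWN_ELEMENTS = frozenset(
    "H C N O S P F Cl Br I Na K Mg Ca Zn Mn Fe Cu Se".split()
)

MOLECULE_CLASSES = ("protein", "ligand", "water", "ion")

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "SPC"})
ION_RESNAMES = frozenset({"NA", "CL", "SOD", "CLA", "K", "MG", "CA2", "ZN"})


@dataclass
class Trajectory:
    """Cartesian coordinates (A) over frames, with timestamps (ps)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    timestamps: np.ndarray  # (n_frames,), ps, strictly increasing

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.coordinates.shape[0],):
            raise ValueError(
                "timestamps length must equal the number of frames"
            )
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def window(self, start_ps: float, end_ps: float) -> "Trajectory":
        """Frames with start_ps < t <= end_ps (half-open, end-inclusive)."""
        mask = (self.timestamps > start_ps) & (self.timestamps <= end_ps)
        if not mask.any():
            raise ValueError(
                f"no frames in window ({start_ps}, {end_ps}] ps"
            )
        return Trajectory(self.coordinates[mask], self.timestamps[mask])


@dataclass
class Topology:
    """Per-atom identity and interaction annotations.

    All arrays are aligned to the trajectory atom order.  ``bonds`` is a
    list of (i, j) index pairs; bonded hydrogens of donors are derived from
    it.  ``molecule_class`` assigns each atom to protein / ligand / water /
    ion, which downstream stages use to filter intermolecular interactions.
    """

    names: Sequence[str]
    elements: Sequence[str]
    masses: np.ndarray
    resids: np.ndarray
    resnames: Sequence[str]
    segids: Sequence[str]
    molecule_class: Sequence[str]
    bonds: list = field(default_factory=list)
    donor: Optional[np.ndarray] = None
    acceptor: Optional[np.ndarray] = None
    hydrophobic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.names = list(self.names)
        self.elements = list(self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = list(self.resnames)
        self.segids = list(self.segids)
        self.molecule_class = list(self.molecule_class)
        for attr in ("elements", "resnames", "segids", "molecule_class"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch with names ({n})")
        if self.masses.shape != (n,) or self.resids.shape != (n,):
            raise ValueError("masses/resids length mismatch")
        if np.any(self.masses <= 0):
            bad = int(np.argmax(self.masses <= 0))
            raise ValueError(f"non-positive mass for atom {bad} ({self.names[bad]})")
        unknown = set(self.elements) - KNOWN_ELEMENTS
        if unknown:
            raise ValueError(f"unknown element(s): {sorted(unknown)}")
        for cls in self.molecule_class:
            if cls not in MOLECULE_CLASSES:
                raise ValueError(f"unknown molecule class {cls!r}")
        self.bonds = [(int(i), int(j)) for i, j in self.bonds]
        for flag in ("donor", "acceptor", "hydrophobic"):
            v = getattr(self, flag)
            if v is None:
                setattr(self, flag, np.zeros(n, dtype=bool))
            else:
                v = np.asarray(v, dtype=bool)
                if v.shape != (n,):
                    raise ValueError(f"{flag} flag length mismatch")
                setattr(self, flag, v)
        self._validate_flags()

    def _validate_flags(self) -> None:
        heavy = self.is_heavy
        for flag in ("donor", "acceptor", "hydrophobic"):
            v = getattr(self, flag)
            offenders = np.flatnonzero(v & ~heavy)
            if offenders.size:
                i = int(offenders[0])
                raise ValueError(
                    f"{flag} flag set on hydrogen atom {i} ({self.names[i]}); "
                    "interaction flags are only valid on heavy atoms"
                )
        bh = self.bonded_hydrogens
        for i in np.flatnonzero(self.donor):
            if not bh[int(i)]:
                raise ValueError(
                    f"donor atom {int(i)} ({self.names[int(i)]}) has no bonded hydrogen"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    @property
    def bonded_hydrogens(self) -> list:
        """Per-atom list of bonded hydrogen indices."""
        bh: list = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            if self.elements[j] == "H":
                bh[i].append(j)
            if self.elements[i] == "H":
                bh[j].append(i)
        return bh

    def atom_label(self, i: int) -> str:
        return (
            f"{self.segids[i]}/{self.resnames[i]}{self.resids[i]}/{self.names[i]}"
        )

    def residue_label(self, i: int) -> str:
        return f"{self.segids[i]}/{self.resnames[i]}{self.resids[i]}"

    def selection(
        self,
        heavy_only: bool = False,
        molecule: Optional[str] = None,
        resid: Optional[int] = None,
    ) -> np.ndarray:
        """Indices matching simple attribute filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if heavy_only:
            mask &= self.is_heavy
        if molecule is not None:
            mask &= np.array([c == molecule for c in self.molecule_class])
        if resid is not None:
            mask &= self.resids == resid
        return np.flatnonzero(mask)


def classify_residue(resname: str) -> str:
    """Conventional molecule class from a residue name."""
    up = resname.upper()
    if up in WATER_RESNAMES:
        return "water"
    if up in ION_RESNAMES:
        return "ion"
    return "protein"


def derive_default_flags(top: Topology) -> Topology:
    """Fill donor/acceptor/hydrophobic flags with conventional defaults.

    donor      = N or O heavy atom with >= 1 bonded hydrogen
    acceptor   = N or O heavy atom
    hydrophobic = C or S heavy atom bonded only to C, S or H

    Existing ``True`` flags are preserved (explicit annotations win).
    """
    bh = top.bonded_hydrogens
    neighbours: list = [[] for _ in range(top.n_atoms)]
    for i, j in top.bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
    donor = top.donor.copy()
    acceptor = top.acceptor.copy()
    hydrophobic = top.hydrophobic.copy()
    for i in range(top.n_atoms):
        e = top.elements[i]
        if e in ("N", "O"):
            acceptor[i] = True
            if bh[i]:
                donor[i] = True
        elif e in ("C", "S"):
            if all(top.elements[j] in ("C", "S", "H") for j in neighbours[i]):
                hydrophobic[i] = True
    return Topology(
        names=top.names,
        elements=top.elements,
        masses=top.masses,
        resids=top.resids,
        resnames=top.resnames,
        segids=top.segids,
        molecule_class=top.molecule_class,
        bonds=top.bonds,
        donor=donor,
        acceptor=acceptor,
        hydrophobic=hydrophobic,
    )


@dataclass
class FepWindowSamples:
    """Energy-difference samples H(lambda_to) - H(lambda_from) for one window.

    Samples are in kcal/mol at the stated temperature.  ``block_size`` is the
    number of consecutive samples per SEM block (e.g. one block per ns of
    simulation), or ``None`` when block errors are not requested.
    """

    lambda_from: float
    lambda_to: float
    temperature: float
    samples: np.ndarray
    block_size: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        for lam, name in ((self.lambda_from, "lambda_from"), (self.lambda_to, "lambda_to")):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"{name}={lam} outside [0, 1]")
        if self.lambda_from == self.lambda_to:
            raise ValueError("lambda_from and lambda_to must differ")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.block_size is not None and self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.size
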