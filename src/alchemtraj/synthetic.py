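"""Synthetic input generators with analytically known ground truth.

These stand in for MD/FEP engine output so every downstream stage can be
validated against closed forms: Gaussian-fluctuation trajectories with a
prescribed covariance (quasi-harmonic oracle), Gaussian per-window energy
differences (Zwanzig oracle, ``dG = mu - sigma^2 / 2 k_B T``), exactly
linear-in-temperature free-energy series (van't Hoff oracle), and
protein-ligand-water snapshots with geometrically planted interactions
(detection oracle).  All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import constants
from .core import FepWindowSamples, Topology, Trajectory

__all__ = [
    "GaussianTrajectorySpec",
    "FepSampleSpec",
    "SamplingSchedule",
    "ScheduleFrames",
    "HBondPlant",
    "WaterBridgePlant",
    "HydrophobicPlant",
    "PlantedComplexSpec",
    "PlantedComplex",
    "gen_gaussian_trajectory",
    "gen_fep_samples",
    "gen_vant_hoff_series",
    "gen_schedule_frames",
    "gen_planted_complex",
    "isotropic_covariance",
    "two_conformer_structures",
]


# ---------------------------------------------------------------------------
# Gaussian-fluctuation trajectories
# ---------------------------------------------------------------------------

def isotropic_covariance(n_atoms: int, variance: float) -> np.ndarray:
    """Diagonal 3N x 3N covariance with the same per-coordinate variance."""
    return np.eye(3 * n_atoms) * float(variance)


@dataclass
class GaussianTrajectorySpec:
    """Multivariate-Gaussian coordinate fluctuations about a mean structure.

    ``covariance`` is a symmetric PSD matrix over the 3N Cartesian
    coordinates (A^2).  ``ar1_rho`` adds optional AR(1) frame-to-frame
    correlation while preserving the marginal covariance (for block-SEM
    tests); the default is i.i.d. frames.  ``rigid_motion`` composes each
    frame with a random rotation + translation, which alignment must remove.
    """

    n_atoms: int
    n_frames: int
    masses: np.ndarray
    covariance: np.ndarray
    mean_structure: np.ndarray
    rigid_motion: bool = False
    ar1_rho: float = 0.0
    interval_ps: float = constants.SAMPLING_INTERVAL_PS
    seed: int = 0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.mean_structure = np.asarray(self.mean_structure, dtype=float)
        if self.n_atoms < 1 or self.n_frames < 1:
            raise ValueError("n_atoms and n_frames must be >= 1")
        if self.masses.shape != (self.n_atoms,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive, one per atom")
        d = 3 * self.n_atoms
        if self.covariance.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.mean_structure.shape != (self.n_atoms, 3):
            raise ValueError("mean_structure must be (n_atoms, 3)")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix; reject indefinite input."""
    w, v = np.linalg.eigh(cov)
    tol = 1e-10 * max(1.0, float(np.max(np.abs(w), initial=0.0)))
    if np.min(w) < -tol:
        raise ValueError(
            f"covariance is not positive semi-definite "
            f"(min eigenvalue {np.min(w):.3e})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_gaussian_trajectory(spec: GaussianTrajectorySpec) -> Tuple[Trajectory, Topology]:
    """Draw frames x ~ N(mean_structure, covariance), optionally rigid-moved.

    The sample covariance of the (aligned) frames converges to
    ``spec.covariance`` as ``n_frames`` grows.
    """
    rng = np.random.default_rng(spec.seed)
    d = 3 * spec.n_atoms
    factor = _covariance_factor(spec.covariance)
    z = rng.standard_normal((spec.n_frames, d))
    if spec.ar1_rho != 0.0:
        rho = spec.ar1_rho
        scale = math.sqrt(1.0 - rho * rho)
        for t in range(1, spec.n_frames):
            z[t] = rho * z[t - 1] + scale * z[t]
    dev = z @ factor.T
    coords = spec.mean_structure[None, :, :] + dev.reshape(spec.n_frames, spec.n_atoms, 3)
    if spec.rigid_motion:
        for f in range(spec.n_frames):
            rot = _random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, size=3)
            coords[f] = coords[f] @ rot.T + trans
    timestamps = spec.interval_ps * np.arange(1, spec.n_frames + 1)
    traj = Trajectory(coords, timestamps)
    n = spec.n_atoms
    top = Topology(
        names=[f"C{i+1}" for i in range(n)],
        elements=["C"] * n,
        masses=spec.masses,
        resids=np.ones(n, dtype=int),
        resnames=["LIG"] * n,
        segids=["L"] * n,
        molecule_class=["ligand"] * n,
    )
    return traj, top


# ---------------------------------------------------------------------------
# FEP window samples
# ---------------------------------------------------------------------------

@dataclass
class FepSampleSpec:
    """Gaussian energy-difference samples for one lambda window.

    For Gaussian samples the exact exponential-average free energy is
    ``mu - sigma^2 / (2 k_B T)`` (second-cumulant identity), which serves as
    the analytic oracle downstream.
    """

    lambda_from: float
    lambda_to: float
    mu: float
    sigma: float
    n_samples: int
    temperature: float = constants.TEMPERATURE_HIGH_K
    block_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def analytic_free_energy(self) -> float:
        """Exact Zwanzig limit for Gaussian samples (kcal/mol)."""
        return self.mu - self.sigma**2 / (2.0 * constants.kT(self.temperature))


def gen_fep_samples(spec: FepSampleSpec) -> FepWindowSamples:
    rng = np.random.default_rng(spec.seed)
    samples = spec.mu + spec.sigma * rng.standard_normal(spec.n_samples)
    return FepWindowSamples(
        lambda_from=spec.lambda_from,
        lambda_to=spec.lambda_to,
        temperature=spec.temperature,
        samples=samples,
        block_size=spec.block_size,
    )


# ---------------------------------------------------------------------------
# Linear-in-temperature free-energy series
# ---------------------------------------------------------------------------

def gen_vant_hoff_series(
    dH: float, dS: float, temperatures: Sequence[float]
) -> np.ndarray:
    """Exact ``dG(T) = dH - T*dS`` at each temperature (kcal/mol).

    The finite-temperature-difference decomposition applied to any two
    entries recovers (dH, dS) to machine precision.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size < 2:
        raise ValueError("need at least 2 temperatures")
    if np.unique(temps).size != temps.size:
        raise ValueError("duplicate temperatures are not allowed")
    return dH - temps * dS


# ---------------------------------------------------------------------------
# Sampling-schedule bookkeeping
# ---------------------------------------------------------------------------

def ordinal_start_time_ns(span_start_ns: float) -> float:
    """Start *time* of an ordinal nanosecond span.

    Span labels follow the simulation-analysis convention of naming whole
    nanosecond segments: "11-100 ns" is the 11th through 100th nanosecond,
    i.e. time (10, 100] — 90 ns of trajectory.  A span starting at 0 is
    taken literally (time 0).
    """
    return span_start_ns - 1.0 if span_start_ns >= 1.0 else span_start_ns


@dataclass
class SamplingSchedule:
    """Snapshot schedule: frames every ``interval`` ps per replicate.

    ``span_start_ns``/``span_end_ns`` are ordinal nanosecond labels (see
    :func:`ordinal_start_time_ns`): the sampled time interval is
    ``(start_time, span_end]`` with the start instant excluded and the end
    included, so a 90-ns span at 10 ps yields 9,000 frames per replicate."""

    span_start_ns: float
    span_end_ns: float
    interval_ps: float
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.span_end_ns <= self.span_start_ns:
            raise ValueError("span_end must exceed span_start")
        if self.interval_ps <= 0:
            raise ValueError("interval must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ScheduleFrames:
    n_frames_total: int
    n_frames_per_replicate: int
    timestamps_ps: np.ndarray  # one replicate's timestamps


def gen_schedule_frames(schedule: SamplingSchedule) -> ScheduleFrames:
    start_ns = ordinal_start_time_ns(schedule.span_start_ns)
    span_ps = (schedule.span_end_ns - start_ns) * 1000.0
    ratio = span_ps / schedule.interval_ps
    n = round(ratio)
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ValueError(
            f"interval {schedule.interval_ps} ps does not divide the "
            f"{span_ps} ps span evenly"
        )
    start_ps = start_ns * 1000.0
    timestamps = start_ps + schedule.interval_ps * np.arange(1, n + 1)
    return ScheduleFrames(
        n_frames_total=n * schedule.replicates,
        n_frames_per_replicate=n,
        timestamps_ps=timestamps,
    )


# ---------------------------------------------------------------------------
# Conformer-group fixtures for clustering
# ---------------------------------------------------------------------------

def two_conformer_structures(
    n_structures: int,
    n_atoms: int = 5,
    between_rmsd: float = 5.0,
    within_spread: float = 0.3,
    split: float = 0.5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two internally distinct conformer groups with Gaussian spread.

    The second conformer displaces alternating atoms in opposite directions
    (an internal deformation no rigid-body superposition can remove) scaled
    so the superposed RMSD between the group means is ``between_rmsd``.
    ``within_spread`` is the per-structure RMS deviation from its group
    mean.  Returns (structures, group labels).
    """
    if n_structures < 2 or n_atoms < 2:
        raise ValueError("need >= 2 structures and >= 2 atoms")
    rng = np.random.default_rng(seed)
    base = np.zeros((n_atoms, 3))
    base[:, 0] = 4.0 * np.arange(n_atoms)  # zig-zag chain
    base[:, 1] = np.where(np.arange(n_atoms) % 2 == 0, 0.0, 1.5)
    deform = np.zeros((n_atoms, 3))
    deform[:, 2] = np.where(np.arange(n_atoms) % 2 == 0, 1.0, -1.0)
    # remove the rigid component of the deformation, then scale to the
    # requested superposed RMSD between group means
    from .metrics import apply_transform, rmsd, superpose  # local: avoid cycle

    amp = 1.0
    for _ in range(60):
        other = base + deform * amp
        fit = superpose(other, base)
        gap = rmsd(apply_transform(other, fit), base)
        if abs(gap - between_rmsd) < 1e-9:
            break
        amp *= between_rmsd / gap
    other = apply_transform(other, fit)
    n_a = int(round(split * n_structures))
    labels = np.array([0] * n_a + [1] * (n_structures - n_a))
    out = np.empty((n_structures, n_atoms, 3))
    for i in range(n_structures):
        centre = base if labels[i] == 0 else other
        out[i] = centre + rng.normal(
            scale=within_spread / math.sqrt(3.0), size=(n_atoms, 3)
        )
    return out, labels


# ---------------------------------------------------------------------------
# Planted protein-ligand-water complexes
# ---------------------------------------------------------------------------

_OH_BOND = 0.96  # water O-H bond length, A
_NH_BOND = 1.0  # generic donor-H bond length, A
_SITE_SPACING = 25.0  # A between planted sites; far beyond any cutoff

# construction margins: positives satisfy, negatives violate, each criterion
# by at least this much
_DIST_MARGIN = 0.1
_ANGLE_MARGIN = 5.0


@dataclass
class HBondPlant:
    """One donor-H...acceptor geometry between ligand and protein.

    ``negative=True`` plants a geometry that *violates* the detection
    criteria (by the construction margin).  ``present_mask`` optionally
    turns the interaction off in selected frames (the acceptor is displaced
    out of range) for occupancy tests.  ``ligand_is_donor`` chooses which
    side carries the donor.
    """

    distance: float = 2.8
    angle: float = 160.0
    negative: bool = False
    ligand_is_donor: bool = True
    present_mask: Optional[Sequence[bool]] = None


@dataclass
class WaterBridgePlant:
    """A single water simultaneously H-bonded to ligand and protein.

    The water donates one hydrogen to a ligand acceptor and the other to a
    protein acceptor.  ``negative=True`` places the protein-side partner out
    of range, leaving a water bonded to the ligand only (no bridge).
    """

    distance: float = 2.8
    negative: bool = False
    present_mask: Optional[Sequence[bool]] = None


@dataclass
class HydrophobicPlant:
    """A flagged carbon pair (ligand, protein) at a set distance."""

    distance: float = 3.8
    negative: bool = False
    present_mask: Optional[Sequence[bool]] = None


@dataclass
class PlantedComplexSpec:
    hbonds: List[HBondPlant] = field(default_factory=list)
    bridges: List[WaterBridgePlant] = field(default_factory=list)
    hydrophobics: List[HydrophobicPlant] = field(default_factory=list)
    n_frames: int = 1
    seed: int = 0


@dataclass
class PlantedComplex:
    trajectory: Trajectory
    topology: Topology
    #: expected positive detections, as atom-index tuples per kind
    expected_hbonds: List[Tuple[int, int, int]]
    expected_bridges: List[Tuple[int, int, int]]
    expected_hydrophobic: List[Tuple[int, int]]


def _check_margin(plant, kind: str) -> None:
    if kind == "hbond":
        d_ok = plant.distance <= constants.HBOND_MAX_HEAVY_DIST_A - _DIST_MARGIN
        a_ok = plant.angle >= constants.HBOND_MIN_ANGLE_DEG + _ANGLE_MARGIN
        d_bad = plant.distance >= constants.HBOND_MAX_HEAVY_DIST_A + _DIST_MARGIN
        a_bad = plant.angle <= constants.HBOND_MIN_ANGLE_DEG - _ANGLE_MARGIN
        if plant.negative:
            if not (d_bad or a_bad):
                raise ValueError(
                    "negative H-bond plant must violate the distance or angle "
                    f"criterion by the margin ({_DIST_MARGIN} A / {_ANGLE_MARGIN} deg)"
                )
        elif not (d_ok and a_ok):
            raise ValueError(
                "positive H-bond plant must satisfy both criteria by the margin"
            )
    elif kind == "hydrophobic":
        if plant.negative:
            if plant.distance < constants.HYDROPHOBIC_MAX_DIST_A + _DIST_MARGIN:
                raise ValueError(
                    "negative hydrophobic plant must exceed the cutoff by the margin"
                )
        elif plant.distance > constants.HYDROPHOBIC_MAX_DIST_A - _DIST_MARGIN:
            raise ValueError(
                "positive hydrophobic plant must be inside the cutoff by the margin"
            )
    elif kind == "bridge":
        if plant.distance > constants.HBOND_MAX_HEAVY_DIST_A - _DIST_MARGIN:
            raise ValueError(
                "bridge O...acceptor distance must satisfy the H-bond "
                "criterion by the margin"
            )


def _hbond_geometry(distance: float, angle_deg: float, dh: float = _NH_BOND):
    """Donor at origin, H on +x; place the acceptor so that the D-A
    distance and D-H-A angle are exactly as requested.  Raises when the
    geometry is unrealisable."""
    theta = math.radians(angle_deg)
    # law of cosines at H: |DA|^2 = dh^2 + h^2 - 2 dh h cos(theta)
    disc = dh * dh * math.cos(theta) ** 2 - dh * dh + distance * distance
    if disc < 0:
        raise ValueError(
            f"unrealisable H-bond plant: distance {distance} A with "
            f"angle {angle_deg} deg and D-H bond {dh} A"
        )
    h = dh * math.cos(theta) + math.sqrt(disc)
    if h <= 0:
        raise ValueError("unrealisable H-bond plant: acceptor would coincide with H")
    donor = np.zeros(3)
    hydrogen = np.array([dh, 0.0, 0.0])
    acceptor = hydrogen + h * np.array([-math.cos(theta), math.sin(theta), 0.0])
    return donor, hydrogen, acceptor


class _ComplexBuilder:
    def __init__(self, n_frames: int) -> None:
        self.n_frames = n_frames
        self.names: List[str] = []
        self.elements: List[str] = []
        self.masses: List[float] = []
        self.resids: List[int] = []
        self.resnames: List[str] = []
        self.segids: List[str] = []
        self.molclass: List[str] = []
        self.bonds: List[Tuple[int, int]] = []
        self.donor: List[bool] = []
        self.acceptor: List[bool] = []
        self.hydrophobic: List[bool] = []
        # base coordinates plus per-frame displacement overrides
        self.base: List[np.ndarray] = []
        self.displacements: List[Tuple[int, np.ndarray, np.ndarray]] = []
        self._next_resid = {"protein": 100, "water": 500}

    def add_atom(
        self,
        name: str,
        element: str,
        pos: np.ndarray,
        molclass: str,
        resid: int,
        resname: str,
        segid: str,
        mass: float,
        donor: bool = False,
        acceptor: bool = False,
        hydrophobic: bool = False,
    ) -> int:
        idx = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.masses.append(mass)
        self.resids.append(resid)
        self.resnames.append(resname)
        self.segids.append(segid)
        self.molclass.append(molclass)
        self.donor.append(donor)
        self.acceptor.append(acceptor)
        self.hydrophobic.append(hydrophobic)
        self.base.append(np.asarray(pos, dtype=float))
        return idx

    def next_resid(self, kind: str) -> int:
        self._next_resid[kind] += 1
        return self._next_resid[kind]

    def displace_when_absent(
        self, atom: int, present_mask: Optional[Sequence[bool]], direction: np.ndarray
    ) -> None:
        """Push an atom out of interaction range in non-present frames."""
        if present_mask is None:
            return
        mask = np.asarray(present_mask, dtype=bool)
        if mask.shape != (self.n_frames,):
            raise ValueError("present_mask length must equal n_frames")
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        self.displacements.append((atom, ~mask, 3.0 * d))

    def build(self) -> Tuple[Trajectory, Topology]:
        base = np.array(self.base)
        coords = np.repeat(base[None, :, :], self.n_frames, axis=0)
        for atom, absent, shift in self.displacements:
            coords[absent, atom, :] += shift
        timestamps = constants.SAMPLING_INTERVAL_PS * np.arange(1, self.n_frames + 1)
        top = Topology(
            names=self.names,
            elements=self.elements,
            masses=np.array(self.masses),
            resids=np.array(self.resids),
            resnames=self.resnames,
            segids=self.segids,
            molecule_class=self.molclass,
            bonds=self.bonds,
            donor=np.array(self.donor),
            acceptor=np.array(self.acceptor),
            hydrophobic=np.array(self.hydrophobic),
        )
        return Trajectory(coords, timestamps), top


def gen_planted_complex(spec: PlantedComplexSpec) -> PlantedComplex:
    """Build a complex whose interactions are exactly the planted positives.

    Each plant occupies its own site, spaced far apart so no accidental
    cross-site contacts arise; detection stages must therefore recover the
    positive plants with precision = recall = 1.
    """
    b = _ComplexBuilder(spec.n_frames)
    expected_hb: List[Tuple[int, int, int]] = []
    expected_br: List[Tuple[int, int, int]] = []
    expected_ph: List[Tuple[int, int]] = []
    site = 0

    for plant in spec.hbonds:
        _check_margin(plant, "hbond")
        tag = site + 1  # unique per-site atom names within the ligand residue
        origin = np.array([site * _SITE_SPACING, 0.0, 0.0])
        site += 1
        dpos, hpos, apos = _hbond_geometry(plant.distance, plant.angle)
        if plant.ligand_is_donor:
            d = b.add_atom(f"N{tag}", "N", origin + dpos, "ligand", 1, "LIG", "L",
                           14.007, donor=True)
            h = b.add_atom(f"H{tag}", "H", origin + hpos, "ligand", 1, "LIG", "L", 1.008)
            rid = b.next_resid("protein")
            a = b.add_atom("O", "O", origin + apos, "protein", rid, "ALA", "P",
                           15.999, acceptor=True)
        else:
            rid = b.next_resid("protein")
            d = b.add_atom("N", "N", origin + dpos, "protein", rid, "ALA", "P",
                           14.007, donor=True)
            h = b.add_atom("H", "H", origin + hpos, "protein", rid, "ALA", "P", 1.008)
            a = b.add_atom(f"O{tag}", "O", origin + apos, "ligand", 1, "LIG", "L",
                           15.999, acceptor=True)
        b.bonds.append((d, h))
        b.displace_when_absent(a, plant.present_mask, apos - hpos)
        if not plant.negative and plant.present_mask is None:
            expected_hb.append((d, h, a))
        elif not plant.negative:
            expected_hb.append((d, h, a))  # positive in its present frames

    for plant in spec.bridges:
        _check_margin(plant, "bridge")
        tag = site + 1
        origin = np.array([site * _SITE_SPACING, _SITE_SPACING, 0.0])
        site += 1
        rid = b.next_resid("water")
        # water O donates H1 to a ligand acceptor along -x and H2 to a
        # protein acceptor at the ideal HOH angle (104.5 deg)
        w = b.add_atom("OW", "O", origin, "water", rid, "HOH", "W",
                       15.999, donor=True, acceptor=True)
        h1 = b.add_atom("HW1", "H", origin + np.array([-_OH_BOND, 0.0, 0.0]),
                        "water", rid, "HOH", "W", 1.008)
        ang = math.radians(104.5)
        u2 = np.array([math.cos(ang), math.sin(ang), 0.0])
        h2 = b.add_atom("HW2", "H", origin + _OH_BOND * u2,
                        "water", rid, "HOH", "W", 1.008)
        b.bonds.extend([(w, h1), (w, h2)])
        la = b.add_atom(f"O{tag}", "O", origin + np.array([-plant.distance, 0.0, 0.0]),
                        "ligand", 1, "LIG", "L", 15.999, acceptor=True)
        prid = b.next_resid("protein")
        ppos = origin + (plant.distance + (10.0 if plant.negative else 0.0)) * u2
        pa = b.add_atom("O", "O", ppos, "protein", prid, "SER", "P",
                        15.999, acceptor=True)
        b.displace_when_absent(pa, plant.present_mask, u2)
        if not plant.negative:
            expected_br.append((la, rid, pa))  # bridge keyed by water resid

    for plant in spec.hydrophobics:
        _check_margin(plant, "hydrophobic")
        tag = site + 1
        origin = np.array([site * _SITE_SPACING, -_SITE_SPACING, 0.0])
        site += 1
        c1 = b.add_atom(f"C{tag}", "C", origin, "ligand", 1, "LIG", "L",
                        12.011, hydrophobic=True)
        rid = b.next_resid("protein")
        c2 = b.add_atom("CB", "C", origin + np.array([plant.distance, 0.0, 0.0]),
                        "protein", rid, "LEU", "P", 12.011, hydrophobic=True)
        b.displace_when_absent(c2, plant.present_mask, np.array([1.0, 0.0, 0.0]))
        if not plant.negative:
            expected_ph.append((c1, c2))

    if site == 0:
        raise ValueError("planted complex needs at least one plant")
    traj, top = b.build()
    return PlantedComplex(
        trajectory=traj,
        topology=top,
        expected_hbonds=expected_hb,
        expected_bridges=expected_br,
        expected_hydrophobic=expected_ph,
    )
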