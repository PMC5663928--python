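"""Quasi-harmonic configurational entropy from coordinate fluctuations.

The mass-weighted covariance of aligned Cartesian coordinates,
``sigma = M^(1/2) C M^(1/2)``, is eigen-decomposed; each retained
eigenvalue ``lam`` maps to a harmonic mode of angular frequency
``omega = sqrt(k_B T / lam)`` and the entropy is the sum of quantum
harmonic-oscillator mode entropies

    S = k_B * sum_i [ x_i / (exp(x_i) - 1) - ln(1 - exp(-x_i)) ],
    x_i = hbar * omega_i / (k_B T)

(the classical high-temperature form ``k_B * (1 - ln x)`` is available by
flag).  Alignment leaves ~6 near-zero rigid-body modes, which are removed
by an eigenvalue floor and counted in the result.  The binding entropy
change is ``dS_conf = S(complex) - S(free)``, averaged over replicate
simulations with the SEM taken across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import constants
from .core import Topology, Trajectory
from .metrics import apply_transform, superpose

__all__ = [
    "QhEntropyResult",
    "DeltaEntropyResult",
    "mass_weighted_covariance",
    "qh_entropy",
    "delta_entropy",
    "convergence_windows",
    "oscillator_mode_entropy",
]

#: modes with eigenvalues below this (amu*A^2) are treated as rigid-body
#: remnants of the alignment and discarded
EIGENVALUE_FLOOR_AMU_A2 = 1e-8


@dataclass
class QhEntropyResult:
    eigenvalues: np.ndarray  # amu*A^2, descending, retained modes only
    mode_frequencies: np.ndarray  # rad/s
    entropy: float  # kcal/mol/K
    temperature: float  # K
    n_modes_discarded: int
    n_frames_used: int = 0
    window_label: str = ""


@dataclass
class DeltaEntropyResult:
    """Binding entropy change with replicate statistics.

    ``minus_T_delta_S = -T * delta_S`` exactly, at the stated temperature;
    SEM is the sample standard deviation of the replicate values divided by
    sqrt(n_replicates).
    """

    delta_S: float  # kcal/mol/K, mean over replicates
    delta_S_sem: float
    minus_T_delta_S: float  # kcal/mol
    minus_T_delta_S_sem: float
    temperature: float
    per_replicate: np.ndarray


def mass_weighted_covariance(
    traj: Trajectory,
    topology: Topology,
    selection: Optional[np.ndarray] = None,
    reference: Optional[np.ndarray] = None,
    align: bool = True,
) -> np.ndarray:
    """Mass-weighted covariance (amu*A^2) of aligned selected coordinates.

    Each frame is superposed onto ``reference`` (default: first frame) over
    the selection (default: heavy atoms) to remove overall translation and
    rotation, then the 3n x 3n coordinate covariance ``C`` is accumulated
    and returned as ``M^(1/2) C M^(1/2)``.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance requires at least 2 frames")
    if selection is None:
        selection = topology.selection(heavy_only=True)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    n_dof = 3 * selection.size
    if traj.n_frames < n_dof + 1:
        warnings.warn(
            f"only {traj.n_frames} frames for {n_dof} degrees of freedom; "
            "covariance will be rank-deficient",
            stacklevel=2,
        )
    if reference is None:
        reference = traj.coordinates[0]
    x = np.empty((traj.n_frames, selection.size, 3))
    for f in range(traj.n_frames):
        if align:
            fit = superpose(traj.coordinates[f], reference, selection)
            x[f] = apply_transform(traj.coordinates[f], fit)[selection]
        else:
            x[f] = traj.coordinates[f, selection]
    flat = x.reshape(traj.n_frames, n_dof)
    c = np.cov(flat, rowvar=False, ddof=0).reshape(n_dof, n_dof)
    sqrt_m = np.sqrt(np.repeat(topology.masses[selection], 3))
    return sqrt_m[:, None] * c * sqrt_m[None, :]


def oscillator_mode_entropy(x: np.ndarray, classical: bool = False) -> np.ndarray:
    """Per-mode entropy in units of k_B for dimensionless x = hbar*omega/kT."""
    x = np.asarray(x, dtype=float)
    if classical:
        return 1.0 - np.log(x)
    return x / np.expm1(x) - np.log1p(-np.exp(-x))


def qh_entropy(
    covariance: np.ndarray,
    temperature: float,
    classical: bool = False,
    eigenvalue_floor: float = EIGENVALUE_FLOOR_AMU_A2,
    n_frames_used: int = 0,
    window_label: str = "",
) -> QhEntropyResult:
    """Configurational entropy (kcal/mol/K) from a mass-weighted covariance."""
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, float(np.abs(cov).max()))):
        raise ValueError("covariance must be symmetric")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = np.linalg.eigvalsh(cov)[::-1]  # descending
    retained = w[w >= eigenvalue_floor]
    discarded = w.size - retained.size
    if retained.size == 0:
        warnings.warn("all modes below the eigenvalue floor; entropy = 0", stacklevel=2)
        return QhEntropyResult(
            eigenvalues=retained,
            mode_frequencies=np.empty(0),
            entropy=0.0,
            temperature=temperature,
            n_modes_discarded=discarded,
            n_frames_used=n_frames_used,
            window_label=window_label,
        )
    x = constants.hbar_omega_over_kT(retained, temperature)
    entropy = float(constants.BOLTZMANN_KCAL_MOL_K * np.sum(oscillator_mode_entropy(x, classical)))
    return QhEntropyResult(
        eigenvalues=retained,
        mode_frequencies=constants.mode_frequency(retained, temperature),
        entropy=entropy,
        temperature=temperature,
        n_modes_discarded=discarded,
        n_frames_used=n_frames_used,
        window_label=window_label,
    )


def delta_entropy(
    complex_results: Sequence[QhEntropyResult],
    free_results: Sequence[QhEntropyResult],
    temperature: float = constants.TEMPERATURE_HIGH_K,
) -> DeltaEntropyResult:
    """dS_conf = S(complex) - S(free), paired per replicate; -T*dS reported."""
    if len(complex_results) == 0 or len(free_results) == 0:
        raise ValueError("need at least 1 replicate on each side")
    if len(complex_results) != len(free_results):
        raise ValueError(
            f"replicate counts differ: {len(complex_results)} complex vs "
            f"{len(free_results)} free"
        )
    per_rep = np.array(
        [c.entropy - f.entropy for c, f in zip(complex_results, free_results)]
    )
    mean = float(per_rep.mean())
    if per_rep.size > 1:
        sem = float(per_rep.std(ddof=1) / np.sqrt(per_rep.size))
    else:
        sem = 0.0
    return DeltaEntropyResult(
        delta_S=mean,
        delta_S_sem=sem,
        minus_T_delta_S=-temperature * mean,
        minus_T_delta_S_sem=temperature * sem,
        temperature=temperature,
        per_replicate=per_rep,
    )


def convergence_windows(
    traj: Trajectory,
    topology: Topology,
    windows: Sequence[Tuple[float, float, str]],
    temperature: float = constants.TEMPERATURE_HIGH_K,
    selection: Optional[np.ndarray] = None,
    classical: bool = False,
) -> List[QhEntropyResult]:
    """Entropy per time window (start_ns, end_ns, label) for convergence checks.

    Windows use the (start, end] frame convention in ns; each must contain
    at least 2 frames.
    """
    results = []
    for start_ns, end_ns, label in windows:
        sub = traj.window(start_ns * 1000.0, end_ns * 1000.0)
        cov = mass_weighted_covariance(sub, topology, selection=selection)
        results.append(
            qh_entropy(
                cov,
                temperature,
                classical=classical,
                n_frames_used=sub.n_frames,
                window_label=label,
            )
        )
    return results
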