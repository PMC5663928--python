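"""Single source of truth for physical constants and analysis defaults.

Every module imports from here so that cross-module identities
(e.g. ddH + (-T*ddS) == ddG) hold bit-for-bit.
"""

import numpy as np

# --- physical constants ---------------------------------------------------
#: Boltzmann constant in kcal/mol/K (the working energy unit throughout).
BOLTZMANN_KCAL_MOL_K = 1.987204e-3

#: SI constants used only to form the dimensionless hbar*omega/kT ratio of
#: the quasi-harmonic oscillator spectrum.
BOLTZMANN_J_K = 1.380649e-23
HBAR_J_S = 1.054571817e-34
AMU_KG = 1.66053906660e-27
ANGSTROM_M = 1.0e-10

# --- analysis defaults ----------------------------------------------------
#: Simulation / report temperatures (K): the lower and upper legs of the
#: finite-temperature-difference decomposition.
TEMPERATURE_LOW_K = 288.15
TEMPERATURE_HIGH_K = 298.15

#: Hydrogen bond: minimum donor-hydrogen-acceptor angle (deg) and maximum
#: donor-heavy-atom to acceptor-heavy-atom distance (Angstrom).
HBOND_MIN_ANGLE_DEG = 120.0
HBOND_MAX_HEAVY_DIST_A = 3.0

#: Hydrophobic contact: maximum distance between flagged atom pairs (A).
HYDROPHOBIC_MAX_DIST_A = 4.0

#: Conformational clustering: fixed cluster-radius threshold on ligand
#: heavy-atom RMSD (Angstrom).
CLUSTER_RADIUS_A = 1.6

#: Soft-core Lennard-Jones shift parameter (Angstrom^2).
SOFTCORE_ALPHA_A2 = 4.0

#: Alchemical coupling schedule: 21 lambda points = 20 subintervals.
LAMBDA_SCHEDULE = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))

#: Trajectory sampling interval used for clustering/occupancy (ps).
SAMPLING_INTERVAL_PS = 10.0


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return BOLTZMANN_KCAL_MOL_K * temperature


def mode_frequency(eigenvalue_amu_A2: np.ndarray, temperature: float) -> np.ndarray:
    """Quasi-harmonic mode angular frequency (rad/s).

    ``omega = sqrt(k_B T / lambda)`` with ``lambda`` an eigenvalue of the
    mass-weighted coordinate covariance in amu*A^2.
    """
    lam_si = np.asarray(eigenvalue_amu_A2, dtype=float) * AMU_KG * ANGSTROM_M**2
    return np.sqrt(BOLTZMANN_J_K * temperature / lam_si)


def hbar_omega_over_kT(eigenvalue_amu_A2: np.ndarray, temperature: float) -> np.ndarray:
    """Dimensionless oscillator ratio hbar*omega / k_B*T per mode."""
    omega = mode_frequency(eigenvalue_amu_A2, temperature)
    return HBAR_J_S * omega / (BOLTZMANN_J_K * temperature)
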