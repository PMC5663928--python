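"""Quasi-harmonic entropy: closed forms, invariances, replicate statistics."""

import math

import numpy as np
import pytest

from alchemtraj import constants, synthetic
from alchemtraj.core import Trajectory
from alchemtraj.entropy import (
    DeltaEntropyResult,
    convergence_windows,
    delta_entropy,
    mass_weighted_covariance,
    oscillator_mode_entropy,
    qh_entropy,
)


def _gauss(n_atoms, n_frames, var, seed=0, rigid=False):
    spec = synthetic.GaussianTrajectorySpec(
        n_atoms=n_atoms,
        n_frames=n_frames,
        masses=np.full(n_atoms, 12.011),
        covariance=synthetic.isotropic_covariance(n_atoms, var),
        mean_structure=np.array(
            [[4.0 * i, 1.5 * (i % 2), 0.7 * (i % 3)] for i in range(n_atoms)]
        ),
        rigid_motion=rigid,
        seed=seed,
    )
    return synthetic.gen_gaussian_trajectory(spec)


class TestCovariance:
    def test_rigid_trajectory_zero_matrix(self):
        traj, top = _gauss(3, 50, 0.0)
        cov = mass_weighted_covariance(traj, top)
        assert np.allclose(cov, 0.0, atol=1e-18)

    def test_isotropic_eigenvalues_closed_form(self):
        # 1 unconstrained atom, mass m, variance v, alignment off ->
        # eigenvalues all m*v
        m, v = 12.011, 0.2
        traj, top = _gauss(1, 200_00, v, seed=3)
        cov = mass_weighted_covariance(traj, top, align=False)
        w = np.linalg.eigvalsh(cov)
        assert np.allclose(w, m * v, rtol=0.05)

    def test_alignment_recovers_internal_covariance(self):
        # internal fluctuations composed with random rigid motions: the
        # aligned covariance matches the (rotation-free) reference within
        # sampling error
        traj_r, top = _gauss(4, 4000, 0.02, seed=5, rigid=True)
        traj_p, _ = _gauss(4, 4000, 0.02, seed=5, rigid=False)
        ref = traj_p.coordinates[0]
        cov_r = mass_weighted_covariance(traj_r, top, reference=ref)
        cov_p = mass_weighted_covariance(traj_p, top, reference=ref)
        s_r = qh_entropy(cov_r, 298.15).entropy
        s_p = qh_entropy(cov_p, 298.15).entropy
        assert s_r == pytest.approx(s_p, rel=0.02)

    def test_too_few_frames_rejected(self):
        traj, top = _gauss(2, 1, 0.1)
        with pytest.raises(ValueError, match="at least 2 frames"):
            mass_weighted_covariance(Trajectory(traj.coordinates[:1], traj.timestamps[:1]), top)


class TestQhEntropy:
    def test_zero_covariance_zero_entropy(self):
        with pytest.warns(UserWarning, match="below the eigenvalue floor"):
            res = qh_entropy(np.zeros((6, 6)), 298.15)
        assert res.entropy == 0.0
        assert res.n_modes_discarded == 6

    def test_single_mode_unit_ratio(self):
        # mode with hbar*omega/kT = 1: direct evaluation of the oscillator
        # formula gives s/k_B = 1/(e-1) - ln(1 - 1/e) = 1.0406518...
        expected = 1.0 / (math.e - 1.0) - math.log(1.0 - math.exp(-1.0))
        assert expected == pytest.approx(1.0406518522, abs=1e-9)
        assert oscillator_mode_entropy(np.array([1.0]))[0] == pytest.approx(
            expected, abs=1e-12
        )
        # and through the eigenvalue interface: lam chosen so x = 1
        T = 298.15
        lam = (
            constants.HBAR_J_S**2
            / (constants.BOLTZMANN_J_K * T)
            / (constants.AMU_KG * constants.ANGSTROM_M**2)
        )
        res = qh_entropy(np.array([[lam]]), T, eigenvalue_floor=0.0)
        assert res.entropy == pytest.approx(
            constants.BOLTZMANN_KCAL_MOL_K * expected, rel=1e-9
        )

    def test_high_temperature_classical_limit(self):
        # hbar*omega << kT: quantum and classical forms agree within 1%
        x = np.array([1e-3])
        q = oscillator_mode_entropy(x, classical=False)
        c = oscillator_mode_entropy(x, classical=True)
        assert q[0] == pytest.approx(c[0], rel=0.01)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        traj, top = _gauss(3, 2000, 0.05, seed=9)
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = Trajectory(traj.coordinates @ q.T + 7.0, traj.timestamps)
        s1 = qh_entropy(mass_weighted_covariance(traj, top), 298.15).entropy
        s2 = qh_entropy(mass_weighted_covariance(moved, top), 298.15).entropy
        assert s1 == pytest.approx(s2, rel=1e-6)

    def test_monotone_in_covariance_scale(self):
        traj, top = _gauss(3, 1000, 0.05, seed=2)
        cov = mass_weighted_covariance(traj, top, align=False)
        entropies = [
            qh_entropy(c * cov, 298.15).entropy for c in (1.0, 1.5, 2.0, 4.0)
        ]
        assert entropies == sorted(entropies)

    def test_six_rigid_body_modes_discarded(self):
        # after alignment a >= 3-atom rigid-plus-noise system leaves >= 6
        # near-zero modes that the floor removes
        traj, top = _gauss(4, 5000, 0.01, seed=4, rigid=True)
        cov = mass_weighted_covariance(traj, top)
        res = qh_entropy(cov, 298.15)
        assert res.n_modes_discarded >= 6


class TestDeltaEntropy:
    def test_identical_sides_zero(self):
        reps = [_result_with_entropy(0.03)] * 3
        res = delta_entropy(reps, reps, 298.15)
        assert res.delta_S == 0.0 and res.minus_T_delta_S == 0.0

    @pytest.mark.parametrize(
        "ds,expected_int",
        [(-0.125, 37), (-0.067, 20), (-0.09, 27)],
    )
    def test_minus_T_delta_S_integer_rounding(self, ds, expected_int):
        # -T*dS at 298.15 K reproduces the reported integer values
        free = [_result_with_entropy(0.2)] * 3
        cplx = [_result_with_entropy(0.2 + ds)] * 3
        res = delta_entropy(cplx, free, 298.15)
        assert res.minus_T_delta_S == pytest.approx(-298.15 * ds, abs=1e-9)
        assert round(res.minus_T_delta_S) == expected_int

    def test_sem_over_replicates(self):
        cplx = [_result_with_entropy(e) for e in (0.10, 0.12, 0.14)]
        free = [_result_with_entropy(e) for e in (0.20, 0.20, 0.20)]
        res = delta_entropy(cplx, free, 298.15)
        per = np.array([-0.10, -0.08, -0.06])
        assert res.per_replicate == pytest.approx(per)
        assert res.delta_S_sem == pytest.approx(per.std(ddof=1) / math.sqrt(3))
        assert res.minus_T_delta_S == pytest.approx(-298.15 * res.delta_S)

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate counts differ"):
            delta_entropy(
                [_result_with_entropy(0.1)], [_result_with_entropy(0.1)] * 2, 298.15
            )


def _result_with_entropy(e):
    from alchemtraj.entropy import QhEntropyResult

    return QhEntropyResult(
        eigenvalues=np.empty(0),
        mode_frequencies=np.empty(0),
        entropy=e,
        temperature=298.15,
        n_modes_discarded=0,
    )


class TestConvergenceWindows:
    def test_half_windows_agree_for_stationary_input(self):
        traj, top = _gauss(3, 4000, 0.05, seed=6)
        # timestamps are 10 ps apart -> 40 ns total; halves = (0,20], (20,40]
        results = convergence_windows(
            traj, top, [(0.0, 40.0, "full"), (0.0, 20.0, "first"), (20.0, 40.0, "second")]
        )
        full, first, second = (r.entropy for r in results)
        assert first == pytest.approx(second, rel=0.05)
        assert first == pytest.approx(full, rel=0.05)

    def test_full_window_equals_single_call(self):
        traj, top = _gauss(3, 500, 0.05, seed=7)
        res = convergence_windows(traj, top, [(0.0, 5.0, "full")])
        direct = qh_entropy(mass_weighted_covariance(traj, top), 298.15)
        assert res[0].entropy == pytest.approx(direct.entropy, rel=1e-12)

    def test_disjoint_windows_tile_frames(self):
        traj, top = _gauss(3, 600, 0.05, seed=8)
        results = convergence_windows(
            traj, top, [(0.0, 3.0, "a"), (3.0, 6.0, "b")]
        )
        assert sum(r.n_frames_used for r in results) == traj.n_frames

    def test_empty_window_rejected(self):
        traj, top = _gauss(3, 100, 0.05)
        with pytest.raises(ValueError, match="no frames"):
            convergence_windows(traj, top, [(500.0, 600.0, "late")])
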