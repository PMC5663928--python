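import numpy as np
import pytest

from alchemtraj import synthetic


@pytest.fixture
def mixed_planted_complex() -> synthetic.PlantedComplex:
    """One positive plant of each kind plus a negative of each kind."""
    spec = synthetic.PlantedComplexSpec(
        hbonds=[
            synthetic.HBondPlant(2.8, 160.0),
            synthetic.HBondPlant(3.2, 170.0, negative=True),
            synthetic.HBondPlant(2.8, 110.0, negative=True),
        ],
        bridges=[
            synthetic.WaterBridgePlant(2.8),
            synthetic.WaterBridgePlant(2.8, negative=True),
        ],
        hydrophobics=[
            synthetic.HydrophobicPlant(3.5),
            synthetic.HydrophobicPlant(3.9),
            synthetic.HydrophobicPlant(4.1, negative=True),
        ],
        n_frames=1,
        seed=0,
    )
    return synthetic.gen_planted_complex(spec)


@pytest.fixture
def small_gaussian_trajectory():
    """300-frame isotropic Gaussian trajectory of 4 carbon atoms."""
    spec = synthetic.GaussianTrajectorySpec(
        n_atoms=4,
        n_frames=300,
        masses=np.full(4, 12.011),
        covariance=synthetic.isotropic_covariance(4, 0.04),
        mean_structure=np.array(
            [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.2, 1.3, 0.0], [3.0, 1.3, 1.1]]
        ),
        seed=11,
    )
    return synthetic.gen_gaussian_trajectory(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
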