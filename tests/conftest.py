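import numpy as np
import pytest

from httex1 import ConstructSpec, HelixKineticsParams, default_regions, gen_ss_trajectory


@pytest.fixture(scope="session")
def q16_spec():
    return ConstructSpec(polyq_length=16)


@pytest.fixture(scope="session")
def q16_regions(q16_spec):
    return default_regions(q16_spec)


@pytest.fixture(scope="session")
def q16_trajectories(q16_spec, q16_regions):
    """Five synthetic trajectories with nucleation confined to the central region."""
    return [
        gen_ss_trajectory(
            HelixKineticsParams(
                nucleation_region=q16_regions["central"], n_frames=5000, seed=100 + k
            ),
            q16_spec,
        )
        for k in range(5)
    ]


def random_ss_matrix(rng, n_frames, n_residues, p_h=0.4):
    """Random DSSP matrix biased toward helix/coil with some strand content."""
    codes = np.array(list("HCET"))
    probs = np.array([p_h, 0.85 - p_h, 0.1, 0.05])
    return rng.choice(codes, size=(n_frames, n_residues), p=probs)
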