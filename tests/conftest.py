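import numpy as np
import pytest

import conapkpd as cp


@pytest.fixture(scope="session")
def ref_params() -> cp.ModelParameters:
    """The packaged reported parameter set (with assumed baselines)."""
    return cp.reference_parameters()


@pytest.fixture(scope="session")
def control_traj(ref_params) -> cp.Trajectory:
    """Vehicle-control simulation (ConA, no drug) on a 0.01 h grid."""
    return cp.simulate_group(ref_params, dose=0.0, t_end=30.0, grid_step=0.01)


@pytest.fixture(scope="session")
def noiseless_table(ref_params):
    """Noise-free synthetic study under the default trial design."""
    return cp.generate_study(cp.StudyDesign(), ref_params, noise_cv=0.0, seed=0)


def perturbed(truth: dict, names, factor: float = 1.5) -> dict:
    """Alternating x*f / x/f perturbation of generating values (fit inits)."""
    return {
        n: truth[n] * (factor if i % 2 == 0 else 1.0 / factor)
        for i, n in enumerate(names)
    }
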