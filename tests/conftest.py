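import numpy as np
import pytest

from lpdstrat import simulate


@pytest.fixture(scope="session")
def study_cohort():
    """One synthetic cohort at the default study conditions (A=150, G=300, K=4)."""
    return simulate.simulate_cohort(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(study_cohort):
    """A converged estimated-prior decomposition of the study cohort."""
    from lpdstrat import LatentProcessDecomposition
    return LatentProcessDecomposition(
        study_cohort.expression, 4, prior="estimated").fit(seed=3)


def align_theta(theta_est, mu_est, truth):
    """Permute estimated signatures onto the truth by mu-column matching."""
    from lpdstrat import match_signatures
    perm = match_signatures(mu_est, truth.mu)
    out = np.empty_like(theta_est)
    for k in range(theta_est.shape[1]):
        out[:, perm[k]] = theta_est[:, k]
    return out, perm
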