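import numpy as np
import pytest

import kirscreen as ks


def make_traj(times, nuclei, dead=None, well_id="W", condition=None):
    times = np.asarray(times, float)
    nuclei = np.asarray(nuclei, float)
    if dead is None:
        dead = np.zeros_like(nuclei)
    return ks.WellTrajectory(
        well_id=well_id, times=times, nuclei=nuclei, dead=dead, condition=condition
    )


@pytest.fixture(scope="session")
def small_panel():
    return ks.generate_panel(n_kinases=20, n_expressed=12, seed=1)


@pytest.fixture(scope="session")
def small_inhibition(small_panel):
    return ks.generate_inhibition_matrix(
        small_panel, n_inhibitors=10, hits_per_inhibitor=3, seed=2
    )


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return ks.generate_ground_truth(
        small_panel, ["FGF2", "VEGFA"], n_true_per_gf=3, n_shared=2, seed=3
    )


@pytest.fixture()
def exact_config():
    """Noise-free simulator settings for oracle-style checks."""
    return ks.SimConfig(detection_prob=1.0, count_error_cv=0.0)
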