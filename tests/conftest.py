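"""Shared fixtures: synthetic subjects in the regimes the suite probes."""

import numpy as np
import pytest

from rcbvpipe.simulate import AcquisitionSpec, CohortSpec, synthesize_subject

#: voxel set of the planted arterial corner block
ARTERY_BLOCK = {(z, y, x) for z in range(2) for y in range(4) for x in range(4)}


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def noisefree_subject(acq):
    """Noise-free, leak-free subject: the exact forward-model regime."""
    cohort = CohortSpec(noise_sd=0.0, leak_fraction=0.0)
    return synthesize_subject(acq, cohort, "wildtype",
                              np.random.default_rng(101))


@pytest.fixture(scope="session")
def noisy_subject(acq):
    """Baseline SNR 50 (default noise), leak-free."""
    cohort = CohortSpec(noise_sd=20.0, leak_fraction=0.0)
    return synthesize_subject(acq, cohort, "wildtype",
                              np.random.default_rng(202))


@pytest.fixture(scope="session")
def leaky_subject(acq):
    """Noise-free with leakage in a quarter of tumor voxels."""
    cohort = CohortSpec(noise_sd=0.0, leak_fraction=0.25)
    return synthesize_subject(acq, cohort, "mutant",
                              np.random.default_rng(303))
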