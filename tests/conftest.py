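import numpy as np
import pytest

from allomorph import (
    PopulationSpec,
    build_spec,
    gpa_align,
    simulate_dataset,
)


def small_populations(n_per: int = 20):
    """Six small populations spanning a size gradient (fast test design)."""
    labels = ["A", "B", "C", "D", "E", "F"]
    means = np.linspace(0.9, 1.5, 6)
    return tuple(
        PopulationSpec(lb, n_per, float(mu), 0.1) for lb, mu in zip(labels, means)
    )


@pytest.fixture(scope="session")
def small_sim():
    """Simulated dataset + ground truth, 6 populations x 20, angle 40 deg."""
    spec = build_spec(
        angle_e_w=40.0, populations=small_populations(), noise_sd=0.005, seed=7
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    return gpa_align(small_dataset)
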