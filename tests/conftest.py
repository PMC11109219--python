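import numpy as np
import pytest

from seqmeg import simulate
from seqmeg.datatypes import SensorEpochs


@pytest.fixture(scope="session")
def design():
    return simulate.build_design(rng=0)


@pytest.fixture(scope="session")
def small_grid():
    return simulate.make_grid((5, 5, 4), spacing_mm=12.0)


@pytest.fixture(scope="session")
def leadfield(small_grid):
    return simulate.make_leadfield(30, small_grid, rng=1)


@pytest.fixture(scope="session")
def subject(design, leadfield):
    """One simulated subject at default effect/noise parameters."""
    return simulate.simulate_subject(design, leadfield, rng=7)


def make_null_epochs(rng, n_per_class=27, n_channels=30, n_times=50,
                     labels=("A", "B")):
    """Pure-noise epochs with two statistically identical classes."""
    rng = np.random.default_rng(rng)
    data = rng.standard_normal((2 * n_per_class, n_channels, n_times))
    lab = np.array([labels[0]] * n_per_class + [labels[1]] * n_per_class,
                   dtype=object)
    return SensorEpochs(data=data, labels=lab, sfreq=250.0,
                        baseline_window=(0, 5),
                        channel_types=np.array(["mag"] * n_channels,
                                               dtype=object),
                        time_zero=5)
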