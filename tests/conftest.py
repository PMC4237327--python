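import numpy as np
import pytest

import nscglioma as ng

# Study conditions used throughout the suite: per-gene per-division
# mutation probability, NSC pool at birth, sequence multiplicity and
# minimum hit number that place the modelled incidence peak near 80 years
# at a registry-like amplitude.
STUDY = dict(u=3e-7, N0=1e5, S=100.0, n_min=5)
STUDY_K = 0.0385


@pytest.fixture(scope="session")
def coarse_grid():
    """dt = 0.01 y grid: cheap enough for repeated fits, fine enough that
    bin averages and peak locations are stable."""
    return ng.SimulationGrid(dt=0.01, t_max=100.0)


@pytest.fixture(scope="session")
def default_table():
    """Noiseless registry-style table at the generator's default study
    conditions (peak near 80 y, ~20 per 100k person-years)."""
    return ng.generate_synthetic_table(ng.SyntheticTableSpec())


@pytest.fixture(scope="session")
def fitted(default_table, coarse_grid):
    """Calibration of the default table at the generating n_min."""
    return ng.fit(
        default_table, STUDY["n_min"], u=STUDY["u"], N0=STUDY["N0"], grid=coarse_grid
    )
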