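import numpy as np
import pandas as pd
import pytest

from mpmi import catalog, profiles, simulate as sim


@pytest.fixture(scope="session")
def markers_and_primers():
    return catalog.load_catalog()


@pytest.fixture(scope="session")
def markers(markers_and_primers):
    return markers_and_primers[0]


@pytest.fixture(scope="session")
def sim_counts():
    """A 40-sample two-group simulated trial (fold 3, seed 1)."""
    return sim.gen_counts(sim.SimulationConfig(seed=1, n_samples_per_group=20))


@pytest.fixture(scope="session")
def sim_matrix(sim_counts):
    ec_counts, unmapped = profiles.regroup_ko_to_ec(sim_counts.table, sim_counts.ko_to_ec)
    return profiles.normalize(
        ec_counts, set(sim_counts.normalization_ecs), unmapped_mass=unmapped
    )


def balanced_matrix(markers, n_weight=None, d_weight=None):
    """One-sample matrix giving the numerator and denominator sets equal
    total weighted abundance (every N reaction 1/12, every D 1/10)."""
    num = sorted(m.ec_number for m in markers if m.role == "N")
    den = sorted(m.ec_number for m in markers if m.role == "D")
    row = {ec: (n_weight if n_weight is not None else 1.0 / len(num)) for ec in num}
    row.update({ec: (d_weight if d_weight is not None else 1.0 / len(den)) for ec in den})
    return profiles.ECAbundanceMatrix(
        abundance=pd.DataFrame([row], index=["s1"]).astype(float)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
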