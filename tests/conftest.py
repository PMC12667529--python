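import numpy as np
import pandas as pd
import pytest

from aggrefinger import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rod_cloud():
    """Factory: localization cloud for a rod of given length/seed (camera px)."""
    def make(length_nm=150.0, seed=0, sigma_nm=12.0, n_locs=None,
             orientation=0.4, n_frames=100):
        agg = syn.GroundTruthAggregate(
            length_nm=length_nm, sigma_nm=sigma_nm,
            n_localizations=n_locs or max(50, int(2.0 * length_nm)),
            orientation_rad=orientation, center_nm=(5000.0, 5000.0))
        table, truth = syn.simulate_localization_table(
            [agg], n_frames=n_frames, seed=seed)
        return table, agg
    return make


@pytest.fixture(scope="session")
def small_cohort():
    """Study-sized cohort (3/2/5 donors x 2 regions x 3 replicates)."""
    return syn.simulate_cohort(syn.SyntheticCohortSpec(seed=7))


@pytest.fixture(scope="session")
def proteomics_tables():
    enriched = {"P00050": (4.0, 1.0), "P00051": (0.25, 1.0)}
    return syn.simulate_proteomics(n_proteins=100, enriched=enriched,
                                   cv=0.10, seed=3), enriched


from aggrefinger.benchmarks import brute_force_dbscan  # noqa: E402,F401 - shared oracle
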