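import numpy as np
import pytest

from phyllochron.data_model import (CensoringIntervals, GenotypeKey,
                                    LeafRangeWindow, extract_intervals)
from phyllochron.likelihood import PhyllochronParams
from phyllochron.mcem import McemSettings
from phyllochron.simulate import SimulationDesign, simulate_plants


@pytest.fixture
def key():
    return GenotypeKey(line="F252", selection="Early", genotype="FE036",
                       year="2015")


@pytest.fixture
def window():
    return LeafRangeWindow(8, 12)


@pytest.fixture
def params(key, window):
    return PhyllochronParams(
        key=key, window=window, mu_C=160.0, sigma_C=10.0,
        mu=np.array([20.0, 22.0, 24.0, 21.0]),
        sigma=np.array([4.0, 5.0, 4.5, 4.0]))


@pytest.fixture
def fast_settings():
    """Small MCEM budget for structural tests (not accuracy checks)."""
    return McemSettings(n_mc_start=30, n_mc_growth_factor=1.2, n_mc_max=120,
                        burn_in=30, reburn=5, thinning=1, max_iter=8,
                        rel_tol=5e-3, n_avg_final=3, seed=0)


def make_intervals(key, ranks, lower, upper, plant_id="p1", row_id="r1",
                   last_time=400.0, complete=True):
    return CensoringIntervals(
        plant_id=plant_id, key=key, row_id=row_id,
        ranks=np.asarray(ranks), lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float), last_time=last_time,
        complete=complete)


@pytest.fixture
def simulated_dataset(key, params):
    """A medium simulated dataset with its latent appearance times."""
    design = SimulationDesign(
        params={key: params}, n_rows=5, plants_per_row=10,
        schedule=np.arange(100.0, 360.0, 20.0), seed=42)
    series, latent = simulate_plants(design)
    intervals = [extract_intervals(s) for s in series]
    return series, intervals, latent
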