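"""Shared fixtures: small synthetic catalogs and the two reference MCMC runs."""

from __future__ import annotations

import numpy as np
import pytest

import jollyseber as js
from jollyseber.simulate import (
    SimulationConfig,
    right_whale_trajectory,
    simulate,
)

# fixed seeds: the suite is deterministic end to end
SIM_SEED = 1
FIT_SEED = 3
TREND_SIM_SEED = 11
TREND_FIT_SEED = 5


def recovery_config() -> SimulationConfig:
    """150-strong superpopulation, 10 occasions, the reference survival trio,
    detection 0.8 with individual spread 0.5."""
    return SimulationConfig(
        n_years=10,
        m_super=150,
        target_n=np.linspace(80, 120, 10),
        surv_calf=0.955,
        surv_adult_male=0.985,
        surv_adult_female=0.968,
        capture=0.8,
        sigma=0.5,
    )


def trend_config() -> SimulationConfig:
    """Growth at ~2.8%/yr for 15 years, then ~-1%/yr for 5, with detection
    falling from 0.9 to 0.7 during the decline."""
    T = 20
    capture = np.full(T, 0.9)
    capture[15:] = np.linspace(0.86, 0.70, 5)
    return SimulationConfig(
        n_years=T,
        m_super=500,
        target_n=right_whale_trajectory(T, n0=200, growth=1.028, peak_index=14, decline=0.99),
        capture=capture,
    )


@pytest.fixture(scope="session")
def recovery_sim():
    return simulate(recovery_config(), seed=SIM_SEED)


@pytest.fixture(scope="session")
def recovery_data(recovery_sim):
    return js.CatalogData.from_records(
        recovery_sim.records, 1990, 1999, recovery_sim.pre_study_records, n_aug=40
    )


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """The reference posterior: 3 chains x 2,000 retained draws."""
    model = js.JollySeberModel(recovery_data)
    return model.fit(chains=3, n_adapt_burn=1000, n_samples=2000, seed=FIT_SEED)


@pytest.fixture(scope="session")
def trend_sim():
    return simulate(trend_config(), seed=TREND_SIM_SEED)


@pytest.fixture(scope="session")
def trend_fit(trend_sim):
    data = js.CatalogData.from_records(
        trend_sim.records, 1990, 2009, trend_sim.pre_study_records, n_aug=90
    )
    model = js.JollySeberModel(data)
    return model.fit(chains=2, n_adapt_burn=600, n_samples=1200, seed=TREND_FIT_SEED)


@pytest.fixture(scope="session")
def tiny_sim():
    """~20 ever-entering individuals over 5 occasions; fast fits."""
    cfg = SimulationConfig(
        n_years=5,
        m_super=25,
        target_n=np.linspace(15, 20, 5),
        capture=0.8,
        sigma=0.3,
        frac_unknown_sex=0.1,
    )
    return simulate(cfg, seed=21)


@pytest.fixture(scope="session")
def tiny_data(tiny_sim):
    return js.CatalogData.from_records(
        tiny_sim.records, 1990, 1994, tiny_sim.pre_study_records, n_aug=10
    )
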