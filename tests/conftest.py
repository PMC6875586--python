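"""Shared fixtures: one simulated campaign plot table and fitted ensembles,
built once per session since several test modules interrogate them."""

import numpy as np
import pytest

from nicheval.campaign import CampaignConfig, simulate_campaign_plots
from nicheval.ensemble import fit_ensemble

MASTER_SEED = 1


@pytest.fixture(scope="session")
def campaign_data():
    """(space, plots, truths) for the default three-archetype campaign."""
    cfg = CampaignConfig(seed=MASTER_SEED)
    return simulate_campaign_plots(cfg)


@pytest.fixture(scope="session")
def space(campaign_data):
    return campaign_data[0]


@pytest.fixture(scope="session")
def plots(campaign_data):
    return campaign_data[1]


@pytest.fixture(scope="session")
def truths(campaign_data):
    return campaign_data[2]


@pytest.fixture(scope="session")
def rare_fit(campaign_data):
    """Five-method ensemble for the well-specified specialist."""
    space, plots, _ = campaign_data
    return fit_ensemble(plots, "rare_unimodal", space, seed=101)


@pytest.fixture(scope="session")
def bimodal_fit(campaign_data):
    space, plots, _ = campaign_data
    return fit_ensemble(plots, "bimodal_mire", space, seed=103)


@pytest.fixture(scope="session")
def common_fit(campaign_data):
    """GLM/GAM-only fit of the broad generalist (cheap, used where method
    coverage does not matter)."""
    space, plots, _ = campaign_data
    return fit_ensemble(plots, "common_unimodal", space,
                        methods=("GLM", "GAM"), seed=105)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
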