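import pytest

from isopull.pipeline import run_pipeline
from isopull.synth_data import (
    decoy_config,
    simulate_experiment,
    smoke_config,
    tuning_fixture,
)


@pytest.fixture(scope="session")
def smoke_sim():
    """Noiseless ten-background-protein dataset with interactor tiers."""
    return simulate_experiment(smoke_config())


@pytest.fixture(scope="session")
def smoke_result(smoke_sim):
    return run_pipeline(
        smoke_sim.report, smoke_sim.sample_sheet, smoke_sim.protein_db,
        bait_id=smoke_sim.config.bait_id,
    )


@pytest.fixture(scope="session")
def decoy_sim():
    """Low-noise dataset with control-enriched decoys planted at fold 4."""
    return simulate_experiment(decoy_config())


@pytest.fixture(scope="session")
def decoy_result(decoy_sim):
    return run_pipeline(
        decoy_sim.report, decoy_sim.sample_sheet, decoy_sim.protein_db,
        bait_id=decoy_sim.config.bait_id,
    )


@pytest.fixture(scope="session")
def tuning_data():
    """Handcrafted dataset whose bait has ion CV 0.28 and coverage 35%."""
    return tuning_fixture()
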