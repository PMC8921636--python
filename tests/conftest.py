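import pytest

from tcrdetect import (
    ReadModelParams,
    SpikeInDesign,
    fit_read_model,
    generate_spikein_experiment,
)

TRUTH = ReadModelParams(r_e=0.7, eta=1.5, lam=1.3)
T_READ = 10**6


@pytest.fixture(scope="session")
def truth_params():
    return TRUTH


@pytest.fixture(scope="session")
def study_experiment():
    """One seeded experiment with the study layout (9 tiers x 5 clones x 6 reps)."""
    return generate_spikein_experiment(SpikeInDesign(seed=42), TRUTH, t_read=T_READ)


@pytest.fixture(scope="session")
def calibrated(study_experiment):
    """Maximum-likelihood fit to the TRB spike-ins of the seeded experiment."""
    obs = study_experiment.calibration_observations("TRB")
    return fit_read_model(obs, t_read=T_READ)
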