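import pytest

from tirzepbpk import (
    CalibrationSpec, adult_model_builder, build_model, calibrate,
    default_tirzepatide, reference_adult,
)
from tirzepbpk.drug import compute_distribution

#: Training-study observed single-dose 5 mg PK parameters (adult).
TRAINING_TARGETS = {"auc_0_inf": 90500.0, "cmax": 397.0, "t_half": 123.0}

#: Fixed seed for every stochastic test in the suite.
SUITE_SEED = 20231128


@pytest.fixture(scope="session")
def drug():
    return default_tirzepatide()


@pytest.fixture(scope="session")
def adult():
    return reference_adult()


@pytest.fixture(scope="session")
def adult_distribution(drug, adult):
    return compute_distribution(drug, adult)


@pytest.fixture(scope="session")
def default_model(adult, drug, adult_distribution):
    """Reference adult with the package default kinetic constants."""
    return build_model(adult, drug, distribution=adult_distribution)


@pytest.fixture(scope="session")
def calibration_result(adult, drug):
    """Middle-out calibration to the training-study observed parameters."""
    spec = CalibrationSpec(objective_targets=dict(TRAINING_TARGETS),
                           n_samples=1500, seed=SUITE_SEED, polish=True)
    builder = adult_model_builder(adult, drug)
    return calibrate(builder, spec)


@pytest.fixture(scope="session")
def calibrated_model(adult, drug, adult_distribution, calibration_result):
    best = calibration_result.best_parameters
    return build_model(adult, drug, distribution=adult_distribution,
                       ka=best["ka"], cl_pept_factor=best["cl_pept_factor"],
                       cl_renal=best["cl_renal"])
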