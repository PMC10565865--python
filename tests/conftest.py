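import dataclasses

import pytest

from fallsim.cohort import (
    EXP1_DESIGN,
    EXP2_COHORT,
    EXP2_DESIGN,
    generate_cohort,
    generate_exp1_cohort,
    generate_trials,
)

TRUE_L_EXP1 = 1.21
TRUE_L_EXP2 = 1.30
TRUE_MU_EXP2 = 0.18


@pytest.fixture(scope="session")
def exp1_roster():
    return generate_exp1_cohort(seed=101)


@pytest.fixture(scope="session")
def exp2_roster():
    return generate_cohort(EXP2_COHORT, seed=202)


@pytest.fixture(scope="session")
def exp1_noiseless(exp1_roster):
    design = dataclasses.replace(EXP1_DESIGN, noise_sd_omega=0.0)
    dataset, _ = generate_trials(exp1_roster, design, seed=11, true_L=TRUE_L_EXP1)
    return dataset


@pytest.fixture(scope="session")
def exp1_noisy(exp1_roster):
    dataset, _ = generate_trials(exp1_roster, EXP1_DESIGN, seed=12, true_L=TRUE_L_EXP1)
    return dataset


@pytest.fixture(scope="session")
def exp2_noiseless(exp2_roster):
    design = dataclasses.replace(EXP2_DESIGN, noise_sd_omega=0.0)
    dataset, _ = generate_trials(
        exp2_roster, design, seed=21, true_L=TRUE_L_EXP2, true_mu_F=TRUE_MU_EXP2
    )
    return dataset


@pytest.fixture(scope="session")
def exp2_noisy(exp2_roster):
    dataset, _ = generate_trials(
        exp2_roster, EXP2_DESIGN, seed=22, true_L=TRUE_L_EXP2, true_mu_F=TRUE_MU_EXP2
    )
    return dataset
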