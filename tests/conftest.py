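import numpy as np
import pytest

from lambdascape import counting, fitness, phenotyping, synthetic

MU_SUPPLY_SCALED = 7.7e-8 * 500  # desk-scale mu preserving the flask-scale N*mu


@pytest.fixture(scope="session")
def model():
    return synthetic.GroundTruthModel.default(seed=0)


@pytest.fixture(scope="session")
def truth(model):
    return synthetic.generate_true_landscapes(model)


@pytest.fixture(scope="session")
def phenotypes(truth):
    return phenotyping.phenotype_table(truth["A"], truth["E"])


@pytest.fixture(scope="session")
def clean_sample(truth):
    """Error-free t0/t4 read sample of environment C at 20k UMIs."""
    f0 = synthetic.generate_library_frequencies(seed=1)
    return synthetic.simulate_competition_reads(
        truth["C"], f0, n_umis=20_000, per_base_error=0.0, seed=2
    )


@pytest.fixture(scope="session")
def noisy_sample(truth):
    """Default-error sample (per-base error 0.001) of environment C."""
    f0 = synthetic.generate_library_frequencies(seed=1)
    return synthetic.simulate_competition_reads(
        truth["C"], f0, n_umis=20_000, per_base_error=0.001, seed=3
    )


@pytest.fixture(scope="session")
def rate_table(clean_sample):
    t0, t4 = clean_sample
    return fitness.selection_rates(
        counting.count_sample(t0, 3, "C0", "t0"),
        counting.count_sample(t4, 3, "C0", "t4"),
    )
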