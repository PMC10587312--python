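import hypothesis
import pytest

from ceftripk import reference
from ceftripk.synthetic import GeneratorConfig, generate_cohort

hypothesis.settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=30,
    deadline=None,
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_patients():
    return reference.patients()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (the study's conditions), seed 1."""
    cfg = GeneratorConfig(seed=1)
    patients, doses, samples, truth = generate_cohort(cfg)
    return cfg, patients, doses, samples, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, censoring-free cohort for exact recovery checks."""
    cfg = GeneratorConfig(seed=3, assay_cv=0.0, lloq_ug_ml=1e-6)
    patients, doses, samples, truth = generate_cohort(cfg)
    return cfg, patients, doses, samples, truth
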