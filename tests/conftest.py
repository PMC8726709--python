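import warnings

import pytest

from contamcheck.simdata import Genome, generate_genome

# per-read-length warnings from the carryover estimator are expected on
# QC-trimmed libraries and would otherwise drown test output
warnings.filterwarnings("ignore", message=".*non-uniform read lengths.*")


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return generate_genome(2000, 0.5, 42, "ref")


@pytest.fixture(scope="session")
def phage_genome() -> Genome:
    return generate_genome(5386, 0.45, 7, "phage")


@pytest.fixture(scope="session")
def default_assessment(tmp_path_factory):
    """Full pipeline on the contamination-confounded study (computed once)."""
    from contamcheck.evaluation import assess_study
    out = tmp_path_factory.mktemp("e2e_default")
    return assess_study("default", seed=1, outdir=str(out))


@pytest.fixture(scope="session")
def independent_assessment(tmp_path_factory):
    """Full pipeline on the genomically independent counterfactual."""
    from contamcheck.evaluation import assess_study
    out = tmp_path_factory.mktemp("e2e_independent")
    return assess_study("independent", seed=1, outdir=str(out))
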