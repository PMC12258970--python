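import numpy as np
import pytest

from sigkit.schemas import SBS96
from sigkit.signatures import SignatureSet
from sigkit.simulate import CohortScenario, generate_reference_signatures, simulate_cohort


@pytest.fixture(scope="session")
def four_signatures() -> SignatureSet:
    """Four well-separated synthetic signatures (pairwise cosine < 0.5)."""
    return generate_reference_signatures(4, max_pairwise_cosine=0.5, seed=2024)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort with fixed 5,000-mutation burdens (fast fixture)."""
    scenario = CohortScenario(
        n_samples=60,
        prevalence=(0.8, 0.7, 0.9, 0.53),
        burden_log10_mean=np.log10(5000),
        burden_log10_sd=0.0,
        seed=11,
    )
    return simulate_cohort(scenario, make_records=False)


@pytest.fixture(scope="session")
def disjoint_refs() -> SignatureSet:
    """Two references with disjoint support (forces unique mixture weights)."""
    a = np.zeros(96)
    b = np.zeros(96)
    a[:48] = np.linspace(1, 2, 48)
    b[48:] = np.linspace(2, 1, 48)
    a /= a.sum()
    b /= b.sum()
    return SignatureSet.from_array(np.column_stack([a, b]), names=["R1", "R2"])
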