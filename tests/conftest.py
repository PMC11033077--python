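import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from equicomorb.model import ComorbidityEquivalenceModel
from equicomorb.phecodes import PhecodeMap
from equicomorb.simulate import GeneratorConfig, default_phenotypes, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (2 sites x 20,000 patients, 40 labeled
    phenotypes, seed 1) fitted end-to-end; shared across the session."""
    bundle = generate_cohort(GeneratorConfig(seed=1))
    results = ComorbidityEquivalenceModel.from_cohort_bundle(bundle).fit()
    return bundle, results


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort configuration for smoke and pipeline tests."""
    return GeneratorConfig(
        n_patients=1500,
        seed=11,
        phenotypes=tuple(default_phenotypes(n_per_class=2, prevalence=0.08)),
        n_filler_phecodes=10,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def toy_map() -> PhecodeMap:
    frame = pd.DataFrame(
        [
            ("295.00", "ICD9", "295.1", ""),
            ("295.01", "ICD9", "295.1", ""),
            ("F20", "ICD10", "295.1", ""),
            ("401.0", "ICD9", "401.1", "401-401.99"),
            ("I10", "ICD10", "401.1", "401-401.99"),
            ("401.9", "ICD9", "401.2", ""),
            ("I15", "ICD10", "401.2", ""),
        ],
        columns=["code", "vocabulary", "phecode", "exclude_range"],
    )
    return PhecodeMap.from_frame(frame)


def make_status(case_control: dict[str, np.ndarray]):
    """Build a PhenotypeStatusMatrix directly from 0/1/-1 status vectors."""
    from equicomorb.phecodes import PhenotypeStatusMatrix

    status = pd.DataFrame(
        {k: np.asarray(v, dtype=np.int8) for k, v in case_control.items()}
    )
    status.index = pd.Index([f"p{i}" for i in range(len(status))], name="patient_id")
    counts = status.clip(lower=0) * 2 + (status == -1).astype(int)
    return PhenotypeStatusMatrix(status=status, counts=counts)
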