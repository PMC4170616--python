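import numpy as np
import pytest

from gliostrat import CohortSpec, ExpressionDataset, SurvivalData, generate_cohort


@pytest.fixture
def small_cohort():
    """Cohort with one planted prognostic probe, desk-scale."""
    spec = CohortSpec(
        n_samples=300,
        n_probes=20,
        prognostic_effects={"probe_00001": 0.7},
        censoring_rate=0.2,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_survival():
    rng = np.random.default_rng(11)
    n = 50
    return SurvivalData(
        time=rng.exponential(100.0, size=n),
        event=(rng.uniform(size=n) < 0.8).astype(int),
    )


def make_dataset(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ExpressionDataset(
        probe_ids=probes or [f"p{i}" for i in range(p)],
        sample_ids=samples or [f"s{j}" for j in range(n)],
        values=values,
    )
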