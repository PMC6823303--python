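import numpy as np
import pytest

from asrtlab import (
    BehaviorParams,
    BetweenSubjectSD,
    CohortParams,
    ErpParams,
    SequenceSpec,
    classify_stream,
    generate_session,
)
from asrtlab.triplets import ANALYSIS_CATEGORIES


@pytest.fixture(scope="session")
def seq():
    """The worked-example sequence 2-r-1-r-3-r-4-r."""
    return SequenceSpec((2, 1, 3, 4))


@pytest.fixture(scope="session")
def long_stream(seq):
    """A long session for empirical frequency checks (~170k trials)."""
    return generate_session(seq, n_blocks=2000, rng_seed=101)


@pytest.fixture(scope="session")
def long_labels(long_stream):
    return classify_stream(long_stream)


def noiseless_cohort_params(n_subjects=2, n_blocks=30):
    """Deterministic cohort: no RT/EEG noise, perfect accuracy, no artifacts."""
    return CohortParams(
        n_subjects=n_subjects,
        n_blocks=n_blocks,
        behavior=BehaviorParams(
            rt_noise_sd=0.0, miss_rate=0.0,
            accuracy={c: 1.0 for c in ANALYSIS_CATEGORIES},
        ),
        erp=ErpParams(noise_sd=0.0, artifact_rate=0.0),
        between=BetweenSubjectSD(baseline_rt=0.0, category_effect=0.0,
                                 p3_offset=0.0, p3_effect=0.0,
                                 late_offset=0.0, late_effect=0.0),
    )


@pytest.fixture(scope="session")
def noiseless_subject(seq):
    from asrtlab import simulate_subject
    return simulate_subject(1, noiseless_cohort_params(),
                            np.random.SeedSequence(7), sequence=seq)
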