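import numpy as np
import pytest

from protriage import GeneratorConfig, simulate_cohort

#: Three collapsed signatures (C2==C3, C4==C5) for planted-k=3 experiments.
THREE_SIGNATURE_PATTERNS = {
    "a": ((2.0, -1.0, -1.0, -1.0, -1.0), 0.4),
    "b": ((-1.0, 2.0, 2.0, -1.0, -1.0), 0.3),
    "c": ((-1.0, -1.0, -1.0, 2.0, 2.0), 0.3),
}

CANONICAL_MAP = {"C1": "VH", "C2": "CC", "C3": "CC", "C4": "CC", "C5": "NEITHER"}


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-structure cohort shared by read-only tests."""
    return simulate_cohort(
        GeneratorConfig(n_patients=200, n_proteins=60, frac_marker_proteins=0.5,
                        signature_effect=3.0, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, censor_frac=0.3):
    times = rng.exponential(10.0, n)
    events = (rng.random(n) > censor_frac).astype(int)
    return times, events
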