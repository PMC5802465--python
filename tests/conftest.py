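import numpy as np
import pytest
from hypothesis import settings

from netcohesion import NetworkSpec, SubjectRecord, make_window_grid

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def default_grid():
    """The standard grid: 160 trimmed TRs, 10-TR windows, step 1 -> 151."""
    return make_window_grid(160, window=10, step=1, trim=5)


@pytest.fixture
def es_network():
    return NetworkSpec("ES", tuple(f"ES_{i}" for i in range(1, 6)))


@pytest.fixture
def tom_network():
    return NetworkSpec("ToM", tuple(f"ToM_{i}" for i in range(1, 8)))


def make_subject(rng, n_nodes=5, T=160, subject_id="S001", group="control",
                 prefix="ES", **kwargs):
    """A subject with independent white-noise node signals (trimmed length)."""
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        node_labels=[f"{prefix}_{i}" for i in range(1, n_nodes + 1)],
        signals=rng.standard_normal((n_nodes, T)),
        **kwargs,
    )


@pytest.fixture
def random_subject(rng):
    return make_subject(rng)
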