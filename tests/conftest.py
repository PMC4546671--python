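import numpy as np
import pytest

from tandemtract.simulate import ErrorModel, ReadRecord, build_template, random_flanks


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_model():
    return ErrorModel(seed=7)


@pytest.fixture
def zero_model():
    return ErrorModel(0.0, 0.0, 0.0, seed=7)


@pytest.fixture
def small_template():
    """Interrupted expansion with unique 200/220-nt flanks, ~1 kb overall."""
    flank5, flank3 = random_flanks(200, 220, seed=11)
    spec = ([("ATTTTCT", 1), ("ATTCT", 1), ("ATATTCT", 1), ("ATTCT", 1),
             ("ATATTCT", 1), ("ATTCT", 1), ("ATTTTCT", 1)]
            + [("ATTCT", 60)] + [("ATCCT", 1), ("ATTCT", 2)] * 8
            + [("ATCCC", 40)])
    return build_template(spec, flank5, flank3)


def make_read(read_id="r0", sequence="ACGT" * 30, quality=1.0, passes=1,
              predicted_accuracy=1.0, source_molecule=None) -> ReadRecord:
    return ReadRecord(read_id, sequence, quality, passes, predicted_accuracy,
                      source_molecule or read_id)


@pytest.fixture
def make_read_factory():
    return make_read
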