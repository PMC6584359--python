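import numpy as np
import pytest

from trfpid.core import EventTable, FeatureSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space(rng):
    """Random 3-channel feature space at 40 Hz, 30 s."""
    data = rng.standard_normal((1200, 3))
    return FeatureSpace(data, rate=40.0, name="toy",
                        subspaces=[("toy", (0, 3))])


@pytest.fixture
def tiny_events():
    return EventTable(
        onsets=np.array([0.5, 1.0, 1.6, 2.25]),
        phonemes=np.array(["AA", "N", "T", "S"], dtype=object),
        articulatory_sets=[frozenset({"voiced", "vowel", "low"}),
                           frozenset({"voiced", "nasal", "alveolar"}),
                           frozenset({"plosive", "alveolar"}),
                           frozenset({"fricative", "alveolar"})],
        manner_classes=np.array(["vowel", "nasal", "plosive", "fricative"],
                                dtype=object))
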