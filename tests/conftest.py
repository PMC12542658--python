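import numpy as np
import pytest

from comnet import CommunitySpec, CountTable, SampleMetadata, generate


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(
        ["t1", "t2", "t3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[5, 0, 2, 1],
                  [1, 3, 2, 0],
                  [0, 1, 2, 7]]),
    )


@pytest.fixture
def toy_meta() -> SampleMetadata:
    return SampleMetadata(
        ["s1", "s2", "s3", "s4"],
        {"group": ["A", "A", "B", "B"]},
    )


@pytest.fixture(scope="session")
def planted_community():
    """Default two-condition community with one module silenced in B."""
    spec = CommunitySpec(seed=7, differential_modules={"B": (0,)})
    return generate(spec)
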