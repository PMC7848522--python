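import numpy as np
import pytest
from hypothesis import settings

import saddlescape as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def two_type():
    """f*/f** = 2: the canonical asymmetric-walk landscape."""
    return ss.build_landscape(["a", "b"], {"a": 1.0, "b": 2.0}, [("a", "b")])


@pytest.fixture
def three_type():
    """Complete 3-type landscape with s = 0.3."""
    return ss.build_landscape(
        ["a", "b", "c"],
        {"a": 1.0, "b": 1.3, "c": 1.6},
        [("a", "b"), ("b", "c"), ("a", "c")],
    )


@pytest.fixture
def four_type_complete():
    """Four types f1 < f2 < f3 < f4 on a complete graph: the phase-portrait
    setting with vertex e(4) attracting the whole interior."""
    ids = ["1", "2", "3", "4"]
    fit = {"1": 1.0, "2": 1.2, "3": 1.5, "4": 2.0}
    edges = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    return ss.build_landscape(ids, fit, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
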