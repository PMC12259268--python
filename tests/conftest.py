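import numpy as np
import pytest

from graftquant import insilico as ins


@pytest.fixture
def small_layout() -> ins.CompartmentLayout:
    """Hand-placed 100x100 canvas with 20x20 red and blue squares."""
    return ins.CompartmentLayout(
        100.0,
        100.0,
        (
            ins.Rect("red", 10.0, 10.0, 20.0, 20.0),
            ins.Rect("blue", 60.0, 60.0, 20.0, 20.0),
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
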