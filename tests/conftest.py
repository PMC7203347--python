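import numpy as np
import pytest

from spikewta import build_pattern_bank, make_synthetic_images


@pytest.fixture(scope="session")
def bank3():
    """Three equalized patterns, the Fig-5-style multi-pattern setting."""
    return build_pattern_bank(3, seed=0)


@pytest.fixture(scope="session")
def stroke_images():
    """Two well-separated stroke classes (vertical-bar 1 vs box 0)."""
    images, labels = make_synthetic_images((0, 1), 160, seed=11)
    return images, labels


def fig5_stream(pats, seed, rates=(0.46, 0.28, 0.15)):
    """Pattern slots carrying three patterns at the benchmark appearance
    rates; the remaining slots are empty."""
    rng = np.random.default_rng(10_000 + seed)
    c1, c2, c3 = rates[0], rates[0] + rates[1], sum(rates)

    def gen():
        while True:
            u = rng.random()
            if u < c1:
                yield pats[0]
            elif u < c2:
                yield pats[1]
            elif u < c3:
                yield pats[2]
            else:
                yield None

    return gen()
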