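import numpy as np
import pytest

import sepselect as ss


@pytest.fixture
def anchor():
    """The hand-documented 6x4 two-class fixture."""
    return ss.fixture_small()


@pytest.fixture
def sim_default():
    """One draw from the default synthetic configuration (64 x 2000)."""
    matrix, planted = ss.simulate(ss.SimulationConfig(seed=7))
    return matrix, planted


@pytest.fixture
def sim_small():
    """A fast 5-class matrix for classifier tests (64 x 60, 12 planted)."""
    cfg = ss.SimulationConfig(p=60, n_informative=12, seed=3)
    matrix, planted = ss.simulate(cfg)
    return matrix, planted


def naive_separability(values, codes):
    """Independent triple-loop oracle for the per-gene separability score.

    Written deliberately without vectorization: per gene, per class, sum the
    values for the mean (same left-to-right order as np.mean over the class
    slice), take absolute deviations, then max within class and min across
    classes.
    """
    values = np.asarray(values, dtype=np.float64)
    codes = np.asarray(codes)
    classes = sorted(set(codes.tolist()))
    n, m = values.shape
    scores = []
    for j in range(m):
        per_class_max = []
        for c in classes:
            members = [values[i, j] for i in range(n) if codes[i] == c]
            mean = np.mean(members)
            per_class_max.append(max(abs(v - mean) for v in members))
        scores.append(min(per_class_max))
    return np.array(scores)


@pytest.fixture
def naive_scorer():
    return naive_separability
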