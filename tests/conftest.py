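from datetime import date

import numpy as np
import pytest

from studbooklife import AnalysisWindow, Exposure


@pytest.fixture
def window():
    return AnalysisWindow(date(1980, 1, 1), date(2019, 12, 31))


@pytest.fixture
def two_individual_exposures():
    # one death at 500 d, one censoring at 600 d -> L(500) = 0.5 exactly
    return [
        Exposure("a", "male", 365, 500, True),
        Exposure("b", "male", 365, 600, False),
    ]


@pytest.fixture
def four_individual_exposures():
    # hand oracle: L(400) = 3/4, L(700) = 3/4 * 1/2 = 0.375,
    # V(400) = (3/4)^2 * 1/(4*3) = 0.046875, median crossing at 600 d
    return [
        Exposure("a", "male", 365, 400, True),
        Exposure("b", "male", 365, 500, False),
        Exposure("c", "female", 365, 700, True),
        Exposure("d", "female", 365, 900, False),
    ]


def random_cohort(rng: np.random.Generator, n: int,
                  truncation: float = 0.3) -> list[Exposure]:
    """Small random cohort with ties (coarse age grid), truncation and
    censoring, for comparison against a reference survival library."""
    entry = np.where(rng.random(n) < truncation,
                     365 + rng.integers(1, 40, n) * 10, 365)
    exit_ = entry + rng.integers(1, 30, size=n) * 10
    event = rng.random(n) < 0.7
    return [Exposure(str(i), "male", int(entry[i]), int(exit_[i]),
                     bool(event[i])) for i in range(n)]
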