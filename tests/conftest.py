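import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import settings

from alncompare import Alignment, random_alignment, random_regap

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def worked_pair():
    """The two-sequence, three-column pair used throughout as a hand-checked case."""
    ref = Alignment.from_rows(["s1", "s2"], ["ACG", "A-G"], name="ref")
    comp = Alignment.from_rows(["s1", "s2"], ["ACG", "AG-"], name="comp")
    return ref, comp


def random_pair(rng, max_n=6, max_width=8, alphabet="ACGT", gap_fraction=0.3):
    """A random alignment plus an independent re-gapping of the same sequences."""
    n = int(rng.integers(2, max_n + 1))
    width = int(rng.integers(2, max_width + 1))
    ref = random_alignment(
        rng, n=n, width=width, alphabet=alphabet, gap_fraction=gap_fraction
    )
    comp = random_regap(rng, ref)
    return ref, comp


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt

    plt.close("all")
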