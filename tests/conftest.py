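import warnings

import numpy as np
import pandas as pd
import pytest

from crescape.motifs import Pwm
from crescape.simulate import ETS_CONSENSUS, ZIC_CONSENSUS


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def ets_pwm():
    return Pwm.from_consensus("ETS", ETS_CONSENSUS)


@pytest.fixture(scope="session")
def zic_pwm():
    return Pwm.from_consensus("ZIC", ZIC_CONSENSUS)


@pytest.fixture(scope="session")
def segmentation_study():
    from crescape.simulate import segmentation_study as build

    return build(seed=1)


def random_intervals(rng, n, chrom="chr1", max_pos=100_000, max_len=500):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + lengths,
    }).sort_values(["start", "end"]).reset_index(drop=True)


def brute_force_overlaps(a, b):
    """O(n*m) overlap oracle: indices of rows in a overlapping any b row."""
    keep = []
    for i, ra in a.iterrows():
        for _, rb in b.iterrows():
            if (ra["chrom"] == rb["chrom"] and ra["start"] < rb["end"]
                    and ra["end"] > rb["start"]):
                keep.append(i)
                break
    return keep
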