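import numpy as np
import pytest

from sehier.pipeline import analyze
from sehier.simulate import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def seed7_bundle():
    """The planted-hub study conditions: 56 SEs, half hierarchical, 5-fold hubs."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def seed7_result(seed7_bundle):
    b = seed7_bundle
    return analyze(
        b.all_peaks, b.contacts_5col(), b.genome,
        blacklist=b.blacklist, tss=b.tss, tads=b.tads, variants=b.variants,
        seed=1,
    )


def match_calls_to_truth(calls, truth):
    """Pair each truth SE with the called SE overlapping its span."""
    pairs = []
    for se in truth.ses:
        match = None
        for c in calls:
            r = c.se.region
            if r.chrom == se["chrom"] and r.start < se["end"] and se["start"] < r.end:
                match = c
                break
        pairs.append((se, match))
    return pairs
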