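import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitovar import ObservedBase, PileupColumn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_column(position, counts, quality=20.0, alternate_strands=True):
    """A pileup column with ``counts`` observations per base, e.g.
    ``{"A": 60, "C": 40}``; strands alternate so dual-strand filters pass."""
    observations = []
    i = 0
    for base, n in counts.items():
        for _ in range(n):
            strand = "+" if (alternate_strands and i % 2 == 0) else "-"
            if not alternate_strands:
                strand = "+"
            observations.append(ObservedBase(base, quality, strand))
            i += 1
    return PileupColumn.from_observations(position, observations)


def random_biallelic_column(rng, position=1, depth=None, mixed_quality=False):
    """Random two-base column; returns (column, major, minor)."""
    bases = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
    depth = depth or int(rng.integers(60, 200))
    f = rng.uniform(0.05, 0.95)
    which = rng.random(depth) < f
    if mixed_quality:
        quals = rng.integers(20, 41, size=depth).astype(float)
    else:
        quals = np.full(depth, 20.0)
    observations = [
        ObservedBase(bases[0] if w else bases[1], q, "+" if s else "-")
        for w, q, s in zip(which, quals, rng.random(depth) < 0.5)
    ]
    return PileupColumn.from_observations(position, observations), bases[0], bases[1]
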