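"""Shared fixtures: small synthetic genomes and enrichment tracks.

Everything is generated programmatically from fixed seeds; the session-scoped
annotation fixtures keep the heavier simulations to one per run.
"""

import numpy as np
import pytest

from metaorigin import (
    EnrichmentTrack,
    FactorOccupancyModel,
    SyntheticGenomeSpec,
    simulate_genome,
)
from metaorigin.tracks import n_anchors


def make_track(values_by_chrom, window=250, step=50, lengths=None):
    """EnrichmentTrack from explicit anchor arrays (lengths derived)."""
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    if lengths is None:
        lengths = {c: (len(v) - 1) * step + window for c, v in values.items()}
    return EnrichmentTrack(values=values, chrom_lengths=lengths, window=window, step=step)


def random_track(rng, n_anchors_by_chrom, window=250, step=50, loc=0.0, scale=1.0):
    return make_track(
        {c: rng.normal(loc, scale, n) for c, n in n_anchors_by_chrom.items()},
        window=window,
        step=step,
    )


@pytest.fixture(scope="session")
def small_annotation():
    """2 x 1.7 Mb chromosomes with 4 origins each plus a 3.4 Mb origin-free
    background chromosome."""
    spec = SyntheticGenomeSpec(
        chrom_lengths={"chr1": 1_700_000, "chr2": 1_700_000, "bg1": 3_400_000},
        origins={
            "chr1": [300_000, 700_000, 1_100_000, 1_400_000],
            "chr2": [300_000, 700_000, 1_100_000, 1_400_000],
            "bg1": [],
        },
        seed=7,
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def mock_model():
    return FactorOccupancyModel(name="Rad21")


@pytest.fixture
def rng():
    return np.random.default_rng(2018)
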