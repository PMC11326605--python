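import numpy as np
import pytest

from oritools.genome import CoverageTrack, GenomeAnnotation, OriginAnnotation


@pytest.fixture
def small_genome() -> GenomeAnnotation:
    return GenomeAnnotation((("chrI", 30_000), ("chrII", 20_000)))


@pytest.fixture
def small_origins(small_genome) -> list[OriginAnnotation]:
    return [
        OriginAnnotation("oriA", "chrI", 10_000, "+"),
        OriginAnnotation("oriB", "chrI", 22_000, "-"),
        OriginAnnotation("oriC", "chrII", 9_000, "+"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240805)


def make_track(genome: GenomeAnnotation, fn) -> CoverageTrack:
    """Coverage track from a function of (chrom, position array)."""
    return CoverageTrack(
        genome,
        {c: np.asarray(fn(c, np.arange(genome.length(c))), dtype=float)
         for c in genome.names},
    )
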