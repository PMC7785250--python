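import numpy as np
import pytest
from hypothesis import settings

from piconflict import SimulationParams, make_conflict_locus

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from piconflict.types import AlignedRead, GenomicInterval


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def locus(default_params):
    return make_conflict_locus(default_params)


def make_read(start, end, strand="+", ref="ref", sequence=None, read_id=None):
    return AlignedRead(
        read_id=read_id or f"r_{ref}_{start}_{end}_{strand}",
        interval=GenomicInterval(ref=ref, start=start, end=end, strand=strand),
        sequence=sequence,
    )


def uniform_reads(rng: np.random.Generator, n: int, ref_length: int = 5000,
                  lengths=(23, 30), ref: str = "ref"):
    """Uniformly placed reads with uniform strand — a null library."""
    reads = []
    for i in range(n):
        ln = int(rng.integers(lengths[0], lengths[1] + 1))
        start = int(rng.integers(0, ref_length - ln))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(make_read(start, start + ln, strand, ref=ref, read_id=f"u{i}"))
    return reads
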