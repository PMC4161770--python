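import numpy as np
import pytest

from marinerscape.model import GenomeSequence
from marinerscape.simulate import _random_background, generate_master


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def master(rng):
    """A synthetic full-length mariner-like master element (1286 nt)."""
    return generate_master(rng)


def make_genome(seed: int, length: int = 30000, gc: float = 0.5,
                inserts: list[tuple[int, str]] | None = None,
                name: str = "g") -> GenomeSequence:
    """Random background genome with sequences planted at given positions.

    ``inserts`` are (position_in_background, sequence); positions refer to
    the untouched background and must be sorted and non-overlapping.
    """
    bg = _random_background(np.random.default_rng(seed), length, gc)
    if not inserts:
        return GenomeSequence(name, bg)
    pieces = []
    cursor = 0
    for pos, seq in inserts:
        pieces.append(bg[cursor:pos])
        pieces.append(seq)
        cursor = pos
    pieces.append(bg[cursor:])
    return GenomeSequence(name, "".join(pieces))
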