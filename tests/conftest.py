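from __future__ import annotations

import numpy as np
import pytest

from colxlink.chain_io import CollagenChain, Region
from colxlink.helix_detect import HelixRegion


def make_chain(seq: str, chain_id: str = "t1", species: str = "test") -> CollagenChain:
    return CollagenChain(chain_id=chain_id, species=species, sequence=seq)


def make_helix(start: int, end: int, label: str = "main_helix") -> HelixRegion:
    return HelixRegion(
        region=Region(start, end, label),
        register=start % 3,
        triplet_count=(end - start) // 3,
        interruptions=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160374)


def random_sequences(rng: np.random.Generator, count: int, max_len: int = 200) -> list[str]:
    """Random G-enriched sequences that exercise register/interruption
    logic (uniform residues would almost never form triplet runs)."""
    letters = np.array(list("GGGGGPPAKHRSTX"))
    out = []
    for _ in range(count):
        n = int(rng.integers(6, max_len + 1))
        out.append("".join(rng.choice(letters, size=n)))
    return out
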