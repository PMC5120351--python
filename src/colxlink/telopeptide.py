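"""Delimitation of the N- and C-telopeptide analysis windows.

The N-telopeptide window runs from the end of the short N-terminal
minor helix (or the chain start when no minor helix exists) to the
start of the main helix. The C-telopeptide window runs from the end of
the main helix to the COLFI propeptide boundary when one is annotated,
else for at most ``c_max_len`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chain_io import CollagenChain, Region
from .helix_detect import HelixRegion

#: Default C-telopeptide window length when no COLFI boundary is annotated.
#: Vertebrate C-telopeptides are ~11-26 residues; 40 leaves slack without
#: swallowing the C-propeptide.
DEFAULT_C_MAX_LEN = 40


@dataclass(frozen=True)
class TelopeptideRegion:
    """A non-collagenous window flanking the main helix.

    ``side`` is ``"N"`` or ``"C"``; ``sequence`` is the corresponding
    substring of the chain.
    """

    region: Region
    side: str
    sequence: str

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")
        if len(self.sequence) != len(self.region):
            raise ValueError("sequence length inconsistent with region span")

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


def extract_telopeptides(
    chain: CollagenChain,
    minor: HelixRegion | None,
    main: HelixRegion,
    c_max_len: int = DEFAULT_C_MAX_LEN,
) -> tuple[TelopeptideRegion | None, TelopeptideRegion | None]:
    """Compute the (N, C) telopeptide windows for one chain.

    A side is None when its window has length zero; chains truncated at
    the N-terminal end (main helix starting at position 0) have no N
    window.
    """
    seq = chain.sequence

    n_telo: TelopeptideRegion | None = None
    n_start = minor.end if minor is not None else 0
    if 0 < main.start and n_start < main.start:
        region = Region(n_start, main.start, "n_telopeptide")
        n_telo = TelopeptideRegion(region=region, side="N", sequence=seq[n_start : main.start])

    c_telo: TelopeptideRegion | None = None
    colfi = chain.region("colfi_stub")
    c_end = colfi.start if colfi is not None else min(main.end + c_max_len, len(seq))
    if main.end < c_end:
        region = Region(main.end, c_end, "c_telopeptide")
        c_telo = TelopeptideRegion(region=region, side="C", sequence=seq[main.end : c_end])

    return n_telo, c_telo
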