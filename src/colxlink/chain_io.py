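"""Chain records, FASTA/annotation input and TSV/JSON report output.

All coordinates are 0-based half-open, both internally and in every
machine-readable output. Log lines may additionally show 1-based
positions, labelled as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

from .errors import (
    AnnotationBoundsError,
    DuplicateChainError,
    SequenceAlphabetError,
    UnknownChainError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .sites import CrosslinkSite

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes plus 'X' (unknown residue).
#: 'X' never matches a motif position and never counts as lysine.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Region labels understood by the annotation table and the report.
REGION_LABELS = frozenset(
    {
        "minor_helix",
        "main_helix",
        "n_telopeptide",
        "c_telopeptide",
        "gpp_terminus",
        "colfi_stub",
        "n_propeptide",
    }
)


@dataclass(frozen=True, order=True)
class Region:
    """A labelled half-open interval [start, end) on a chain sequence."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region bounds [{self.start}, {self.end})")
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class CollagenChain:
    """One collagen alpha-chain: sequence, identity metadata, annotations.

    Parameters
    ----------
    chain_id
        Unique token, the first whitespace-delimited word of the FASTA
        header.
    species
        Free text, the remainder of the header (may be empty).
    sequence
        Upper-case amino acids over ``ACDEFGHIKLMNPQRSTVWYX``.
    regions
        Labelled regions accumulated by the annotation stages.
    """

    chain_id: str
    species: str
    sequence: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise SequenceAlphabetError(self.chain_id, ch, i)

    def __len__(self) -> int:
        return len(self.sequence)

    def add_region(self, region: Region) -> None:
        """Attach a region, refusing same-label overlaps."""
        if region.end > len(self.sequence):
            raise AnnotationBoundsError(
                f"chain {self.chain_id!r}: region {region.label} "
                f"[{region.start}, {region.end}) exceeds length {len(self.sequence)}"
            )
        for other in self.regions:
            if other.label == region.label and other.overlaps(region):
                raise ValueError(
                    f"chain {self.chain_id!r}: overlapping {region.label} regions"
                )
        self.regions.append(region)

    def regions_by_label(self, label: str) -> list[Region]:
        return sorted(r for r in self.regions if r.label == label)

    def region(self, label: str) -> Region | None:
        """The single region with this label, or None."""
        hits = self.regions_by_label(label)
        return hits[0] if hits else None


def _clean_sequence(chain_id: str, raw: str) -> str:
    seq = str(raw).upper().replace("*", "")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceAlphabetError(chain_id, ch, i)
    return seq


def read_fasta(path: str | Path) -> list[CollagenChain]:
    """Read a FASTA file into a list of :class:`CollagenChain`.

    The header's first whitespace-delimited token becomes ``chain_id``;
    the remainder becomes ``species``. Sequences are upper-cased and
    ``'*'`` terminators stripped. A record containing any character
    outside the accepted alphabet raises :class:`SequenceAlphabetError`
    naming the character and its 0-based position. An empty file returns
    an empty list with a logged warning.
    """
    chains: list[CollagenChain] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        chain_id = record.id
        species = record.description[len(record.id):].strip()
        seq = _clean_sequence(chain_id, str(record.seq))
        if chain_id in seen:
            raise DuplicateChainError(f"duplicate chain_id {chain_id!r}")
        seen.add(chain_id)
        chains.append(CollagenChain(chain_id=chain_id, species=species, sequence=seq))
    if not chains:
        logger.warning("no FASTA records found in %s", path)
    return chains


def write_fasta(chains: Iterable[CollagenChain], path: str | Path) -> None:
    """Write chains as FASTA (inverse of :func:`read_fasta` on id/sequence)."""
    with open(path, "w") as fh:
        for chain in chains:
            header = chain.chain_id if not chain.species else f"{chain.chain_id} {chain.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(chain.sequence), 60):
                fh.write(chain.sequence[i : i + 60] + "\n")


def read_annotations(path: str | Path, chains: list[CollagenChain]) -> list[CollagenChain]:
    """Attach regions from a tab-separated table to loaded chains.

    Rows are ``chain_id<TAB>label<TAB>start<TAB>end`` with 0-based
    half-open coordinates. A row naming an unknown chain raises
    :class:`UnknownChainError`; out-of-bounds coordinates raise
    :class:`AnnotationBoundsError` naming the row number.
    """
    by_id = {c.chain_id: c for c in chains}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[:2] == ["chain_id", "label"]:
                continue  # optional header row
            parts = line.split("\t")
            if len(parts) != 4:
                raise AnnotationBoundsError(
                    f"row {lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            chain_id, label, start_s, end_s = parts
            if chain_id not in by_id:
                raise UnknownChainError(f"row {lineno}: unknown chain_id {chain_id!r}")
            chain = by_id[chain_id]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationBoundsError(f"row {lineno}: non-integer coordinate") from exc
            if not (0 <= start < end <= len(chain.sequence)):
                raise AnnotationBoundsError(
                    f"row {lineno}: [{start}, {end}) out of bounds for chain "
                    f"{chain_id!r} of length {len(chain.sequence)}"
                )
            chain.add_region(Region(start, end, label))
    return chains


def write_annotations(chains: Iterable[CollagenChain], path: str | Path) -> None:
    """Write every chain's regions in the 4-column TSV dialect of
    :func:`read_annotations`."""
    with open(path, "w") as fh:
        fh.write("chain_id\tlabel\tstart\tend\n")
        for chain in chains:
            for region in sorted(chain.regions):
                fh.write(f"{chain.chain_id}\t{region.label}\t{region.start}\t{region.end}\n")


REPORT_COLUMNS = ("chain_id", "site_class", "k_pos", "window", "score", "flank_clear")


def write_report(
    chains: list[CollagenChain],
    sites: list["CrosslinkSite"],
    path: str | Path,
    depletion: dict | None = None,
) -> None:
    """Emit the site report as ``<path>.tsv`` and ``<path>.json``.

    The TSV has one row per site (chain_id, site_class, 0-based K
    position, 7-residue motif window, score, flank-exclusion flag); the
    JSON mirrors it and adds the per-chain region annotations, plus the
    depletion results when supplied.
    """
    path = Path(path)
    by_id = {c.chain_id: c for c in chains}
    unknown = [s.chain_id for s in sites if s.chain_id not in by_id]
    if unknown:
        raise UnknownChainError(f"sites reference unloaded chains: {sorted(set(unknown))}")

    tsv_path = path.parent / (path.name + ".tsv")
    json_path = path.parent / (path.name + ".json")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.chain_id}\t{s.site_class}\t{s.k_pos}\t{s.window}\t"
                f"{s.score:.6g}\t{str(s.flank_clear).lower()}\n"
            )

    doc = {
        "sites": [
            {
                "chain_id": s.chain_id,
                "site_class": s.site_class,
                "k_pos": s.k_pos,
                "window": s.window,
                "score": s.score,
                "flank_clear": s.flank_clear,
            }
            for s in sites
        ],
        "chains": {
            c.chain_id: {
                "species": c.species,
                "length": len(c.sequence),
                "regions": [
                    {"label": r.label, "start": r.start, "end": r.end}
                    for r in sorted(c.regions)
                ],
            }
            for c in chains
        },
    }
    if depletion is not None:
        doc["depletion"] = depletion
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
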