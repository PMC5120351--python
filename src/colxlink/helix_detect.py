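"""Detection of collagenous Gly-X-X' regions and helix landmarks.

A collagenous region is a run of consecutive triplets whose first
position is glycine, read in one of three *registers* (the offset mod 3
at which glycines recur). The longest such run is the main triple helix;
a much shorter run N-terminal to it is the minor helix whose end marks
the start of the N-telopeptide; a terminal run of exact G-P-P triplets
marks the C-terminal end of the main helix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chain_io import CollagenChain, Region
from .errors import NoCollagenousDomainError

#: Default minimum number of triplets for a detected region.
DEFAULT_MIN_TRIPLETS = 5
#: Default number of tolerated non-G first-triplet positions per region.
DEFAULT_MAX_INTERRUPTIONS = 1
#: A minor helix must have at most this fraction of the main helix's triplets.
DEFAULT_MINOR_MAX_FRACTION = 0.25
#: Default minimum number of consecutive exact GPP triplets for the terminus.
DEFAULT_GPP_MIN_REPEATS = 2


@dataclass(frozen=True)
class HelixRegion:
    """A detected Gly-X-X' interval with its triplet register.

    ``register`` is ``region.start % 3``; glycine occupies every
    position ``p`` with ``(p - region.start) % 3 == 0`` except at most
    ``interruptions`` of them. The first and last triplet always start
    with G (regions are trimmed to G-anchored ends).
    """

    region: Region
    register: int
    triplet_count: int
    interruptions: int

    def __post_init__(self) -> None:
        if self.register not in (0, 1, 2):
            raise ValueError("register must be 0, 1 or 2")
        if self.triplet_count != (self.region.end - self.region.start) // 3:
            raise ValueError("triplet_count inconsistent with region span")

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


def _count_interruptions(seq: str, start: int, end: int) -> int:
    return sum(1 for p in range(start, end, 3) if seq[p] != "G")


def _maximal_windows(
    seq: str, register: int, min_triplets: int, max_interruptions: int
) -> list[tuple[int, int]]:
    """Containment-maximal G-anchored triplet windows in one register.

    A window [s, e) (e = s + 3t) satisfies the predicate when its first
    and last triplets start with G and at most ``max_interruptions``
    interior triplets do not. Returned windows are those not strictly
    contained in a larger satisfying window of the same register.
    """
    n = len(seq)
    anchors = [p for p in range(register, n - 2, 3) if seq[p] == "G"]
    if not anchors:
        return []
    windows: list[tuple[int, int]] = []
    for s in anchors:
        # furthest G-anchored end triplet reachable from s within budget
        bad = 0
        p = s
        last_good = s
        while p < n - 2:
            if seq[p] != "G":
                bad += 1
                if bad > max_interruptions:
                    break
            else:
                last_good = p
            p += 3
        best_e = last_good + 3
        if (best_e - s) // 3 >= min_triplets:
            windows.append((s, best_e))
    # containment-maximal: drop any window contained in another
    maximal = [
        w
        for w in windows
        if not any(
            (o[0] <= w[0] and w[1] <= o[1] and o != w) for o in windows
        )
    ]
    return maximal


def select_regions(candidates: list[HelixRegion]) -> list[HelixRegion]:
    """Greedy non-overlap selection over candidate regions.

    Candidates are ranked by (triplet_count descending, start ascending,
    register ascending); each is kept iff it overlaps no already-kept
    region. Shared by detection and by the brute-force test oracle.
    """
    ranked = sorted(candidates, key=lambda h: (-h.triplet_count, h.start, h.register))
    kept: list[HelixRegion] = []
    for cand in ranked:
        if not any(cand.region.overlaps(k.region) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda h: h.start)


def detect_gxy_regions(
    chain: CollagenChain,
    min_triplets: int = DEFAULT_MIN_TRIPLETS,
    max_interruptions: int = DEFAULT_MAX_INTERRUPTIONS,
) -> list[HelixRegion]:
    """Find maximal non-overlapping collagenous Gly-X-X' regions.

    Runs are enumerated in each of the three registers: consecutive
    triplets with glycine first, allowing up to ``max_interruptions``
    non-G first positions per run, trimmed so the first and last triplet
    are G-anchored. Runs shorter than ``min_triplets`` are discarded;
    overlaps between registers are resolved in favour of the longer run
    (tie: smaller start, then smaller register).
    """
    if min_triplets < 2:
        raise ValueError("min_triplets must be >= 2")
    if max_interruptions < 0:
        raise ValueError("max_interruptions must be >= 0")
    seq = chain.sequence
    candidates: list[HelixRegion] = []
    for register in range(3):
        for s, e in _maximal_windows(seq, register, min_triplets, max_interruptions):
            candidates.append(
                HelixRegion(
                    region=Region(s, e, "main_helix"),
                    register=register,
                    triplet_count=(e - s) // 3,
                    interruptions=_count_interruptions(seq, s, e),
                )
            )
    return select_regions(candidates)


def classify_helices(
    regions: list[HelixRegion],
    minor_max_fraction: float = DEFAULT_MINOR_MAX_FRACTION,
) -> tuple[HelixRegion | None, HelixRegion]:
    """Split detected regions into (minor, main).

    The main helix is the region with the greatest triplet count (tie:
    the more C-terminal). The minor helix is the longest region strictly
    N-terminal to the main one whose triplet count is at most
    ``minor_max_fraction`` of the main's; None when no region qualifies.
    """
    if not regions:
        raise NoCollagenousDomainError("no collagenous domain")
    main = max(regions, key=lambda h: (h.triplet_count, h.start))
    upstream = [
        h
        for h in regions
        if h.end <= main.start and h.triplet_count <= minor_max_fraction * main.triplet_count
    ]
    minor = None
    if upstream:
        minor = max(upstream, key=lambda h: (h.triplet_count, -h.start))
    if minor is not None:
        minor = HelixRegion(
            region=Region(minor.start, minor.end, "minor_helix"),
            register=minor.register,
            triplet_count=minor.triplet_count,
            interruptions=minor.interruptions,
        )
    return minor, main


def find_gpp_terminus(
    chain: CollagenChain,
    main: HelixRegion,
    min_repeats: int = DEFAULT_GPP_MIN_REPEATS,
) -> Region | None:
    """Locate the (GPP)n motif marking the C-terminal end of the helix.

    Returns the most C-terminal maximal run of at least ``min_repeats``
    consecutive exact ``GPP`` triplets lying within the main helix (in
    its register, ending at or before ``main.end``), as a Region
    labelled ``gpp_terminus``; None when no such run exists.
    """
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    seq = chain.sequence
    best: tuple[int, int] | None = None
    run_start: int | None = None
    for p in range(main.start, main.end - 2, 3):
        if seq[p : p + 3] == "GPP" and p + 3 <= main.end:
            if run_start is None:
                run_start = p
        else:
            if run_start is not None and (p - run_start) // 3 >= min_repeats:
                best = (run_start, p)
            run_start = None
    if run_start is not None:
        # run extends to the helix end
        end = main.start + 3 * ((main.end - main.start) // 3)
        if (end - run_start) // 3 >= min_repeats:
            best = (run_start, end)
    if best is None:
        return None
    return Region(best[0], best[1], "gpp_terminus")
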