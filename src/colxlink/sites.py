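"""Candidate lysyl-oxidase cross-linking site detection and scoring.

Telopeptides are scanned for the X-K-X'-X'' substrate motif (K the
lysine oxidised by LOX; X' mostly glycine or alanine, X'' mostly
proline), and the ends of the main helix for the Y-K-G-Y''-Y''' acceptor
motif (the G is the invariant triplet glycine; Y'' and Y''' are mostly
histidine and arginine). Scores are means of per-offset residue weights;
the weight tables are data, configurable, seeded from the residues
observed at each position in clade-A collagens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chain_io import CollagenChain, Region
from .helix_detect import HelixRegion
from .telopeptide import TelopeptideRegion

#: Default telopeptide weight tables: offsets are relative to the K.
DEFAULT_TELO_WEIGHTS: dict[int, dict[str, float]] = {
    1: {"G": 1.0, "A": 0.8, "S": 0.5},
    2: {"P": 1.0, "H": 0.6, "G": 0.6},
}
DEFAULT_TELO_DEFAULT = 0.1

#: Default helical (acceptor-site) weight tables. Offset +1 is the
#: invariant triplet G and is enforced, not weighted.
DEFAULT_HELIX_WEIGHTS: dict[int, dict[str, float]] = {
    2: {"H": 1.0},
    3: {"R": 1.0},
}
DEFAULT_HELIX_DEFAULT = 0.2

#: Candidates scoring below this are dropped from telopeptide scans.
DEFAULT_SCORE_MIN = 0.3
#: Residues scanned at each end of the main helix for acceptor sites.
DEFAULT_END_WINDOW = 30
#: Flank-exclusion radius: "no other lysine within five residues".
DEFAULT_FLANK = 5

WINDOW_LEFT = 2  # residues shown left of K in the report window
WINDOW_RIGHT = 4  # residues shown right of K


@dataclass(frozen=True)
class MotifModel:
    """Per-offset residue weight table relative to the anchor lysine.

    ``weights`` maps offset -> residue -> weight in [0, 1]; residues
    absent from a table score ``default``. The K offset itself is fixed
    by the scan, never weighted. ``'X'`` and the ``'-'`` pad never match
    any position and score 0.
    """

    weights: dict[int, dict[str, float]]
    default: float

    def __post_init__(self) -> None:
        for table in self.weights.values():
            for res, w in table.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight out of [0,1] for residue {res!r}")
        if not 0.0 <= self.default <= 1.0:
            raise ValueError("default weight out of [0,1]")

    def weight(self, offset: int, residue: str) -> float:
        if residue in ("X", "-"):
            return 0.0
        return self.weights.get(offset, {}).get(residue, self.default)

    def score(self, chain_seq: str, k_pos: int) -> float:
        """Mean weight over the model's offsets; positions beyond the
        chain count as pad."""
        total = 0.0
        for off in self.weights:
            p = k_pos + off
            residue = chain_seq[p] if 0 <= p < len(chain_seq) else "-"
            total += self.weight(off, residue)
        return total / len(self.weights)


def default_telo_model() -> MotifModel:
    return MotifModel(weights={k: dict(v) for k, v in DEFAULT_TELO_WEIGHTS.items()},
                      default=DEFAULT_TELO_DEFAULT)


def default_helix_model() -> MotifModel:
    return MotifModel(weights={k: dict(v) for k, v in DEFAULT_HELIX_WEIGHTS.items()},
                      default=DEFAULT_HELIX_DEFAULT)


@dataclass
class CrosslinkSite:
    """One candidate reactive (telopeptide) or acceptor (helical) lysine."""

    chain_id: str
    site_class: str  # telo_N, telo_C, helix_N, helix_C
    k_pos: int
    window: str
    score: float
    flank_clear: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.site_class not in ("telo_N", "telo_C", "helix_N", "helix_C"):
            raise ValueError(f"unknown site_class {self.site_class!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score out of [0,1]")


def context_window(seq: str, k_pos: int) -> str:
    """The 7-residue report window k_pos-2 .. k_pos+4, '-'-padded."""
    out = []
    for p in range(k_pos - WINDOW_LEFT, k_pos + WINDOW_RIGHT + 1):
        out.append(seq[p] if 0 <= p < len(seq) else "-")
    return "".join(out)


def scan_telopeptide(
    chain: CollagenChain,
    telo: TelopeptideRegion,
    model: MotifModel | None = None,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[CrosslinkSite]:
    """Scan one telopeptide window for X-K-X'-X'' substrate sites.

    Every K in the window is a candidate; the score is the mean of the
    model weights at offsets +1 and +2. Candidates below ``score_min``
    are dropped; survivors are sorted by score descending, ties broken
    in favour of the K closest to the main helix.
    """
    model = model if model is not None else default_telo_model()
    seq = chain.sequence
    site_class = "telo_N" if telo.side == "N" else "telo_C"
    candidates: list[CrosslinkSite] = []
    for p in range(telo.start, telo.end):
        if seq[p] != "K":
            continue
        score = model.score(seq, p)
        if score < score_min:
            continue
        candidates.append(
            CrosslinkSite(
                chain_id=chain.chain_id,
                site_class=site_class,
                k_pos=p,
                window=context_window(seq, p),
                score=score,
            )
        )
    # the main helix abuts the window: at its end on the N side, at its
    # start on the C side
    if telo.side == "N":
        candidates.sort(key=lambda s: (-s.score, -s.k_pos))
    else:
        candidates.sort(key=lambda s: (-s.score, s.k_pos))
    return candidates


def scan_helical(
    chain: CollagenChain,
    main: HelixRegion,
    model: MotifModel | None = None,
    end_window: int = DEFAULT_END_WINDOW,
    enforce_register: bool = True,
) -> list[CrosslinkSite]:
    """Scan both ends of the main helix for Y-K-G-Y''-Y''' acceptor sites.

    Only the first and last ``end_window`` residues of the helix are
    scanned. A candidate is a K immediately followed by G; with
    ``enforce_register`` the K must occupy the third (X') position of a
    triplet, i.e. ``(k_pos - main.start) % 3 == 2``, so the following G
    is a triplet glycine. The score is the mean of the weights at
    offsets +2 and +3. The best-scoring site per end is retained (tie:
    the K nearer the helix end); at most two sites are returned.
    """
    model = model if model is not None else default_helix_model()
    seq = chain.sequence
    results: list[CrosslinkSite] = []
    windows = [
        ("helix_N", main.start, min(main.start + end_window, main.end)),
        ("helix_C", max(main.end - end_window, main.start), main.end),
    ]
    for site_class, lo, hi in windows:
        best: CrosslinkSite | None = None
        best_key: tuple[float, int] | None = None
        for p in range(lo, hi):
            if seq[p] != "K":
                continue
            if p + 1 >= len(seq) or seq[p + 1] != "G":
                continue
            if enforce_register and (p - main.start) % 3 != 2:
                continue
            score = model.score(seq, p)
            # distance from the relevant helix end, for tie-breaking
            dist = p - main.start if site_class == "helix_N" else main.end - 1 - p
            key = (-score, dist)
            if best_key is None or key < best_key:
                best_key = key
                best = CrosslinkSite(
                    chain_id=chain.chain_id,
                    site_class=site_class,
                    k_pos=p,
                    window=context_window(seq, p),
                    score=score,
                )
        if best is not None:
            results.append(best)
    return results


def check_flank_exclusion(
    chain: CollagenChain,
    site: CrosslinkSite,
    flank: int = DEFAULT_FLANK,
    bounds: Region | None = None,
) -> bool:
    """True iff no lysine other than the site's occurs within ±``flank``
    residues of it, clipped to ``bounds`` (default: the whole chain)."""
    seq = chain.sequence
    lo = site.k_pos - flank
    hi = site.k_pos + flank + 1
    if bounds is not None:
        lo = max(lo, bounds.start)
        hi = min(hi, bounds.end)
    lo = max(lo, 0)
    hi = min(hi, len(seq))
    for p in range(lo, hi):
        if p != site.k_pos and seq[p] == "K":
            return False
    return True
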