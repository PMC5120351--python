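"""Independent brute-force reference implementations used by the tests.

These re-derive expected results from first principles (window
enumeration, plain entropy sums) without sharing code paths with the
package internals they check.
"""

from __future__ import annotations

import math


def brute_force_gxy(
    seq: str, min_triplets: int, max_interruptions: int
) -> list[tuple[int, int, int]]:
    """All maximal non-overlapping Gly-X-X' runs as (start, end, register).

    Enumerates every (register, start, end) window, keeps those whose
    first and last triplets start with G and which contain at most
    ``max_interruptions`` non-G first positions, drops windows contained
    in a larger satisfying window of the same register, then selects
    greedily by (triplet count desc, start asc, register asc) subject to
    pairwise disjointness.
    """
    n = len(seq)
    satisfying: list[tuple[int, int, int]] = []
    for register in range(3):
        for start in range(register, n, 3):
            if seq[start] != "G":
                continue
            for end in range(start + 3 * min_triplets, n + 1, 3):
                if seq[end - 3] != "G":
                    continue
                bad = sum(1 for p in range(start, end, 3) if seq[p] != "G")
                if bad <= max_interruptions:
                    satisfying.append((start, end, register))
    maximal = [
        w
        for w in satisfying
        if not any(
            o != w and o[2] == w[2] and o[0] <= w[0] and w[1] <= o[1]
            for o in satisfying
        )
    ]
    maximal.sort(key=lambda w: (-(w[1] - w[0]) // 3, w[0], w[2]))
    kept: list[tuple[int, int, int]] = []
    for w in maximal:
        if all(w[1] <= k[0] or k[1] <= w[0] for k in kept):
            kept.append(w)
    return sorted(kept)


def entropy_information_bits(counts: list[float], pseudocount: float = 0.0) -> float:
    """Information content of one PWM column: log2(20) minus its
    Shannon entropy, computed with plain ``math`` calls."""
    total = sum(counts) + 20.0 * pseudocount
    if total == 0:
        return 0.0
    freqs = [(c + pseudocount) / total for c in counts]
    entropy = -sum(f * math.log2(f) for f in freqs if f > 0)
    return math.log2(20.0) - entropy


def all_lysines(seq: str, start: int, end: int) -> list[int]:
    """Every K position in [start, end) — completeness reference for the
    scanners before score filtering."""
    return [p for p in range(start, end) if seq[p] == "K"]
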