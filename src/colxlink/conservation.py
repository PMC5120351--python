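"""K-anchored site profiles, logo matrices, and the lysine-depletion
probability statistic.

Instead of a full multiple sequence alignment, site windows are aligned
by their anchor lysine: window *i* is the chain substring
``[k_pos - flank_left, k_pos + flank_right + 1)`` padded with ``'-'`` at
chain ends. Per-column residue frequencies give the position-weight
matrix; the information content of a column is ``log2(20)`` minus its
Shannon entropy in bits, the quantity a sequence-logo renderer stacks.

The depletion statistic quantifies how unlikely an observed lysine-free
stretch is under a background lysine frequency f_K: the probability that
N independently drawn residues contain no lysine is ``(1 - f_K)^N``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chain_io import CollagenChain
from .errors import EmptyProfileError
from .sites import CrosslinkSite

logger = logging.getLogger(__name__)

#: Column order of the 20 standard residues in PWM outputs.
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Background lysine frequency in proteins (7.2%).
DEFAULT_F_K = 0.072

LOG2_20 = math.log2(20.0)


@dataclass
class SiteProfile:
    """K-anchored aligned windows with their PWM and information content.

    ``counts`` and ``frequencies`` are (n_positions, 20) arrays over
    :data:`RESIDUES`; ``offsets`` gives each row's offset relative to
    the anchor K (offset 0 is the anchor column, all 'K').
    """

    site_class: str
    windows: list[str]
    offsets: list[int]
    counts: np.ndarray
    frequencies: np.ndarray
    info_content: np.ndarray

    @property
    def width(self) -> int:
        return len(self.offsets)


def entropy_bits(freqs: np.ndarray) -> float:
    """Shannon entropy of one frequency vector, in bits (0 log 0 = 0)."""
    f = np.asarray(freqs, dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def build_profile(
    sites: list[CrosslinkSite],
    chains: list[CollagenChain],
    flank_left: int = 2,
    flank_right: int = 4,
    pseudocount: float = 0.0,
) -> SiteProfile:
    """Build the K-anchored profile of a set of same-class sites.

    Counts exclude the ``'-'`` pad and ``'X'``; frequencies are
    ``(count + pseudocount) / (column_total + 20 * pseudocount)``. A
    column with no countable residues and zero pseudocount is reported
    as uniform with zero information content.
    """
    if not sites:
        raise EmptyProfileError("cannot build a profile from zero sites")
    classes = {s.site_class for s in sites}
    if len(classes) != 1:
        raise ValueError(f"sites span multiple classes: {sorted(classes)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    by_id = {c.chain_id: c for c in chains}

    width = flank_left + flank_right + 1
    offsets = list(range(-flank_left, flank_right + 1))
    windows: list[str] = []
    for s in sites:
        seq = by_id[s.chain_id].sequence
        chars = []
        for p in range(s.k_pos - flank_left, s.k_pos + flank_right + 1):
            chars.append(seq[p] if 0 <= p < len(seq) else "-")
        windows.append("".join(chars))

    res_index = {r: i for i, r in enumerate(RESIDUES)}
    counts = np.zeros((width, 20), dtype=float)
    for w in windows:
        for i, ch in enumerate(w):
            if ch in res_index:  # '-' and 'X' excluded
                counts[i, res_index[ch]] += 1

    frequencies = np.empty_like(counts)
    info = np.empty(width)
    for i in range(width):
        total = counts[i].sum() + 20.0 * pseudocount
        if total == 0:
            frequencies[i] = 1.0 / 20.0
            info[i] = 0.0
            continue
        frequencies[i] = (counts[i] + pseudocount) / total
        info[i] = LOG2_20 - entropy_bits(frequencies[i])

    return SiteProfile(
        site_class=sites[0].site_class,
        windows=windows,
        offsets=offsets,
        counts=counts,
        frequencies=frequencies,
        info_content=info,
    )


@dataclass(frozen=True)
class DepletionResult:
    """Probability that the observed lysine-free stretches arise by chance.

    ``region_lengths`` holds one residue count per chain; ``probability``
    is ``(1 - f_k) ** n_total`` with ``n_total`` their sum.
    """

    region_lengths: tuple[int, ...]
    n_total: int
    f_k: float
    probability: float


def lysine_depletion_probability(
    region_lengths: list[int],
    f_k: float = DEFAULT_F_K,
) -> DepletionResult:
    """Probability of lysine-free stretches of the given total length.

    With a background lysine occurrence ``f_k``, the chance that
    ``n_total = sum(region_lengths)`` independently drawn residues
    contain no lysine is ``(1 - f_k)^n_total``.
    """
    if not 0.0 < f_k < 1.0:
        raise ValueError("f_k must be in (0, 1)")
    lengths = [int(n) for n in region_lengths]
    if any(n < 0 for n in lengths):
        raise ValueError("region lengths must be non-negative")
    n_total = sum(lengths)
    probability = (1.0 - f_k) ** n_total
    return DepletionResult(
        region_lengths=tuple(lengths),
        n_total=n_total,
        f_k=f_k,
        probability=probability,
    )


def measure_depletion_regions(
    chains_with_sites: list[tuple[CollagenChain, dict[str, CrosslinkSite]]],
) -> dict[str, dict]:
    """Measure the lysine-free stretches flanking the main helix.

    For each chain with a rank-1 ``telo_C`` site, the stretch is the
    open interval between the main helix end and the telopeptide K
    (``k_pos - main_helix.end`` residues, excluding both the terminal
    helix residue and the K itself); for ``telo_N``, between the minor
    helix end and the K. Chains lacking the site or the landmark are
    skipped and logged. Returns, per class, the region lengths and a
    per-chain flag saying whether the stretch really contains no lysine.
    """
    out: dict[str, dict] = {
        "telo_C": {"chain_ids": [], "lengths": [], "lysine_free": []},
        "telo_N": {"chain_ids": [], "lengths": [], "lysine_free": []},
    }
    for chain, top_sites in chains_with_sites:
        main = chain.region("main_helix")
        minor = chain.region("minor_helix")

        site = top_sites.get("telo_C")
        if site is None or main is None:
            logger.info("chain %s: no telo_C site or main helix; skipped", chain.chain_id)
        else:
            length = site.k_pos - main.end
            stretch = chain.sequence[main.end : site.k_pos]
            out["telo_C"]["chain_ids"].append(chain.chain_id)
            out["telo_C"]["lengths"].append(length)
            out["telo_C"]["lysine_free"].append("K" not in stretch)

        site = top_sites.get("telo_N")
        if site is None or minor is None:
            logger.info("chain %s: no telo_N site or minor helix; skipped", chain.chain_id)
        else:
            length = site.k_pos - minor.end
            stretch = chain.sequence[minor.end : site.k_pos]
            out["telo_N"]["chain_ids"].append(chain.chain_id)
            out["telo_N"]["lengths"].append(length)
            out["telo_N"]["lysine_free"].append("K" not in stretch)
    return out


def logo_matrix_frame(profile: SiteProfile) -> pd.DataFrame:
    """The logo matrix as a DataFrame: one row per window position, one
    frequency column per residue, plus the info_content column."""
    df = pd.DataFrame(
        profile.frequencies,
        columns=list(RESIDUES),
        index=pd.Index(profile.offsets, name="offset"),
    )
    df["info_content"] = profile.info_content
    return df


def export_logo_matrix(profile: SiteProfile, path: str | Path) -> None:
    """Write the profile's logo matrix as TSV, consumable by any
    sequence-logo renderer."""
    logo_matrix_frame(profile).to_csv(
        path, sep="\t", index_label="offset", float_format="%.10g"
    )
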