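"""Synthetic fibrillar-collagen chains with planted ground truth.

Each generated chain follows the clade-A architecture: an N-propeptide
filler, a short minor Gly-X-X' helix, an N-telopeptide carrying one
cross-link lysine, a long central Gly-X-X' helix with acceptor sites
near both ends and a terminal (GPP)n run, a lysine-poor C-telopeptide
carrying one X-K-X'-X'' site, and a COLFI propeptide stub.

Two generator choices make planted landmarks uniquely recoverable and
are deliberate idealisations: non-collagenous backgrounds never contain
glycine, so helix boundaries are unambiguous; and the triplet following
a background helical lysine never carries H at X or R at X', so the
planted K-G-H-R acceptor sites are the unique top-scoring candidates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chain_io import CollagenChain, Region, write_fasta
from .errors import SyntheticSpecError

#: Residues available to non-collagenous background draws: all standard
#: residues except G (kept out of non-helical segments so planted helix
#: boundaries are the only detectable ones) and K (inserted explicitly).
_NONCOL_RESIDUES = tuple(r for r in "ACDEFHILMNPQRSTVWY")

#: Helix X/X' background: P-enriched, G and K excluded.
_HELIX_RESIDUES = tuple(r for r in "ACDEFHILMNPQRSTVWY")
_HELIX_P = 0.30
_HELIX_A = 0.15

ALL_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic collagen family.

    Lengths are residues unless suffixed ``_triplets`` (Gly-X-X'
    triplets, 3 residues each). ``telo_motif`` spans offsets -1..+2
    around its K; ``helix_motif`` spans -1..+3, its central G being the
    invariant triplet glycine. ``helix_site_offset`` counts triplets
    between each planted acceptor site and the nearest helix landmark
    (the helix start on the N side; the start of the (GPP)n run on the
    C side, so the motif never overwrites the terminus).
    """

    seed: int = 0
    n_chains: int = 19
    n_prop_len: int = 30
    minor_triplets: int = 5
    n_telo_len: int = 15
    main_triplets: int = 100
    c_telo_len: int = 20
    colfi_len: int = 30
    gpp_repeats: int = 3
    telo_motif: str = "EKGP"
    helix_motif: str = "MKGHR"
    helix_site_offset: int = 3
    n_site_from_helix: int = 10  # N-telo K sits this many residues before the main helix
    c_site_offset: int = 10  # C-telo K sits this many residues after the main helix
    background_k_freq: float = 0.072
    substitution_rate: float = 0.0
    spare_planted_k: bool = True
    spare_triplet_g: bool = True
    n_truncated: bool = False  # emulate chains incomplete at the N-terminal end
    decoy_k_offset: int | None = None  # extra K planted this far after the C-telo K

    def validate(self) -> None:
        positive = {
            "n_chains": self.n_chains,
            "n_prop_len": self.n_prop_len,
            "minor_triplets": self.minor_triplets,
            "n_telo_len": self.n_telo_len,
            "main_triplets": self.main_triplets,
            "c_telo_len": self.c_telo_len,
            "colfi_len": self.colfi_len,
            "gpp_repeats": self.gpp_repeats,
            "helix_site_offset": self.helix_site_offset,
        }
        for name, value in positive.items():
            if value <= 0:
                raise SyntheticSpecError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.background_k_freq < 1.0:
            raise SyntheticSpecError("background_k_freq must be in [0, 1)")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SyntheticSpecError("substitution_rate must be in [0, 1)")
        if len(self.telo_motif) != 4 or self.telo_motif[1] != "K":
            raise SyntheticSpecError("telo_motif must be a 4-mer with K second")
        if len(self.helix_motif) != 5 or self.helix_motif[1] != "K" or self.helix_motif[2] != "G":
            raise SyntheticSpecError("helix_motif must be a 5-mer '?KG??'")
        if self.helix_site_offset * 3 >= self.main_triplets * 3 / 2:
            raise SyntheticSpecError("helix_site_offset too large for main_triplets")
        if self.gpp_repeats + self.helix_site_offset + 2 > self.main_triplets:
            raise SyntheticSpecError("gpp_repeats + helix_site_offset exceed main helix")
        if not 1 <= self.n_site_from_helix < self.n_telo_len:
            raise SyntheticSpecError("n_site_from_helix must be in [1, n_telo_len)")
        if not 1 <= self.c_site_offset <= self.c_telo_len - 3:
            raise SyntheticSpecError("c_site_offset must leave room for the motif")
        if self.decoy_k_offset is not None and not (
            4 <= self.decoy_k_offset < self.c_telo_len - self.c_site_offset
        ):
            raise SyntheticSpecError("decoy_k_offset must fall inside the C-telopeptide")


@dataclass
class GroundTruth:
    """Planted annotations of one synthetic chain."""

    chain_id: str
    regions: dict[str, tuple[int, int]]
    sites: dict[str, int]  # site_class -> planted K position
    depletion_lengths: dict[str, int] = field(default_factory=dict)


def _draw_noncollagenous(rng: np.random.Generator, n: int, k_freq: float) -> list[str]:
    """Background for propeptides/COLFI: K at k_freq, otherwise uniform
    over the G-free residue set."""
    out = []
    for _ in range(n):
        if k_freq > 0 and rng.random() < k_freq:
            out.append("K")
        else:
            out.append(_NONCOL_RESIDUES[rng.integers(len(_NONCOL_RESIDUES))])
    return out


def _draw_lysine_free(rng: np.random.Generator, n: int) -> list[str]:
    """Lysine-free, glycine-free background for telopeptides."""
    pool = tuple(r for r in _NONCOL_RESIDUES if r != "K")
    return [pool[rng.integers(len(pool))] for _ in range(n)]


def _draw_helix_x(rng: np.random.Generator, exclude: str = "") -> str:
    """One helix X/X' residue from the P-enriched background."""
    while True:
        u = rng.random()
        if u < _HELIX_P:
            res = "P"
        elif u < _HELIX_P + _HELIX_A:
            res = "A"
        else:
            rest = tuple(r for r in _HELIX_RESIDUES if r not in ("P", "A"))
            res = rest[rng.integers(len(rest))]
        if res not in exclude:
            return res


def _build_main_helix(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[list[str], int, int]:
    """Main-helix residues plus the two planted K offsets (relative to
    the helix start)."""
    T = spec.main_triplets
    triplets: list[list[str]] = []
    prev_k = False
    for _ in range(T):
        x = _draw_helix_x(rng, exclude="H" if prev_k else "")
        if spec.background_k_freq > 0 and rng.random() < spec.background_k_freq:
            xp = "K"
        else:
            xp = _draw_helix_x(rng, exclude="R" if prev_k else "")
        triplets.append(["G", x, xp])
        prev_k = xp == "K"

    # terminal (GPP)n run; the triplet just before it must not itself be
    # GPP, so the planted run is the maximal one
    t_pre = T - spec.gpp_repeats - 1
    if t_pre >= 0 and triplets[t_pre][1:] == ["P", "P"]:
        triplets[t_pre][2] = _draw_helix_x(rng, exclude="P")
    for t in range(T - spec.gpp_repeats, T):
        triplets[t] = ["G", "P", "P"]

    def plant(t: int) -> int:
        """Plant the acceptor motif with its K at triplet t's X' position."""
        m = spec.helix_motif  # Y K G Y'' Y'''
        triplets[t][1] = m[0]
        triplets[t][2] = m[1]
        triplets[t + 1][1] = m[3]
        triplets[t + 1][2] = m[4]
        return 3 * t + 2

    k_n = plant(spec.helix_site_offset)
    k_c = plant(T - spec.gpp_repeats - spec.helix_site_offset)
    return [r for trip in triplets for r in trip], k_n, k_c


def generate_chain(spec: SyntheticSpec, index: int) -> tuple[CollagenChain, GroundTruth]:
    """Generate one chain, deterministic given ``(spec.seed, index)``.

    Each chain draws from its own counter-based substream, so families
    are reproducible under any generation order.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, index])
    parts: list[str] = []
    regions: dict[str, tuple[int, int]] = {}
    sites: dict[str, int] = {}

    pos = 0
    if not spec.n_truncated:
        # N-propeptide filler
        parts.extend(_draw_noncollagenous(rng, spec.n_prop_len, spec.background_k_freq))
        regions["n_propeptide"] = (pos, pos + spec.n_prop_len)
        pos += spec.n_prop_len

        # minor helix: lysine-free Gly-X-X'
        for _ in range(spec.minor_triplets):
            parts.extend(["G", _draw_helix_x(rng), _draw_helix_x(rng)])
        regions["minor_helix"] = (pos, pos + 3 * spec.minor_triplets)
        pos += 3 * spec.minor_triplets

        # N-telopeptide: lysine-free background with the substrate motif
        # planted so its K sits n_site_from_helix residues before the helix
        telo = _draw_lysine_free(rng, spec.n_telo_len)
        k_local = spec.n_telo_len - spec.n_site_from_helix
        telo[k_local - 1 : k_local + 3] = list(spec.telo_motif)
        parts.extend(telo)
        regions["n_telopeptide"] = (pos, pos + spec.n_telo_len)
        sites["telo_N"] = pos + k_local
        pos += spec.n_telo_len

    # main helix with planted acceptor sites and (GPP)n terminus
    helix, k_n_off, k_c_off = _build_main_helix(spec, rng)
    regions["main_helix"] = (pos, pos + len(helix))
    regions["gpp_terminus"] = (pos + len(helix) - 3 * spec.gpp_repeats, pos + len(helix))
    sites["helix_N"] = pos + k_n_off
    sites["helix_C"] = pos + k_c_off
    parts.extend(helix)
    pos += len(helix)

    # C-telopeptide: lysine-free background with the substrate motif
    telo = _draw_lysine_free(rng, spec.c_telo_len)
    telo[spec.c_site_offset - 1 : spec.c_site_offset + 3] = list(spec.telo_motif)
    if spec.decoy_k_offset is not None:
        telo[spec.c_site_offset + spec.decoy_k_offset] = "K"
    parts.extend(telo)
    regions["c_telopeptide"] = (pos, pos + spec.c_telo_len)
    sites["telo_C"] = pos + spec.c_site_offset
    pos += spec.c_telo_len

    # COLFI stub filler
    parts.extend(_draw_noncollagenous(rng, spec.colfi_len, spec.background_k_freq))
    regions["colfi_stub"] = (pos, pos + spec.colfi_len)
    pos += spec.colfi_len

    seq = _apply_substitutions(spec, rng, parts, regions, sites)

    chain_id = f"syn{index:03d}"
    chain = CollagenChain(chain_id=chain_id, species="synthetic", sequence=seq)
    depletion: dict[str, int] = {}
    if "telo_N" in sites:
        depletion["telo_N"] = sites["telo_N"] - regions["minor_helix"][1]
    depletion["telo_C"] = sites["telo_C"] - regions["main_helix"][1]
    truth = GroundTruth(
        chain_id=chain_id, regions=regions, sites=sites, depletion_lengths=depletion
    )
    return chain, truth


def _apply_substitutions(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    parts: list[str],
    regions: dict[str, tuple[int, int]],
    sites: dict[str, int],
) -> str:
    if spec.substitution_rate == 0:
        return "".join(parts)
    protected: set[int] = set()
    if spec.spare_planted_k:
        protected.update(sites.values())
    if spec.spare_triplet_g:
        for label in ("minor_helix", "main_helix"):
            if label in regions:
                start, end = regions[label]
                protected.update(range(start, end, 3))
    out = list(parts)
    for p in range(len(out)):
        if p in protected:
            continue
        if rng.random() < spec.substitution_rate:
            alternatives = tuple(r for r in ALL_RESIDUES if r != out[p])
            out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def generate_chains(
    spec: SyntheticSpec,
    overrides: list[dict] | None = None,
) -> list[tuple[CollagenChain, GroundTruth]]:
    """Generate the whole family; ``overrides[i]`` replaces spec fields
    for chain i (e.g. per-chain telopeptide lengths or truncation)."""
    out = []
    for i in range(spec.n_chains):
        chain_spec = spec
        if overrides is not None and i < len(overrides) and overrides[i]:
            chain_spec = dataclasses.replace(spec, **overrides[i])
        out.append(generate_chain(chain_spec, i))
    return out


def generate_family(
    spec: SyntheticSpec,
    fasta_path: str | Path,
    regions_path: str | Path,
    sites_path: str | Path,
    overrides: list[dict] | None = None,
) -> list[tuple[CollagenChain, GroundTruth]]:
    """Write the family as FASTA plus two ground-truth TSVs.

    The regions TSV uses the annotation dialect of
    :func:`colxlink.chain_io.read_annotations`; the sites TSV has rows
    ``chain_id, site_class, k_pos``.
    """
    family = generate_chains(spec, overrides)
    write_fasta([c for c, _ in family], fasta_path)
    with open(regions_path, "w") as fh:
        fh.write("chain_id\tlabel\tstart\tend\n")
        for _, truth in family:
            for label, (start, end) in sorted(truth.regions.items(), key=lambda kv: kv[1]):
                fh.write(f"{truth.chain_id}\t{label}\t{start}\t{end}\n")
    with open(sites_path, "w") as fh:
        fh.write("chain_id\tsite_class\tk_pos\n")
        for _, truth in family:
            for site_class, k_pos in sorted(truth.sites.items(), key=lambda kv: kv[1]):
                fh.write(f"{truth.chain_id}\t{site_class}\t{k_pos}\n")
    return family
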