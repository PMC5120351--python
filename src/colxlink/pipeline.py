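"""The full analysis wired end to end.

annotate (helices, GPP terminus, telopeptides) -> scan (substrate and
acceptor sites) -> rank -> flank-exclusion check -> K-anchored profiles
-> lysine-depletion statistic. This is the library surface the CLI and
the reproduction script drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chain_io import CollagenChain, Region
from .config import RunConfig
from .conservation import (
    SiteProfile,
    DepletionResult,
    build_profile,
    lysine_depletion_probability,
    measure_depletion_regions,
)
from .errors import NoCollagenousDomainError
from .helix_detect import classify_helices, detect_gxy_regions, find_gpp_terminus
from .sites import CrosslinkSite, check_flank_exclusion, scan_helical, scan_telopeptide
from .telopeptide import extract_telopeptides

logger = logging.getLogger(__name__)

SITE_CLASSES = ("telo_N", "telo_C", "helix_N", "helix_C")


@dataclass
class ChainAnalysis:
    """Everything computed for one chain."""

    chain: CollagenChain
    status: str = "ok"  # "ok" or "no_main_helix"
    sites: dict[str, list[CrosslinkSite]] = field(default_factory=dict)

    @property
    def top_sites(self) -> dict[str, CrosslinkSite]:
        return {cls: ranked[0] for cls, ranked in self.sites.items() if ranked}


@dataclass
class FamilyAnalysis:
    """Family-level results: per-chain analyses, per-class profiles and
    the depletion statistics."""

    chains: list[ChainAnalysis]
    profiles: dict[str, SiteProfile]
    depletion_regions: dict[str, dict]
    depletion: dict[str, DepletionResult]

    def all_sites(self) -> list[CrosslinkSite]:
        out: list[CrosslinkSite] = []
        for analysis in self.chains:
            for cls in SITE_CLASSES:
                out.extend(analysis.sites.get(cls, []))
        return out


def annotate_chain(chain: CollagenChain, config: RunConfig | None = None) -> ChainAnalysis:
    """Detect and attach the helix, GPP-terminus and telopeptide regions.

    Chains with no detectable collagenous domain get status
    ``no_main_helix`` and no annotations; they are reported, not dropped.
    """
    config = config or RunConfig()
    regions = detect_gxy_regions(
        chain,
        min_triplets=config.helix_min_triplets,
        max_interruptions=config.helix_max_interruptions,
    )
    try:
        minor, main = classify_helices(regions, config.helix_minor_max_fraction)
    except NoCollagenousDomainError:
        logger.warning("chain %s: no collagenous domain detected", chain.chain_id)
        return ChainAnalysis(chain=chain, status="no_main_helix")

    chain.add_region(main.region)
    if minor is not None:
        chain.add_region(minor.region)
    gpp = find_gpp_terminus(chain, main, config.helix_gpp_min_repeats)
    if gpp is not None:
        chain.add_region(gpp)
    n_telo, c_telo = extract_telopeptides(chain, minor, main, config.telo_c_max_len)
    for telo in (n_telo, c_telo):
        if telo is not None:
            chain.add_region(telo.region)
    return ChainAnalysis(chain=chain)


def analyze_chain(chain: CollagenChain, config: RunConfig | None = None) -> ChainAnalysis:
    """Annotate one chain and scan it for cross-linking sites."""
    config = config or RunConfig()
    analysis = annotate_chain(chain, config)
    if analysis.status != "ok":
        return analysis

    main_region = chain.region("main_helix")
    # rebuild the helix view used by the scanners
    from .helix_detect import HelixRegion  # local import to avoid cycle noise

    main = HelixRegion(
        region=main_region,
        register=main_region.start % 3,
        triplet_count=(main_region.end - main_region.start) // 3,
        interruptions=sum(
            1
            for p in range(main_region.start, main_region.end, 3)
            if chain.sequence[p] != "G"
        ),
    )

    telo_model = config.telo_model()
    helix_model = config.helix_model()

    sites: dict[str, list[CrosslinkSite]] = {}
    from .telopeptide import TelopeptideRegion

    for label, side in (("n_telopeptide", "N"), ("c_telopeptide", "C")):
        region = chain.region(label)
        if region is None:
            continue
        telo = TelopeptideRegion(
            region=region, side=side, sequence=chain.sequence[region.start : region.end]
        )
        ranked = scan_telopeptide(chain, telo, telo_model, config.sites_score_min)
        for s in ranked:
            s.flank_clear = check_flank_exclusion(chain, s, config.sites_flank, region)
        sites[f"telo_{side}"] = ranked

    helical = scan_helical(
        chain,
        main,
        helix_model,
        config.sites_end_window,
        config.sites_enforce_register,
    )
    for s in helical:
        s.flank_clear = check_flank_exclusion(chain, s, config.sites_flank, main_region)
        sites.setdefault(s.site_class, []).append(s)

    analysis.sites = sites
    return analysis


def analyze_family(
    chains: list[CollagenChain],
    config: RunConfig | None = None,
) -> FamilyAnalysis:
    """Run the full pipeline over a chain collection.

    Profiles are built per site class from the rank-1 sites; the
    depletion statistic uses the lysine-free stretches between each
    helix landmark and the rank-1 telopeptide lysine, at the configured
    background lysine frequency.
    """
    config = config or RunConfig()
    analyses = [analyze_chain(chain, config) for chain in chains]

    profiles: dict[str, SiteProfile] = {}
    for cls in SITE_CLASSES:
        top = [a.top_sites[cls] for a in analyses if cls in a.top_sites]
        if top:
            profiles[cls] = build_profile(
                top,
                chains,
                flank_left=config.conservation_flank_left,
                flank_right=config.conservation_flank_right,
                pseudocount=config.conservation_pseudocount,
            )

    with_sites = [(a.chain, a.top_sites) for a in analyses if a.status == "ok"]
    depletion_regions = measure_depletion_regions(with_sites)
    depletion = {
        cls: lysine_depletion_probability(info["lengths"], config.conservation_f_k)
        for cls, info in depletion_regions.items()
        if info["lengths"]
    }
    return FamilyAnalysis(
        chains=analyses,
        profiles=profiles,
        depletion_regions=depletion_regions,
        depletion=depletion,
    )


def depletion_json(result: FamilyAnalysis) -> dict:
    """Depletion results in the JSON-report dialect."""
    out: dict = {}
    for cls, dep in result.depletion.items():
        info = result.depletion_regions[cls]
        out[cls] = {
            "chain_ids": info["chain_ids"],
            "lengths": list(dep.region_lengths),
            "lysine_free": info["lysine_free"],
            "n_total": dep.n_total,
            "f_k": dep.f_k,
            "probability": dep.probability,
        }
    return out
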