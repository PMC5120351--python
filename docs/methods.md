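# Methods

This note records what each stage of the analysis computes, the
assumptions behind it, the defaults and why they were chosen, and what
the synthetic data does and does not emulate.

## Coordinate and alphabet conventions

All coordinates are 0-based half-open, internally and in every machine
output; log lines may additionally print 1-based positions, labelled as
such. Sequences use the 20 standard one-letter codes plus `X` (unknown
residue). `X` never matches a motif position and never counts as
lysine — ambiguity is treated conservatively. Selenocysteine (`U`) and
pyrrolysine (`O`) are rejected rather than silently remapped.
Hydroxyproline and hydroxylysine are not representable in one-letter
sequence; `P` and `K` stand for both the plain and hydroxylated forms,
which is also why the lysine/hydroxylysine distinction at cross-linking
sites is invisible to this analysis.

## Collagenous region detection

A collagenous region is a maximal run of consecutive G-X-X′ triplets in
one of three registers (start offset mod 3), with glycine at the first
position of every triplet except at most `helix.max_interruptions` of
them. Regions are trimmed to G-anchored ends: an interruption may not
occupy the first or last triplet, which stabilises boundary recovery.
Runs shorter than `helix.min_triplets` are discarded. Overlapping runs
from different registers are resolved in favour of the longer run, ties
by smaller start, then smaller register — applied as a greedy selection
over containment-maximal windows ranked by that key.

Defaults: `min_triplets = 5`, `max_interruptions = 1`. Real main helices
run to ~338 triplets and are described as uninterrupted, but database
chains contain `X` runs and occasional substitutions, so one tolerated
interruption is allowed; both are configurable. The X and X′ positions
are deliberately unconstrained: composition-based scoring (e.g. triple-
helix propensity) is out of scope, detection is purely positional.

The **main helix** is the detected region with the most triplets (tie:
the more C-terminal). The **minor helix** is the longest region strictly
N-terminal to it with at most `minor_max_fraction = 0.25` of the main
helix's triplets. No quantitative definition of "short" exists for the
minor helix; 0.25 cleanly separates the human-like architecture (minor
helix of tens of residues vs a main helix of ~1000) and is
configurable.

The **(GPP)n terminus** is the most C-terminal run of at least
`gpp_min_repeats = 2` consecutive *exact* GPP triplets within the main
helix, in its register. Exact G-P-P is required because the motif is
named as such; how many repeats suffice is not specified anywhere, so 2
is this package's choice, exposed in config and worth a sensitivity
check when applied to divergent chains.

## Telopeptide windows

The N-telopeptide window runs from the minor helix end (or the chain
start when no minor helix exists) to the main helix start; chains whose
sequence begins inside the main helix (N-terminally incomplete database
entries) have no N window. The C-telopeptide window runs from the main
helix end to the COLFI boundary when one is annotated — a user-supplied
`colfi_stub` region always wins — else for `telo.c_max_len = 40`
residues. Vertebrate C-telopeptides are ~11–26 residues; 40 leaves
slack for invertebrate chains without swallowing much of the
C-propeptide. For chains where the window holds no recognisable site,
the rule-based window is still reported and the scan simply returns
nothing; no attempt is made to shift windows by homology.

## Site scanning and scoring

**Telopeptide (substrate) sites.** Every lysine in the window is a
candidate. Score = mean of per-offset weights at +1 (X′: G 1.0, A 0.8,
S 0.5, else 0.1) and +2 (X″: P 1.0, H 0.6, G 0.6, else 0.1).
Candidates below `sites.score_min = 0.3` are dropped; the rest are
ranked by score, ties to the K closest to the main helix. The weight
tables are configuration data seeded from the residues observed at each
position across clade-A chains; `score_min = 0.3` admits every consensus
variant seen in that clade (KGP, KAH, KAG, KST, KSG, KGH) while
rejecting unrelated lysines in arbitrary context (score 0.1). The
single-site-per-telopeptide assumption lives in downstream consumers,
which take rank 1; the report keeps all passing candidates.

**Helical (acceptor) sites.** Only the first and last
`sites.end_window = 30` residues of the main helix are scanned — the
biological acceptor sites sit near the helix ends, and the window must
comfortably contain the planted synthetic sites and the ~90-residue
real offsets scaled down. A candidate is a K immediately followed by G
with the register constraint `(k_pos − helix.start) mod 3 == 2`: the
acceptor pattern Y-K-G-Y″-Y″′ places K in the third triplet position so
that the following G is the invariant triplet glycine. The constraint
can be disabled for interrupted helices. Score = mean of weights at +2
(H 1.0 else 0.2) and +3 (R 1.0 else 0.2); the best-scoring site per end
is kept (tie: nearer the helix end). No score floor applies — helix ends
with only a bare K-G still report their best candidate, matching the
transition from KG-only to KGH patterns across lineages.

**Flank exclusion.** A site is flagged `flank_clear` when no other
lysine occurs within ±`sites.flank = 5` residues, clipped to the
analysis region. A lysine exactly 6 residues away is clear; exactly 5
away is not.

## Conservation profiles

Site windows are aligned by their anchor K rather than by a multiple
sequence alignment: window i is `[k_pos − flank_left, k_pos +
flank_right + 1)` (defaults 2 and 4), padded with `-` at chain ends.
This matches how the site logos are centred on the cross-linking lysine
and removes the alignment program as a dependency; it is exact at the
anchor and degrades only if the true alignment would place gaps inside
the 7-residue window. Counts exclude pads and `X`; frequencies apply a
pseudocount (default 0 — raw alignment frequencies; 0.5 is the
documented alternative for small families); column information content
is `log2(20) − H` bits, without small-sample correction by default
(renderer-specific corrections vary; a config flag can add the
pseudocount smoothing). An all-pad column is reported as uniform with
zero information.

## Depletion statistic

For each chain with a rank-1 C-telopeptide site, the measured stretch
is the open interval between the main helix end and the site's K
(`k_pos − main_helix.end` residues — the terminal helix residue and the
K itself both excluded); on the N side, between the minor helix end and
the K. The probability that the summed stretch length N is lysine-free
by chance is `(1 − f_K)^N` with `conservation.f_k = 0.072`, the average
lysine occurrence in proteins. Whether the original totals counted the
boundary residues is not recoverable; the open-interval rule is one
deterministic, stated choice, and each chain's stretch is additionally
checked and reported as actually lysine-free or not. Chains lacking the
site or the landmark are skipped and logged.

## Synthetic data

The generator emits chains with the clade-A architecture: N-propeptide
filler, minor helix (default 5 triplets), N-telopeptide (15 residues,
lysine-free, substrate motif EKGP planted with its K 10 residues before
the main helix), main helix (100 triplets with background lysines at
third-triplet positions at frequency 0.072, acceptor motifs MKGHR
planted 3 triplets from each end, terminal (GPP)₃), C-telopeptide (20
residues, lysine-free, motif K 10 residues after the helix end), and a
COLFI stub. 100 triplets keeps the architecture's proportions (helix ≫
minor helix ≫ telopeptides) at about a third of real scale; all lengths
are spec fields. A single integer seed drives a counter-based per-chain
substream, so families are reproducible under any generation order.

Design choices that make planted truth exactly recoverable:

- Non-collagenous backgrounds exclude glycine, so the planted helix
  boundaries are the only detectable ones.
- The triplet following a background helical lysine never draws H at X
  or R at X′, and the triplet preceding the (GPP)n run is never itself
  GPP, so the planted acceptor sites and terminus are the unique
  top-scoring/maximal candidates.
- The C-side acceptor offset is counted from the start of the (GPP)n
  run, so the motif never overwrites the terminus.
- Substitution noise (optional, i.i.d. per residue) spares planted K
  anchors and triplet glycines by default, isolating scanner robustness
  from helix-detection degradation; a flag lifts both protections.

What the generator does **not** emulate: realistic amino-acid
composition beyond lysine frequency and the Gly-X-X′ skeleton, indels,
domain-level homology between chains, interrupted helices, or genuinely
ambiguous boundaries. Passing recovery tests therefore demonstrates the
pipeline's correctness on architecturally faithful input, not its
robustness to alignment-hard real sequences — on real chains the
configurable slack (interruptions, `c_max_len`, relaxed register) does
that work and deserves per-dataset review.

## Numerical and degenerate-input conventions

Scores and frequencies are plain double arithmetic; no tolerance issues
arise beyond the 1e-9 column-sum check on PWM frequencies. Ties are
broken deterministically everywhere (documented per operation above).
Degenerate inputs: an empty FASTA yields an empty collection and a
warning; chains with no detectable collagenous domain are reported with
status `no_main_helix`, never dropped; a telopeptide window of length
zero is absent, not empty; an empty site list cannot form a profile
(named error); depletion of zero total length is exactly 1.

## Problem sizes in the verification suite

The property suite runs helix-detection oracle comparison on 500 random
G-enriched sequences of ≤200 residues, noise-free recovery on 100
families of 2 chains, and 2%-substitution recall on 200 families of 2
chains; the reproduction script uses a 19-chain family for the
depletion statistics. Recovery rates are scale-free (they depend on the
planted architecture, not on chain count), so small families are used
throughout; the full suite completes in a few seconds.
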