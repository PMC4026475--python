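# Methods

This note records the models, parameter choices and numerical decisions
behind `numtscan`, and what the simulation-based tests do and do not
establish.

## Repeat decomposition

An R2 array is modelled as a contiguous tiling of a sequence by
fixed-width repeat units (11 bp for the built-in A–E inventory) and
short literal segments representing truncated units.  The decomposer
runs a forward dynamic program over tiling end positions.  Transitions
consume either one full unit — an 11-bp window within edit distance ≤ 2
of some inventory unit — or a literal of 1–10 bp that must be an exact
prefix or suffix of an inventory unit (a truncated-unit model; arbitrary
literals would absorb flanking sequence).  The tiling maximising the
tuple (exact units, total units, −literal bp) wins, leftmost on ties.
Inexact units are assigned to the nearest class (earlier label on ties)
and flagged so callers can audit them.

Numerical choices:

* **Unit tolerance = edit distance 2.**  The motif classes themselves
  differ by 1–2 substitutions; a stricter tolerance fragments arrays, a
  looser one merges classes.  Substitution (Hamming) distance is used as
  a fast screen — it equals the edit distance for substitution-dominated
  variation — with a Levenshtein fallback (edlib) for windows failing the
  screen, so indel-shifted units within tolerance are still recognised.
* **Literal minimum lengths.**  Internal literals (between full units)
  may be as short as 2 bp; array-boundary literals must reach 5 bp.  The
  asymmetry reflects risk: an internal literal only appears where the
  tiling phase demands it, while a boundary literal competes with random
  flanking sequence (a ≥5-bp exact affix match has probability ≲ 1 % per
  boundary on random flanks).
* **Array requirement: ≥ 2 units.**  A single within-tolerance window is
  not an array.  No exact-unit quota is imposed beyond scoring: two
  consecutive near-motif windows in random sequence are already
  vanishingly unlikely (~10⁻⁴ per 300 bp), so sequences without tandem
  structure — numts here — return an empty decomposition, N = 0.
* **N counts full units only**; literals contribute to array length but
  not to N.  This matches the published table's arithmetic
  (length = 11·N + literal bp).
* **Period inference** counts exact k-mer recurrences (k = 8 by default)
  at every candidate spacing 5–50 and returns the spacing with the most,
  smallest on ties, or none below 3 recurrences.  Raw counts (not
  normalised per opportunity) deliberately favour the fundamental period
  over its multiples.

Three of the published size-class rows shipped in
`numtscan.known_structures` print run counts that contradict their own
N and length columns; they are flagged (`arithmetic_consistent`) and
excluded from length/N summaries, since the N and length columns agree
with each other and with the accompanying prose.

## Distances and clades

K2P distances are computed with pairwise deletion (complete deletion
behind a flag): sites with a gap or ambiguity in either sequence, or in
the masked R2 block, are excluded.  Saturated pairs (1 − 2P − Q ≤ 0)
raise an error naming the pair rather than returning NaN.

Clade partitioning replaces model-based tree inference: at the
divergences involved (numt vs mtDNA separations several-fold larger than
within-clade variation) any reasonable partitioner recovers the clades,
and posterior probabilities are not a goal.  Average-linkage merge
heights are scanned for the largest relative gap; heights below a noise
floor (a quarter of the median positive height) are floored first,
because merges of identical clones occur at height 0 and would otherwise
produce degenerate ratios.  The resulting partition is accepted only if
mean between-clade distance / mean within-clade distance ≥ 5 (the
`min_ratio` default); otherwise the trivial single clade is returned.
Per-clade silhouette means are reported as separation scores.

## Mutational steps and networks

Steps between gapped haplotypes = substitutions per site + one step per
maximal run of columns gapped in exactly one sequence (an indel is one
event regardless of length; shared-gap columns are transparent).  This
indel-as-one-event convention is a modelling choice, not a theorem: the
resulting dissimilarity is **not** a metric on gapped strings (an
all-gap intermediate can hide substitutions under a single indel), though
it coincides with Hamming distance — and is therefore metric — on
gapless strings.  Networks keep every edge belonging to at least one
minimum spanning tree (Kruskal with ties retained), a deliberate
simplification of statistical-parsimony networks: it preserves the
step-count comparisons between groups without implementing connection
limits.

## Numt calling

Three lines of evidence, combined conservatively: repeat absence
(fraction of members with N = 0 ≥ 0.9 — not 1.0, tolerating decomposer
edge cases), anchor membership (a clade holding an independently
verified mtDNA sequence is never called numt; anchor evidence dominates),
and mean internal steps reported as corroboration rather than a hard
criterion.  With no anchors supplied, the clade with the highest
repeat-bearing fraction is presumed authentic.  An anchor split across
clades is recorded as a warning on the report, not an error.

## Heteroplasmy calling

Sequence heteroplasmy must be separated from polymerase error.  The
default method uses **variant-site support**: a variant (column, base)
pair carried by ≥ 2 of an individual's clones is treated as genuine;
private variants are discounted as error; clones are then grouped by
their signatures over supported variants.  The rationale is that a
polymerase error is private to one clone's template lineage while a real
minor haplotype's diagnostic sites recur independently — the same
principle behind standard amplicon denoising.

A distance-based alternative (`method="distance"`) collapses singleton
haplotypes lying within ceil(λ + 2√λ) steps of the nearest multi-clone
haplotype, λ from the error model.  It is not the default because at the
study's own error rate (λ ≈ 1.2 expected core errors per clone,
error-free probability e^(−λ) ≈ 0.3) most clones are unique exact
haplotypes, so a genuine minor haplotype rarely yields the two identical
clones the rule needs, and detection sensitivity drops to ~0.5 at
10 clones per individual; the site-support rule reaches ~0.98 under the
same conditions.  Neither method can rescue an individual whose minor
haplotype was sampled into fewer than two clones — a sampling limit, not
an algorithmic one.

Length heteroplasmy is simpler: ≥ 2 distinct R2 array lengths among the
individual's decompositions.

## Error model

Per-clone error counts are Poisson with mean λ = rate × length × cycles
(errors rare, independent per bp and cycle).  Defaults: rate
7.2 × 10⁻⁵ /bp/cycle, 34 cycles; length is an explicit input because the
relevant span differs by use (full amplicon for raw expectations, the
unmasked core for haplotype collapsing).  Re-cloning summaries count
mutations against a per-site majority consensus, ties going to the
first-seen base and flagged.  The Poisson zero class (e^(−1.77) ≈ 17 %
identical clones) understates observed identical fractions (~30 % in
re-cloning experiments), consistent with the effective error rate being
lower than the nominal one; the report surfaces both numbers rather than
reconciling them.

## Simulator: what it emulates, and what it does not

The generator's defaults encode the study regime: four taxa
((East,Hainan),(Central,septentrionalis)) with 7/4/3/4 individuals; a
stem lineage of 0.3 expected substitutions/site carrying two
translocations at stem fractions 0.7 (numt-1) and 1.0 (numt-2); taxon
branch lengths 0.006; numt rate factor 0.1; 10 mtDNA clones per
individual (the protocol picks 8–12 per fragment), each sampling one of
the individual's R2 size classes; deterministic numt clone counts per
individual (1 and 4, preserving the observed ~1:4 amplification
propensity of the two numt loci); minor-haplotype frequency 0.5 at 2
core sites in East/Hainan individuals only; size-class counts drawn with
weights fitted to the observed per-individual class counts
(1:0.25, 2:0.5, 3:0.15, 4:0.1); slippage of ±1 unit per event with a
geometric event count; Taq errors at 7.2 × 10⁻⁵/bp/cycle × 34 cycles on
every clone.  Placing both translocations high on the stem makes the two
numt clades mutually closer than either is to mtDNA — the qualitative
ordering observed in real data — while keeping all three clades
separable.

Substitutions are applied as Poisson event counts per branch with a 0.8
transition fraction (multiple hits allowed), which is what makes the K2P
correction meaningful.  Deliberate simplifications, and hence limits on
what passing tests show about real data:

* the core region evolves substitution-only — the 131 indels of the real
  alignment, and alignment error generally, are not modelled;
* the R2 array is inherited unchanged apart from slippage (no point
  mutations inside units along the tree), so motif-class turnover among
  taxa is not reproduced;
* the alignment records the R2 region as a left-justified, gap-padded
  block (numts all-gap) rather than per-unit homology columns — harmless
  here because that block is masked in every downstream computation;
* numts lose the array instantly at translocation (the simplest mechanism
  reproducing their observed lack of repeats) rather than decaying;
* no paternal-leakage scenario and no within-taxon population structure
  beyond one private-polymorphism draw per individual.

Per-individual truth flags are defined over the clones actually emitted
(≥ 2 distinct true core haplotypes, ≥ 2 distinct array lengths), so
sensitivity scoring is a property of each dataset, not of the unobserved
generating process.

## Problem sizes used in the test suite

The recovery study runs 20 seeded replicates of the default regime
(18 individuals, ~270 clones of ~600–720 bp each); the decomposer fuzz
property uses 500 arrays of up to 30 units; network enumeration checks
stop at 6 haplotypes, where spanning-tree enumeration is exact.  These
sizes keep the full suite under a minute while leaving every statistical
margin wide (clade recovery and verdicts were exact, and heteroplasmy
sensitivity ≈ 0.98, across all tested seeds).
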