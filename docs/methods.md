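# Methods

This note documents the models and conventions behind `camscan`: what each
statistic is, which knobs matter, what the synthetic generator does and
does not emulate, and where genuinely open design choices were resolved.

## Inputs and coordinates

The unit of analysis is a per-gene aligned CDS matrix over named strains
(FASTA, gap `-`, alphabet A/C/G/T/N), with a two-column strain table
assigning each strain to one of exactly two lineages. All reported
coordinates are 1-based closed intervals over alignment columns. Inputs are
assumed pre-aligned; the package never realigns.

## Consensus reference

Variants are called against the column-wise majority consensus of the
reference lineage (by default the lexicographically first lineage label,
mirroring the usual convention of scanning the larger or derived clade
against the other). Two deliberate choices:

- the gap character votes like any other symbol, so a lineage-wide
  deletion produces a gapped reference — required so that material present
  only in the query lineage polarises as an insertion;
- ties break by the fixed priority A < C < G < T < N < -. Any fixed order
  would do; fixing one makes runs reproducible. N is votable with lowest
  base priority because ambiguity should never displace an observed base.

Consensus is idempotent and, for an odd-sized reference clade, a single
strain's private mutation can never flip the consensus — which is what
makes the planted-truth oracle mapping (below) exact.

## Variant scanning

SNPs are per-(strain, column) mismatches where both sides hold an
unambiguous base; columns showing `-` or N on either side are skipped
(gaps belong to the INDEL caller; N carries no signal), but columns
adjacent to gaps are kept. Transitions are purine↔purine or
pyrimidine↔pyrimidine pairs; of the 12 ordered base pairs, 4 are
transitions, so an unbiased process gives ts/tv = 0.5.

INDELs are maximal runs of strain-gaps over reference bases (deletion,
sequence recorded from the reference) or reference-gaps over strain bases
(insertion, sequence from the carrier). Records identical in (start,
length, polarity, sequence) merge across strains into one record with the
union carrier set; insertions at the same spot with different sequences
never merge. Size classes split at 40 bp (small ≤ 40 < large), the
empirical boundary commonly used for coding-region INDEL surveys.

Summary conventions: category shares are percentages rounded half-up to
2 decimals; identity is the fraction of a category's records carried by
every member of the query lineage; divergence is Σ event length divided by
the total alignment column count — including gap columns, since the
alignment, not the ungapped reference, is the comparison frame. Both the
merged-record count and the carrier-expanded event count are reported,
because genome-scale tallies appear in both conventions and they differ by
roughly the mean carrier multiplicity.

## Codon statistics

All codon work uses translation table 11 (stops TAA/TAG/TGA). Following
standard practice for codon-usage indices, only CDSs strictly longer than
300 bp enter, with the terminal codon removed and tallied separately;
frame-broken copies (length ≢ 0 mod 3 — incomplete or pseudogenised genes
do occur in real panels) are kept but flagged, and codon counts floor to
whole codons.

- **RSCU**: observed count × family size / family total. An unused codon
  has RSCU 0 — the codon-aversion condition. Families with zero usage are
  flagged absent rather than treated as uniformly averse.
- **ENC**: Wright's estimator from mean per-family codon homozygosities
  F = (nΣp² − 1)/(n − 1), averaged within degeneracy classes (9 two-fold,
  Ile, 5 four-fold, Leu/Ser/Arg):
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.
  Families with n ≤ 1 (or F ≤ 0) are excluded from their class mean; a
  class with no estimable family is imputed at the uniform expectation 1/k
  and flagged — behaviour of legacy tools here is undocumented, and
  flagging keeps the imputation auditable. Values are clipped at 61
  (sampling noise can push the raw sum past the uniform ceiling); the
  formula cannot go below 20.
- **PR2**: x = G₃/(G₃+C₃), y = A₃/(A₃+T₃). Default accumulation is over
  the five four-fold families only, where third-position changes are
  strictly synonymous and the (0.5, 0.5) point is the exact
  mutation–selection balance; `fourfold_only=False` restores the
  all-codon variant some scripts use. Zero denominators flag the point
  undefined rather than guessing.
- **SVCs**: computed from *count-pooled* group RSCU (summing codon counts
  across a lineage's strains), not from averaged per-strain RSCU —
  pooling matches consensus-sequence usage and is robust for short genes.
  The boundary RSCU = 1 counts as unpreferred. Single-codon families
  (Met, Trp) are excluded from RSCU-preference reporting, SVCs and CAMs:
  their relative usage is constant by construction.
- **ENC group test**: a two-sided F-test on the two lineages' ENC
  variances at α = 0.05 selects between the pooled-variance and Welch
  t-tests (both two-sided); significance tiers are reported as > 0.05,
  < 0.05, < 0.01. Degenerate zero-variance-in-both cases resolve by
  convention (equal means → p = 1, distinct → p = 0), which agrees with
  the limit of the pooled test. With groups of 3 and 4 the test is
  correctly calibrated: the acceptance script measures a type-I error of
  ≈ 0.05 over 10⁴ null replicates.

## Codon aversion motifs and the identification map

A motif is the sorted tuple of sense codons with zero count (59
reportable codons; sortedness gives canonical set equality, since no
natural ordering exists). Motifs shrink monotonically as usage is added.

A gene is *lineage-diagnostic* when its motif-value sets for the two
lineages are disjoint — a motif observed in both lineages, including the
empty motif, disqualifies it. Disjointness (rather than "different
multisets") is the reading that guarantees error-free lineage assignment
of unseen strains.

The identification map is built greedily: at each node, among genes not
used on the path, pick the one whose motif-equality partition of the
node's strains has the most blocks; break ties by fewest total motif
codons over the node's strains, then lexicographic gene id — and *record*
the tied alternatives, since real data typically admits several equally
valid pathways. With `lineage_first` the root is restricted to
lineage-diagnostic genes when any exist. Strains that no gene separates
end in a flagged non-separable leaf. Greedy construction provably reaches
the finest achievable partition (two strains are separable iff they
differ in some gene, and any distinguishing gene used on their common
path splits them), which the tests verify against exhaustive search on
small instances. Query descent returns the leaf strain, or on a novel
motif / missing gene the remaining candidate set — never a silent wrong
answer.

## The synthetic generator

`SimConfig` defaults encode the emulated study conditions: 40 genes of
300–3300 nt (multiples of 3), target GC 0.34, clades of 3 + 4 strains on
((a1,a2,a3),(b1,b2,b3,b4)), tip substitution rate 0.002/site with stem
branches at 30×, κ = 3, INDEL rate 1e-5/site/tip-branch with 85%
multiple-of-three lengths (small lengths geometric, p = 0.5, capped at
40; large events with probability 0.08, uniform over 41–120), seed 42.
The stem-heavy rates put within-clade identity near 99% and between-clade
identity in the mid-80s, per-strain-per-gene SNP density against the
other lineage's consensus around 0.12–0.14/site, and about one merged
INDEL record per gene alignment — the density regime of the real panels
this emulates. κ = 3 gives an expected transition fraction
κ/(κ+2) = 0.6, i.e. per-gene ts/tv centred near 3.

Ancestral CDSs start with ATG, end with a random stop and contain no
internal stops; internal codons are drawn base-wise at a GC adjusted (by
bisection on the closed-form expectation) so that stop-codon rejection
still lands the target composition, within ±0.03 for panels of ≥ 20
genes.

Evolution is event-sourced: node states are (column-id, base) lists;
insertions allocate fresh column ids spliced into a master order, and the
emitted alignment is the true one — no realigner, because the scanners
are under test, not an aligner. Three simplifications are deliberate:

- substitutions hit only ancestral (non-inserted) columns;
- all event footprints are pairwise disjoint with one column of padding,
  enforced by rejection sampling (events that cannot be placed after 50
  tries are dropped, not recorded);
- insertions tandem-copy the sequence immediately to their left, and
  INDELs avoid the first and last codon so start/stop validation stays
  clean.

Disjointness is what makes the truth channel exactly invertible: every
recorded event survives verbatim into the alignment, replaying the event
log against the ancestor reproduces each row byte-for-byte, and
`expected_variants` can translate the log into the exact calls a
consensus-reference scan must produce (query-side events verbatim,
reference-stem events with flipped polarity, reference-minority events
absorbed by the majority consensus). The acceptance script verifies 100%
recovery with zero spurious calls on ~19,000 events.

Codon aversions are planted by synonymously recoding every occurrence of
a codon in the target strains (same protein, table 11), logging both the
base edits and the aversion marker.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment error and gap ambiguity (real INDEL
calls depend on aligner choices; ours are exact by construction),
overlapping or recurrent mutations at one site, rate heterogeneity across
sites and genes, selection shaping codon usage (simulated genes are
near-uniform users, so simulated ENC sits near 55 while biased real genes
run 37–50), AT-biased mutation (the K80-like process drifts composition
toward GC 0.5, adding ~1 percentage point of GC per default run), and
recombination or gene-specific trees.

## Numerical conventions

Percentages and reported reals round half-up (ENC and PR2 to 2 decimals,
GC% to 2 decimals, shares to 2 decimals); ts/tv with zero transversions
reports infinity, with no substitutions at all NaN; undefined statistics
(empty categories, zero denominators) are flagged, never silently zeroed.
Every stochastic routine takes an explicit generator; the CLI defaults to
seed 42. Reports embed the seed, the scientific configuration and its
hash (the output directory is excluded as non-scientific), making a run
reproducible from its own provenance block; identical configuration and
seed produce byte-identical reports.

Problem sizes used by the validation suite — 50-gene panels for scanner
recovery, ~10⁴ planted substitutions and ~10³ INDELs for parameter
recovery, 10⁴ replicates for test calibration, 9-gene planted panels for
the identification map — were chosen as the smallest sizes at which the
binomial error bands make the checks sharp.

## Known limitations

- INDEL sharing requires exact (start, length, polarity, sequence)
  equality; near-identical events separated by alignment jitter in real
  data would not merge. No left-normalisation is attempted.
- The ENC missing-class imputation and the 1/k convention are one
  defensible choice among several; flagged values should be filtered
  before fine-grained ENC comparisons.
- The identification map is only as stable as the motif table: motifs
  from genes near the 300 bp eligibility boundary are noisy, and novel
  strains with unseen motifs resolve to candidate sets, not strains.
- `expected_variants`' oracle mapping assumes an odd-sized reference
  clade (≥ 3) so private mutations cannot flip the consensus.
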