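# Methods

## Coordinate and sequence conventions

All intervals are 0-based half-open on the forward strand; minus-strand
features carry forward-strand coordinates plus a strand flag, and conversion
to the 1-based stranded convention of BLAST tables happens only at I/O
boundaries. Translation uses the bacterial/archaeal code (NCBI table 11).
An accepted alternative start codon (ATG, CTG, GTG, TTG, ATT, ATC) renders
Met when it is the first codon of a reported ORF. Only `N` is accepted as an
ambiguity code: a codon containing `N` translates to `X` and is treated as
neither start nor stop — conservative and deterministic. Other IUPAC
degenerate bases are rejected at parse time.

## Hit-anchored ORF calling

For each homology hit the caller scans a window `flank_nt` (default 500 nt)
either side of the hit interval, clipped to the record, **in the hit's frame
and strand only**. The retention rule requires the ORF to reproduce hit
residues with an identical translation, so an ORF in any other frame scores
zero coverage; restricting the scan changes nothing and does 6× less work.

Within the window, stop codons and the window edges delimit segments; each
segment yields at most one ORF, from its first accepted start codon to the
delimiting stop (the stop codon is included in the interval and
`min_orf_nt` = 300 nt is measured on that interval, i.e. ~100 codons
including the stop). Two deliberately configurable edge policies:

* the window edge is treated like a sequence edge (`window_bounded=True`,
  default): an ORF may begin or end at the window boundary without a
  start/stop codon;
* a 5′-edge segment with no start codon at all still yields an ORF with
  `has_start_codon=False` (`allow_edge_start=True`, default) — edge-truncated
  genes on contig ends are real and would otherwise vanish.

Hit coverage is the fraction of (degapped) subject residues whose codon lies
inside the ORF, in its frame, and whose **raw table-11 translation** of the
genomic codon equals the subject residue; `X` never counts as identical.
The raw translation (start codon *not* forced to Met) is used because the
subject protein in a tblastn row is itself a raw translation — forcing Met
would fabricate a mismatch at CTG/GTG starts. Hits with an empty or
non-codon-tiling (gapped) subject protein fall back to the in-frame
nucleotide-overlap fraction. The qualifying ORF (length ≥ 300 nt, coverage
≥ 0.5, both boundaries inclusive on their stated sides) of maximal length is
returned; segment disjointness makes the maximum essentially unique, and a
residual tie is broken toward the smaller start coordinate.

## Profile HMM

The scorer is a minimal local-alignment profile HMM chosen so that an
exhaustive path-enumeration oracle can verify it: begin → M_j entry uniform
over the L match states; per column match/insert/delete states with
transitions from {M_j, I_j, D_j} to {M_{j+1}, I_j, D_{j+1}}; exit permitted
from every match state at no cost. Scores are log2-odds against a
background null; flanking residues are null-emitted. All accumulation is in
log2 space (`logaddexp2`), underflow-safe. Forward sums paths, viterbi
maximizes; forward ≥ viterbi always. One nuance: appending background
residues leaves the viterbi score exactly unchanged (the optimal path
ignores them) but moves the forward score by the tiny extra mass of
alignments absorbing the flank — millibits on realistic models, bounded but
not zero.

`build_profile` estimates a model from an aligned seed set: columns with gap
fraction < 0.5 become match states; match emissions are counts plus
background-proportional pseudocounts (weight 1.0); transitions are counted
from each row's local state path (first to last match) with +1 smoothing;
the background is uniform (1/20) by default. Identical inputs give
byte-identical serialized models (a plain-text JSON schema, round-tripping
probabilities to < 1e-12).

### Thresholds

Retention follows the distant-reference principle: a model's cutoff is the
score of a sequence from a cluster only distantly related to the family, and
retention is inclusive (score ≥ cutoff). The published constants (KS 352,
CLF 66) are meaningful **only under the external HMMER scorer** and are
applied verbatim only in external-adapter mode (`PyhmmerScorer`). The
builtin scorer has its own bit scale and always calibrates via
`calibrate_threshold` on a user-supplied cutoff protein. Classification
scores a protein against both models; candidates are models whose threshold
is met; ties between qualifying KS and CLF scores resolve deterministically
to KS (logged).

## Pairing and regions

Intergenic distance is measured between the closest interval ends;
overlapping or abutting genes have distance 0 and pass the filter — the only
reading under which "overlapping matches pass" is natural. "Over 2 kb
removed" is strict (gap 2000 kept, 2001 removed); "less than 6 kb" is strict
(5999 kept, 6000 removed). Strand concordance is *not* required — divergent
and convergent KS/CLF orientations are recorded but never filtered. Pairing
is an unrestricted many-to-many product, so the pair count can exceed the
count of distinct KS or CLF genes.

Regions extend each pair's bounding footprint by 30 kb per side, clip at
record edges, and merge overlapping extensions (pairs up to 60 kb apart
merge). A `pair-distance` merge rule is available that instead keeps pairs
more than 30 kb apart in separate regions — the two rules differ exactly for
pairs 30–60 kb apart; the extended-overlap rule is the default because it is
the stated merge procedure. Region categorization consumes annotation
tokens: KS_CLF needs ≥1 `t2ks` and ≥1 `t2clf`, KS_FAS ≥1 `t2ks` and ≥1
`t2fas`, FAS_FAS ≥2 `t2fas`; categories are non-exclusive and the empty set
is valid; unknown tokens warn and are ignored.

## Phylogeny preparation

Gap-column trimming keeps a column iff its gap fraction is ≤ 0.05 ("more
than 5 %" is exclusive: exactly 5 % stays), counting every row including
fully gapped ones, and returns the kept-column index map. Support collapse
contracts internal edges whose child support is < 0.70 (strict), reattaching
children to the grandparent with the contracted edge's length added, so leaf
sets and root-to-leaf path lengths are preserved and the operation is
idempotent. Support values are read from internal node labels (the FastTree
dialect; bracket-comment supports are rewritten on read); `auto` scale
detection maps values > 1 to the percent scale. Nodes without a support
value are kept by default (with a warning); `zero` and `error` policies are
available, since the correct treatment is genuinely ambiguous. Outgroup
rooting splits the outgroup leaf's edge at its midpoint; if the tree is
already rooted with the outgroup as one of two root children it is returned
unchanged, which is what makes rerooting idempotent (a second midpoint split
would halve the leaf edge again). Trees are dendropy objects throughout.

## Synthetic data

The generator emulates the genomic structure the pairing stage assumes —
and only that. A contig is i.i.d. background at a chosen GC fraction
(default 0.55, a typical actinobacterial neighbourhood) into which genes are
planted as `start codon + reverse-translated body + stop codon`, preceded on
the coding strand by an in-frame stop codon anchoring the 5′ boundary (real
genes are preceded by in-frame stops; without the anchor the
first-start-after-a-stop rule may legitimately extend an ORF upstream into
background, and exact coordinate comparison against truth would be
meaningless). Reverse translation draws synonymous codons uniformly and can
produce no in-frame stops by construction. All randomness flows from one
spec seed through named substreams, so fixtures are bit-stable.

The toy families are three independent random consensus sequences of 150
residues (KS, CLF and a FAS-like decoy family), each with a 30-row seed
alignment at 10 % per-copy substitution. Cutoff proteins for KS and CLF are
the consensus at 45 % divergence — distant enough to score far below any
family member yet far above unrelated-sequence noise (on the builtin scale:
noise ≈ 10, cutoffs ≈ 87/119, weakest family samples ≈ 300 bits), the
qualitative ordering the aurachin-style calibration assumes. The default
scenario is one 20 kb contig with three KS–CLF pairs at gaps 200/900/1800 nt
(mixed strands, mixed start codons) and two decoys, each gene receiving one
simulated hit covering its central 80 % of codons with an exactly identical
subject translation at e-value 1e-50.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: evolutionary substitution/indel structure
within families (samples come from the profile itself), gapped or partial
BLAST alignments, sequencing errors and ambiguity codes, compositional bias
and repeats, overlapping genes, and realistic hit e-value distributions.
Recovery being exact here demonstrates the machinery's correctness, not the
sensitivity of the published models on real genomes.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice: 500
random ≤3 kb windows for the ORF oracle, exhaustive HMM path enumeration at
L ≤ 3 × sequence ≤ 5 over a 4-letter alphabet, 200 samples per family for
classification recovery, and five 20 kb contigs for end-to-end recovery.
These sizes exercise every boundary of every rule; the statistics they
produce are properties of the algorithms, not estimates of database-scale
yields.
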