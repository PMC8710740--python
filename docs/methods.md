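# Methods

This note records the models, conventions and numerical choices behind
`plastevo`, in the order data flows through the pipeline.

## Coordinates and the size partition

All intervals are 0-based half-open internally; GenBank's 1-based closed
convention is converted exactly at file boundaries, and features spanning
the circular origin are stored as two intervals. "Coding" means
protein-coding CDS only: the non-coding bucket holds tRNA, rRNA, introns,
intergenic spacers and pseudogenes, so `total = coding + noncoding` is an
identity, enforced at construction of every size record. Overlapping CDS
intervals are counted as a positional union (each genomic position counts
once); whether overlapping reading frames should be double-counted is a
genuinely open convention, and the union is the choice made here. A feature
is a pseudogene when its GenBank entry carries a `pseudo`/`pseudogene`
qualifier. Sequences may contain N; any other ambiguity code is rejected at
read time because the repeat detector assumes a five-letter alphabet.
Reported clade means are rounded half-up to the nearest bp (the convention
of printed size tables); raw means are kept alongside.

## Quadripartite detection

The structure is found de novo as the maximal pair of disjoint,
non-adjacent segments where one equals the reverse complement of the other.
Matching is exact (v1): plastome IR copies are homogenized by gene
conversion and are near-identical in practice, and exactness keeps the
result checkable against an exhaustive all-pairs oracle. The search is
seed-and-extend on k-mers (k = min(15, min_ir_len)) of the reverse
complement, run on the doubled sequence so repeats spanning the circular
origin are found; maximal extensions are deduplicated by their
anti-diagonal invariant, and the same circular pair found from both copies
is collapsed. Ties between equally long pairs break to the leftmost start
and are logged. The longer single-copy gap is labelled LSC, the circle is
rotated so LSC starts at position 0, and IRb is the copy first encountered
from the LSC start.

`min_ir_len` defaults to 1,000 bp — far below real plastome IRs (≥ 20 kb in
Triticeae) but high enough to exclude chance repeats; tests and the
scaled-down simulations override it (100–300 bp).

Junction distances are measured from the nearest feature *edge* to the
junction, 0 when abutting; a distance-to-gene-start convention would differ
for genes oriented away from the junction, and the nearest-edge choice is
flagged here because published junction figures rarely state theirs. A
feature whose interval contains a junction is reported with its bp split
across the two regions.

## Indel events

An event is a maximal run of contiguous alignment columns with an identical
taxon gap-presence pattern. This matches how discrete deletions are
described ("a 529-bp deletion between petN and trnC"), makes counts
invariant to alignment length, and lets adjacent events with different
taxon sets stay distinct. All-gap and gap-free columns yield nothing.

Placement treats gap presence as a binary character on the rooted tree.
Fitch parsimony (down-pass state sets, up-pass resolution) yields the
branches requiring a change; an ambiguous root set is resolved to the
outgroup's observed state. Polarity is read from the resolved root:
ancestral base → deletion, ancestral gap → insertion. When several branches
change (homoplasy), all are listed and the preorder-first is marked
primary; this tie-break is deterministic and logged per event. Exhaustive
enumeration on small trees confirms both the change count and the chosen
branch set are minimum-change.

Region classification maps the event through the reference row of the
alignment (gapped reference columns fall back to the nearest mapped column
to the left, with a warning). Events inside either IR copy are classed
`ir`; elsewhere an overlapping feature decides (CDS > intron > pseudogene),
and intergenic events are `igs` with the flanking gene pair named. The
reference taxon defaults to the first alignment row and should be a genome
that retains the loci of interest — configurable because the natural
reference (a well-annotated genome) may itself carry clade deletions.

Per-node counts are **clade-cumulative**: a node's count is the number of
events whose primary branch lies strictly within the clade it subtends, so
counts grow monotonically toward the root and the root carries the total.
This convention is chosen because published per-node indel tables increase
toward the root; the per-branch event table is always emitted so any other
counting rule can be recomputed from it.

The sliding-window identity scan (default 600 bp window, 200 bp step)
averages pairwise identity over columns where both sequences have a base;
N matches nothing, and columns with more than 50% gaps (configurable) are
excluded.

## Ancestral reconstruction

Weighted squared-change parsimony minimizes Σ (Δx)²/b over branches
(weight 1/b per branch of length b, the Maddison formulation implemented by
the classic Mesquite ancestral-states module); unweighted mode sets b ≡ 1.
At the optimum each internal value is the weight-averaged value of its
neighbours, giving a symmetric positive-definite sparse linear system
solved directly (`scipy.sparse.linalg.spsolve`) — deterministic and exact
to solver precision, no iteration or initialization. Zero-length branches
are replaced by ε = 1e-9 × tree height (logged); negative lengths are
errors. Reconstructed values provably lie within the tip range (the
objective is convex and coordinate-wise monotone), and with time branch
lengths the weighted optimum equals the Brownian-motion ML ancestral state,
which is why root error shrinks with the BM rate and vanishes at rate 0.
Both time-calibrated and substitution-length trees are accepted; results
are reported per input tree, not mixed.

## Statistics

Correlations use scipy: Spearman on mid-ranks with the t-approximation on
n − 2 df, Pearson product-moment. Pairs with missing values are dropped
(the packaged node table has two nodes without indel counts, leaving
n = 31). The replication path reports Pearson R for node age vs cumulative
indel count, and for node genome size vs the per-MY indel accumulation
rate (count divided by node age) — normalizing by age removes the dominant
age dependence before asking whether larger genomes accumulate events
faster; Spearman analogues are attached for rank-based sensitivity.
Kruskal–Wallis is tie-corrected with the χ² approximation (df = k − 1);
pairwise follow-ups are two-sided Mann–Whitney rank-sum tests with Holm
adjustment — the adjustment choice is recorded in output metadata since
boxplot-style significance stars rarely name one.

## Synthetic data

The generator's purpose is ground truth: every emitted file is derived
from a known evolutionary history, so recovery can be checked event by
event.

- **Template.** A scaled-down quadripartite genome (12.1 kb LSC / 2.3 kb
  IR / 1.35 kb SSC, ~10× below real size so tests run in seconds) with a
  Triticeae-style layout of ~55 named genes (petN, trnC, psbE, petL, trnT,
  trnE, ycf2, ycf15, rpl23, accD, rps19, ndhH, …), including an
  rps19 ending 36 bp before JLB and an ndhH spanning JSA (40 bp SSC / 260
  bp IRa) to exercise the junction-geometry code. IRa sequence and
  annotation are derived from IRb.
- **Tree.** The preset phylogeny has the 33 ingroup taxa of the packaged
  size table in four clades plus an outgroup, ultrametric in MY with crown
  age 27.63 and clade crown ages 12.71 / 12.62 / 17.16 / 15.09 (clades
  I–IV); within-clade topology is pectinate with evenly spaced ages — the
  statistics depend on clade membership and ages, not on within-clade
  shape.
- **Evolution.** Homology is tracked by column identity: deletions remove
  columns, insertions splice fresh columns into a master order, so the
  *true alignment* is emitted directly and no aligner runs in the test
  path. Substitutions are uniform (Jukes–Cantor-style) at `subst_rate`
  (default 0.001 subs/site/MY, plastome-typical); stochastic indels arrive
  as a Poisson process at `indel_rate` (default 2 events/branch/MY) with
  geometric lengths (p = 0.2, mean 5 bp — plastome indels are mostly
  short). Planted events are deterministic deletions centred in a named
  spacer on a named branch; stochastic indels re-draw positions that would
  collide with a planted locus so the diagnostic patterns stay clean. IR
  changes are mirrored into both copies (emulating gene conversion), so an
  IR deletion shortens the genome by twice its length and appears as two
  gap runs in the alignment — the pipeline accordingly calls the planted
  800 bp IR deletion once per copy.
- **Determinism.** One `numpy` generator seeded from the config drives
  everything; identical config + seed give byte-identical output files.

What the generator does *not* emulate: rate heterogeneity (GTR+Γ),
codon-aware evolution, tandem-repeat slippage, rearrangements/inversions,
and alignment error (the truth alignment sidesteps MAFFT entirely).
Passing recovery tests therefore demonstrate correctness of the calling,
placement and reconstruction machinery under known homology — not
robustness to misalignment or to mutation processes beyond the model
above.

## Problem sizes and tolerances

Oracle checks run at sizes where exhaustive computation is feasible and
fast: 50 random ~2 kb genomes for the repeat DP, trees of ≤ 8 tips for
Fitch enumeration, 20 random 6-tip trees for the squared-change optimizer
comparison (agreement to 1e-8 relative), 100 Brownian replicates per rate
for root-recovery error, and 200 replicates for the Poisson event-count
check (3 standard errors). The σ² = 0 root reconstruction is exact to
direct-solver precision (~1e-10 on a 136 kb trait value).

## Known limitations

- Exact-match IR cores only; a mismatch-tolerant extension is stubbed but
  not implemented, so heavily diverged IR pairs (rare in grasses) would go
  undetected.
- Fitch placement reports the branch set of one canonical
  most-parsimonious reconstruction (outgroup-anchored, ancestral-state
  preference); the full MPR set is not enumerated for large trees.
- Region classification uses a single reference genome; events falling in
  loci absent from the reference inherit the nearest mapped column's
  class.
- Linear plastomes and de novo annotation are out of scope; features are
  read from the GenBank record as given.
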