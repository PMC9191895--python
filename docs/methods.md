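# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical conventions that make every run reproducible.

## Sequence search

**Pairwise alignment.** Local alignment is exact Smith–Waterman with
affine gaps (three-state dynamic programming), BLOSUM62 scores, gap open
−11 and gap extend −1 per residue. Traceback is deterministic with tie
order diagonal > up > left. Percent identity is identical columns over
alignment columns — the quantity thresholded when building similarity
networks. An `X` (or `N` in DNA) scores as background everywhere.

**Profiles.** A family profile is a per-column log₂-odds matrix over the
20 residues, built from a progressive multiple alignment with
pseudocounts: `p_c = (count_c + α·b_c)/(n + α)` with α = 1 and a uniform
background b = 0.05. Columns with non-gap occupancy below 50% are not
match columns and are dropped. This is a PSSM with affine gap penalties
(−4 bits open, −0.5 bits extend), not a full profile HMM: at the scale
this package targets the two recruit the same members, and the PSSM
keeps every score exactly reproducible. This is the main fidelity gap
relative to the HMM-based tools the pipeline stands in for.

**E-values.** Null scores come from scoring the profile against
residue-shuffled database sequences (default 200 shuffles); a Gumbel
tail is fitted by method of moments (λ = π/(σ√6), μ = m − γ/λ with the
Euler–Mascheroni constant γ), and `E(s) = N · P(S ≥ s)`. E-values are
exactly proportional to the database size N and monotone decreasing in
the score. The method-of-moments fit is approximate in the extreme tail:
across seeds, the observed count of null targets at E ≤ 1 in a database
of 500 ranges over roughly 0–4 with a mean near 1.4 (the calibrated
nominal is 1). A maximum-likelihood or censored-tail fit would tighten
this; it has not been needed for family recruitment, where inclusion
thresholds sit many orders of magnitude below 1.

**Iterative search.** Round 1 recruits by pairwise alignment from the
seeds (identity ≥ 20%, raw score ≥ 50). Each later round realigns the
included set, rebuilds and recalibrates the profile, re-searches, and
includes targets at E ≤ 1e−5 (peptide preset; 1e−10 for receptors). The
included set grows monotonically; the loop stops at a fixpoint or after
5 rounds. The published workflow does not state an iteration count or
convergence rule; fixpoint-or-5 is this package's choice.

## Similarity network and communities

Edges connect candidate pairs with local percent identity strictly above
the threshold (20% peptides / 50% receptors), weighted by that identity.
Edges additionally require a raw alignment score ≥ 50: the published
network was built from search hits that had already passed an E-value
cutoff, and without a significance gate short spurious local alignments
between unrelated proteins would satisfy a bare identity threshold.

Communities are found by standard two-phase Louvain on weighted
modularity `Q = Σ_c [S_in,c/(2m) − (S_tot,c/(2m))²]`. Node order in the
local-move phase is a seeded shuffle, making runs deterministic under
`rng_seed`; the reported Q always equals an independent recomputation,
and the per-pass Q trace is non-decreasing. Only communities containing
at least one seed survive. On random graphs of ≤ 8 nodes Louvain matches
exhaustive partition enumeration in ≥ 90% of instances and never exceeds
the true optimum.

## Genomic rescue

Both genome strands are translated in all three frames; ORFs run from
the first ATG after a stop through the stop codon, bounded to 25–400
residues (wide enough for any precursor the peptide route considers).
ORF proteins are scored against the family profile with E-values
calibrated on the shuffled ORF set; hits overlapping any annotated
feature by ≥ 1 bp on either strand are discarded (conservative masking),
and survivors become de-novo records carrying genomic coordinates and
strand. Gene structure is intron-free by construction in the benchmark,
so ORF extraction replaces de-novo gene prediction; spliced genes in
real genomes would need a gene finder in this slot.

## Filters and domain callers

* Length bounds are inclusive: "maximum 300" keeps length 300,
  "minimum 500" keeps length 500. The screen bound "< 150" is strict.
* The cysteine-spacing filter accepts a protein iff two cysteines occur
  with 9–11 residues strictly between them (equivalently the regex
  `C[^C]{9,11}C`). Counting the spacing inclusive of the cysteines is
  the other defensible reading of "9–11 amino acid spacing"; the bounds
  are parameters, so that convention is `min_gap=7, max_gap=9`.
* The signal-peptide caller is a transparent rule: ≥ 1 K/R in the first
  five residues, an 8-residue window of mean Kyte–Doolittle hydropathy
  ≥ 1.8 within the first 30, and cleavage at the first post-core
  position with small residues (A,G,S,C,T,V) at −3 and −1. The TM caller
  slides a 19-residue window at mean hydropathy ≥ 1.6, merges
  overlapping calls, trims hydrophilic window smear at the ends, and
  labels non-TM spans alternately extracellular/intracellular assuming
  type-I topology (N-terminus outside after the SP). The kinase caller
  requires ≥ 3 of the ordered motifs GxGxxG, K (within 30 residues),
  HRD, DFG (within 60 of HRD); the LRR caller matches the consensus
  LxxLxLxxNxL requiring all five conserved positions (four aliphatic
  L/I/V/F slots and the N) and selects non-overlapping windows greedily.
  These are stand-ins for the dedicated predictors practitioners use on
  real data; no fidelity to their probability outputs is claimed, and
  their thresholds are package constants.
* The confident set is the relaxed set passing the cysteine filter minus
  an explicit, logged exclusion list — the reproducible surrogate for
  manual alignment curation, which is inherently irreproducible.

## Phylogeny

Distances are p-distances with pairwise gap deletion, optionally
Poisson-corrected (d = −ln(1−p), capped at 10 when saturated). Trees are
canonical Saitou–Nei neighbor joining: Q-criterion pair choice with
lexicographic tie-breaks, negative branch lengths clamped to zero with
the subtraction shifted to the sister branch. NJ is exact on additive
matrices, which is the module's primary oracle. This replaces
approximate-ML tree building used on real data; for the clade-level
questions the pipeline answers, distance trees are sufficient and
exactly testable.

Rooting inserts the root at the midpoint of the outgroup's pendant edge,
or at the midpoint of the longest leaf-to-leaf path; pairwise path
lengths are preserved. A node's *age* is its maximum branch-length path
to a descendant leaf; clades at cutoff c are the maximal nodes with age
≤ c, which always partition the leaves, and raising c only merges
clades. The age cutoffs 9 (peptides) and 5.5 (receptors) are carried as
presets; their original units depend on the branch lengths of the tool
that produced them, so with NJ Poisson branch lengths they are
operational parameters, not calibrated constants.

Bootstrap support resamples alignment columns with replacement (no
realignment), rebuilds the NJ tree, and reports the fraction of
replicates containing each internal bipartition of the reference tree;
1000 replicates by default, deterministic under the seed.

Sequence logos drop columns whose non-gap occupancy is strictly below 5%
and report per-column residue frequencies with information content
IC = log₂20 − H bits.

## Synthetic benchmark

The generator plants a star-evolving family: one ancestor, every member
an independently substituted copy (default 10% per site, no indels so
mature-region coordinates stay aligned; an indel mode is deliberately
absent from the default model). Default conditions: 8 species × 3
members, precursor 60–120 residues, signal peptide 25 residues, one
C-x(9–11)-C pair in the C-terminal half, 25% of members absent from
proteome and annotations (a global quota spread round-robin across
species, so the realised fraction equals the nominal one), 40 decoys per
species (40–140 residues, scrubbed of any 9–11-spaced cysteine pair),
expression log₂FC ~ N(4, 0.5) for family transcripts and N(0, 0.5) for
decoys — about 5σ of separation, matching a strongly induced family.
CDSs are reverse-translated with uniform synonymous codons, embedded in
random background DNA behind an in-frame stop so each ORF coincides with
its coding interval, half on the minus strand.

Two constructions are engineered to the package's own callers: the
signal peptide (M + basic + hydrophobic LIF core + A-S-A cleavage
cassette, with class-preserving mutation so the call and cleavage
position survive divergence) and the receptor architecture (exact LRR
consensus positions and kinase motif anchors are never mutated). This
makes recall on planted truth exactly 100% by construction — that is the
point: the benchmark tests the pipeline's bookkeeping, thresholds,
coordinates and statistics, not the biological accuracy of the
rule-based callers. Passing it therefore demonstrates correctness of the
machinery, and says nothing about SP/TM/LRR sensitivity on real
proteins, about intron-containing genes, codon bias, transposons, or
non-star family evolution.

## Problem sizes and determinism

The standard benchmark (338 proteins, 8 genomes of ~3 kb, 108 receptor
candidates) runs the full peptide route in a few seconds and the
acceptance script in well under a minute on one core; these sizes were
chosen so that the planted family separates cleanly from decoys with
about 5σ of expression contrast while keeping exhaustive oracles
(brute-force partition enumeration, reference DP, regex) affordable.
Every source of randomness flows from explicit integer seeds; rerunning
with the same manifest reproduces outputs byte-identically. Dynamic
programming kernels are numba-compiled; results do not depend on the
compilation.
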