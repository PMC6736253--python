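# Methods

## Model and procedure

**Single-gain (Dollo) reconstruction.**  A domain family's
presence/absence profile over the leaves of a rooted binary species
tree is explained by a history with exactly one gain and any number of
subsequent losses; regain is forbidden.  The loss-minimising history is
unique: the gain sits at the MRCA of the present leaves, and a node
inside the gain subtree is present iff at least one of its descendant
leaves is present.  Losses are attributed to the child node of each
present→absent branch.  Leaves outside the gain subtree are *pre-gain*
and yield no absence calls.  For profiles that satisfy the ancestral
(LECA) criteria — presence in ≥ 3 supergroups and on both sides of the
root — the gain necessarily falls at the root, so the gain-placement
convention only matters for non-ancestral families.  All-absent
profiles are rejected (no gain is placeable); they indicate an upstream
filtering bug rather than data.

**Absence classes.**  Inside the gain subtree, an absent leaf is
*clade-specific* when its parent node is reconstructed absent (the
absence is phylogenetically supported by an ancestral loss) and
*species-specific* when the parent is present (a terminal-branch loss
contradicted by every sister taxon).  The two classes partition the
absences exactly.

**Horizontal-transfer screen.**  Naive single-gain reconstruction
mistakes independent prokaryote-to-eukaryote transfers on both root
sides for ancestral presence.  The screen consumes externally inferred
per-family gene trees (tree inference, alignment and trimming are
explicitly inputs, not part of this package).  Eukaryotic sequence sets
are first reduced to cross-root bidirectional best hits (mutual
best-scoring pairs between the two root sides; ties broken
lexicographically).  In each gene tree every *maximal* monophyletic
all-eukaryote clade is tested: species from both root sides must be
present, and the mean of five supergroup presence percentages (distinct
species with a homolog in the clade — including unsampled sequences
assigned to their best-scoring tree leaf — over the supergroup's total
species count) must be ≥ 15% (inclusive).  One qualifying clade
anywhere in the tree accepts the family; otherwise it is flagged and
excluded from the strict ancestral set.  Maximality prevents nested
sub-clades from being counted repeatedly.

**Verification and correction.**  Absences of ancestral families are
re-searched in six-frame translated genomes.  Candidate hits pass the
same chain as proteome hits: per-family bitscore cutoff (inclusive ≥,
gathering-cutoff semantics; a missing cutoff is an error, never a
silent keep) and greedy best-scoring non-overlapping selection.
Overlap is judged per family in forward-strand genomic coordinates
across frames and strands — two frames over one locus are a single
biological signal — with deterministic tie-breaks (higher score, then
smaller start, then target id).  A hit whose aligned translation
contains `*` anywhere in the envelope is a pseudogene; pseudogene-only
absences stay absent.  An absence with ≥ 1 clean hit is *found* and is
flipped to present; the reconstruction is then re-run per family with
the ancestral set frozen from the uncorrected analysis.  Flipping a
species-specific absence always removes exactly one loss; flipping a
clade-specific absence can leave the count unchanged (cherry) or raise
it (an ancestral loss fragments into shallower ones), never lower it —
this asymmetry is why species-specific false absences dominate the
correction.

## Six-frame translation

Frames are labelled +1..+3/−1..−3 with the offset applied at the 5′ end
of the respective strand (transeq convention); reverse frames translate
the reverse complement.  Trailing nucleotides that do not fill a codon
are dropped, never padded.  Codons containing `N` translate to `X`,
which the pseudogene filter never treats as a stop.  Any NCBI
translation table known to Biopython is accepted; tables 1 (standard)
and 6 (ciliate nuclear, TAA/TAG → Q) are the ones exercised.  The
sequence alphabet is restricted to `A,C,G,T,N`.  Peptide↔genome
coordinate mapping is 0-based half-open everywhere inside the package;
1-based inclusive coordinates exist only at the HMMER-format parsing
boundary.

## The toy detector

The built-in detector stands in for a profile search so the pipeline is
self-contained: a family is a consensus peptide, and a hit is a target
window matching it with at most `max_mismatches` substitutions, scored
`length − 2·mismatches`.  Target positions showing `*` or `X` are
tolerated rather than counted as mismatches — a profile search aligns
straight through in-frame stops, which is exactly what makes pseudogene
copies detectable (and then flaggable) in translated DNA.  Candidate
windows are located by a pigeonhole anchor scheme (split the consensus
into `max_mismatches + 2` chunks; any admissible window with at most
one tolerated stop leaves one chunk intact for a C-speed exact search)
and verified per position; very short consensus peptides fall back to a
brute-force scan.  Default score cutoffs equal the consensus length, so
exact copies (including stop-tolerated pseudogene copies) pass and
degraded matches do not.

## Synthetic data: what it emulates and what it does not

The generator reproduces the causal structure the analysis assumes:

* a rooted binary species tree whose leaves are partitioned into
  monophyletic supergroup clades distributed over both root sides
  (defaults: 50 species, 6 supergroups);
* domain families gained at the root and lost independently on each
  branch with probability `p_loss_per_branch` (default 0.05); a
  gain-at-random-node mode exists to exercise pre-gain handling;
* per truly-present cell, one uniform draw assigns pseudogene
  (`p_pseudogene`, default 0.02), unpredicted (`p_unpredicted`, default
  0.10) or predicted-present status, so the failure modes are mutually
  exclusive and each occurs at its nominal marginal rate;
* concrete sequences: consensus peptides (20–40 aa, uniform over the
  20-residue alphabet) back-translated with uniformly random synonymous
  codons (never a stop), embedded at random strands and frames in
  uniform-composition background with random 30–120 nt spacers, so
  planted segments never overlap; pseudogene copies get exactly one
  strictly internal codon replaced by a stop codon of the active table,
  which makes the stop-filter decision unambiguous; predicted-present
  families also appear as proteome entries.

Deliberately *not* emulated: sequence divergence along the tree
(detection is by planted motif, so detector sensitivity on diverged
real homologs is untested here), introns and gene structure, assembly
gaps and low-coverage regions (absences caused by incomplete sequencing
are undetectable by DNA-level search and are out of scope), GC bias
(a knob exists, default off), and length-dependent prediction failure
(the rate is uniform; the length-group statistics are exercised on
synthetic counts instead).  Consequently, passing tests demonstrate the
correctness of the inference chain, not the sensitivity of any real
homology search.

## Statistics

Per-genome category comparisons use the two-sided Wilcoxon signed-rank
test with zero differences dropped; for n ≤ 25 the exact null is used
(scipy's permutation-based exact distribution, which matches full
2^n sign-pattern enumeration even with tied ranks), otherwise the
normal approximation with continuity correction.  Profile-length group
comparisons (top-k families by found-absence count vs the rest,
k = 100) use the two-sided Wilcoxon rank-sum test, exact for small
untied groups.  Correlation with assembly quality uses Kendall τ-b on
log-transformed N50.  Cross-set percentage relationships are fitted by
ordinary least squares with a 95% slope interval.  Displayed
percentages are rounded half-up to two decimals; internal arithmetic
keeps full precision.  Genome-level summaries exclude a genome from a
category's median when it has no absences in that category, and
universal-set (BUSCO-style) summaries include only genomes with more
than `min_busco_absences_per_genome` (default 5) absences.

## Evaluation conventions

Verification precision/recall are scored against the planted
unpredicted set restricted to cells the analysis actually turned into
absence records: a planted failure in a family rejected by the
ancestral filter, or in a species outside the reconstructed gain
subtree, can never be "found" by the procedure and is reported
separately as coverage.  Pseudogene-flag agreement is exact-set
equality over the same scope.  The generator's event log is compared
with reconstructions after collapsing planted sibling-branch loss pairs
into their parent (the two histories are observationally identical and
the reconstruction is minimal by construction).

## Problem sizes and determinism

The shipped study conditions — 50 species, 400 families, one contig per
genome (~70 kb) — give stable medians and a decisive signed-rank
p-value while a full run (simulate → translate → scan → reconstruct →
verify → correct) completes in a few seconds.  Oracle suites use
exhaustive enumeration on trees of ≤ 7 leaves and on 2^n sign
patterns at n ≤ 12, where brute force is exact and fast.  Every source
of randomness is a numpy `default_rng` seeded from the single run seed
(sub-seeds are fixed offsets), so all outputs are bit-reproducible for
a given seed.
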