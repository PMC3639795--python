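# Methods

`pylseeker` predicts pyrrolysine-incorporating genes in prokaryotic
genomes. Pyrrolysine (Pyl, the 22nd amino acid) is inserted at the amber
stop codon UAG in a small set of archaea and bacteria; a candidate Pyl
gene therefore looks like an open reading frame interrupted by a single
in-frame UAG, with translation continuing to a later stop. The pipeline
finds such interrupted ORFs (iORFs), clusters them by homology of the
region downstream of the amber codon (the putative PYLIS region),
scores each cluster with sequence-, structure- and coding-based
features, and ranks clusters by a weighted feature combination fitted to
known positives. This note records the models, the defaults and their
rationale, and the choices made where the design was genuinely open.

## iORF extraction

An iORF is defined by the grammar

    iORF  ::=  start  not-stop*  TAG  not-stop*  stop
    start ::= TTG | CTG | ATT | ATC | ATA | ATG | GTG      (table 11)
    stop  ::= TAA | TAG | TGA

scanned on both strands in all three frames. Because the not-stop
stretches exclude stop codons, the amber is the first stop-like codon
after the start and the terminal stop is the next stop after the amber;
the scanner is a single left-to-right pass per frame keeping the
5'-most start since the last stop. One iORF is emitted per qualifying
amber codon. Only iORFs with at least 100 nt strictly between the amber
and the terminal stop are kept, so a PYLIS structure fits inside the
coding region; the PYLIS region is the 100 nt immediately 3' of the
amber, and its peptide is the translation of the first 33 complete
codons (nt 1-99; 100 is not a codon multiple, so the 100th nt is used
only at nucleotide level). Coordinates are 0-based half-open
internally, converted to 1-based only at GFF3/TSV boundaries. Codons
containing N can appear inside not-stop stretches but never act as
start, amber, or stop (conservative handling of assembly gaps).
Genomes are treated as linear; origin-spanning iORFs on circular
chromosomes are a known omission.

## Homology clustering

Each 33-residue PYLIS peptide is searched against all candidate
genomes. The built-in backend scores Smith-Waterman local alignments
(BLOSUM62, gap open 11 / extend 1 in the BLAST convention) between
PYLIS peptides, prefiltered by shared exact 4-mers in the spirit of
BLAST seeding, and converts raw scores to e-values with the
Karlin-Altschul parameters for gapped BLOSUM62 (lambda = 0.267,
K = 0.041) over a search space of query length x six-frame database
size (2 x total genome nt). Restricting subjects to PYLIS regions
implements the rule that hits outside iORFs are ignored; hits of a
query to its own iORF are discarded. Exact-word seeding is less
sensitive than BLAST's neighborhood words; at the divergences the
benchmark plants (<= 10% per site) the loss is negligible (calibrated
by test). Tabular hits from an external six-frame tool can be supplied
instead and are mapped onto iORFs by coordinate overlap.

Matches at e <= 1e-6 are edges of an undirected graph over iORFs;
clusters are the connected components with >= 2 members. By default a
single directional hit makes an edge (querying every iORF makes
symmetric hits co-occur); a strict mode requires both directions. Two
pruning rules then drop artefact clusters: (a) a member's 100-bp
downstream region fully inside a reliably annotated protein-coding
gene in a different reading frame (shadow ORFs; the opposite strand
counts as a different frame), or (b) any overlap (>= 1 nt) with a
reliably annotated RNA gene. "Reliably annotated" means the product
description contains none of: pseudo, predicted, putative, unknown,
possible, hypothetical, probable (case-insensitive), and no pseudo
flag. Same-frame overlaps never prune, since true Pyl genes are
annotated in the same frame as their iORF.

## Coding potential

A first-order HMM whose states are amino acids: each state emits the
synonymous codons of its amino acid, so a codon string determines its
state path and the likelihood is a product of initial, transition,
emission, and gene-length terms. Training is maximum likelihood with
Laplace smoothing (pseudocount 1) on each genome's annotated genes;
terminal stops are stripped (no stop state) and non-ATG starts are
emitted by the amino acid they literally encode (a flag can force M).
The length model is the empirical distribution of training gene lengths
in codons, Gaussian-kernel smoothed (bandwidth 10 codons), truncated to
[10, 3000] codons and floored by a 1e-3 uniform mixture so every
supported length has positive probability; lengths outside the support
clamp to its edge. Any proper length distribution satisfies the module
contract; this one is config-exposed.

An iORF is scored as base-2 log-odds: the HMM term decodes the iORF's
codons with the amber deleted (states may emit UAG with no effect on
probability) and the terminal stop stripped; the null term charges the
full nucleotide length of the iORF, amber and stop included, at uniform
nucleotide frequency (log2 1/4 per nt). Codons containing N contribute
a maximum-entropy emission (1/61) with uniform transitions around them.
The base of the logarithm only rescales the feature, which is min-max
normalized downstream; base 2 is used.

The published retention rule keeps clusters with mean coding potential
below zero, which contradicts the strongly positive coding values
reported for the clusters that survive it. Both behaviors ship:
`filter_clusters_by_coding` defaults to the literal negative rule,
while the pipeline configuration defaults to the sign under which
gene-like clusters survive (`coding_rule: positive`).

## Structure comparison

Base-pairing probability matrices are computed with a McCaskill-style
inside/outside partition function over nested structures under a
deliberately simplified energy model: per-pair energies GC -3, AU -2,
GU -1 (kcal/mol-like), kT = 0.6, minimum hairpin 3, no stacking or
loop entropies and no lone-pair prohibition. This is exact for its own
model — the builtin probabilities match exhaustive structure
enumeration to 1e-9 — but parity with full nearest-neighbour folders
(RNAfold) is not claimed; any external tool emitting a dot-plot matrix
can be substituted through the backend hook.

Two matrices are compared by a Sankoff-style simultaneous alignment
over (i, j; k, l) spans: matched base pairs score the geometric mean
sqrt(p_a p_b) of their probabilities (pairs below p_min = 1e-4 carry no
signal), matched unpaired positions score sigma = 0, gaps cost -0.1 per
position. The O(n^4) span DP is banded (positions further than the
band apart never align) and sparsified to the strongest pairs per
position. Function defaults are band 30 and 10 pairs per position;
the pipeline aligns 100-nt, equal-length PYLIS regions with band 15 and
6 pairs per position — near-diagonal alignments lose almost nothing at
these settings and the full feature stage drops from ~5 to ~1.5 min on
one CPU. An unbanded exact mode is available for sequences <= 60 nt.
The geometric-mean pair bonus replaces the unrecoverable "default
settings" of the original probability-matrix aligner; the contract is
any symmetric, monotone pair-match bonus, and the choice is exposed.

Cluster structure similarity `f_structure` is the mean pairwise
alignment score (computed over at most 4 evenly chosen members per
cluster). For the dendrogram of positive-cluster PYLIS regions,
distances are 1/score (scores <= 0 capped at 1e6) and the tree is
canonical neighbor joining (Saitou-Nei) with negative branch lengths
clamped to zero, written as Newick.

## Cluster features, normalization, significance, ranking

Eight raw features per cluster: size (member count), organisms
(distinct genomes), upstream/downstream (mean nt from start codon to
amber, and amber to terminal stop, excluding both codons), diversity
(mean pairwise DIST_3 between nucleotide PYLIS regions), synonymous-
codon similarity (mean pairwise percent identity of the PYLIS peptides,
100 x (1 - DIST_1/33); the literal reciprocal-distance form 1/DIST_1 is
available behind a flag but cannot produce the published percent-scale
values and is undefined for identical pairs), structure (above), and
coding (above). DIST_m is the unit-cost edit distance in which every
maximal run of insertions, and of deletions, must have length divisible
by m — DIST_3 tolerates codon-sized indels while charging frameshifts;
DIST_1 is Levenshtein. When the length difference of the two strings
is not a multiple of m no script exists and the distance is infinite
(this cannot occur for the fixed-length PYLIS regions).

Features are min-max normalized to [0,1] across clusters (a constant
feature maps to 0 with a warning), and two combined features are added:
sqrt(coding x upstream) and (structure x diversity x syn_codons)^(1/3).

Significance of a feature is the probability that the n known positive
clusters would rank as well as observed by chance: 1e5 means of n ranks
drawn without replacement from {1..N} are sampled, a normal is fitted
(for N = 958, n = 6: mu ~ 479, sigma ~ 113, matching the finite-
population closed form mu = (N+1)/2, sigma = sqrt((N^2-1)/12n x
(N-n)/(N-1)) = 112.6 within 2%), and the p-value is the lower-tail CDF
at the observed mean rank. Ranks are ordinal, 1 = best, ties broken by
cluster id; every feature is oriented high-is-better (config-exposed).
Features with p > alpha (default 0.05) are discarded; no multiple-
testing correction is applied across the ten features, by design.

Weights over the selected features minimize the summed true ranks of
the positives under score_i = sum_h w_h fhat_ih, with w >= 0 and
sum w = 1 (the objective is scale-invariant). The rank objective is a
step function, so descent runs on a sigmoid-relaxed surrogate with
temperature annealed from 10*tau to tau (tau = 0.01) and normalized
softmax-parametrized gradient steps. Restarts form a deterministic,
permutation-symmetric set (uniform, every single-feature vertex, every
pairwise mixture); every restart's start and end point, plus the exact
vertices, enter a candidate pool and the candidate with the lowest true
objective wins. This guarantees the result is never worse than equal
weights or the best single feature, and that permuting feature columns
permutes the weights. A derivative-free cyclic coordinate search is
available as an alternative.

## Synthetic benchmark

The generator emulates the study conditions at desk scale with full
ground truth. Background genomes are random sequence at a target GC
with annotated protein-coding genes (60-600 codons, ~30% coverage,
both strands, ~1 in 10 annotated "hypothetical protein"). Coding
sequence follows a fixed shared process: amino acids from a first-order
Markov chain (successor preference 0.35) and synonymous codons with
geometrically decaying weights (ratio 1/3) — both dependencies are
learnable by the codon HMM, so codon shuffling destroys a real signal,
as in genuine coding sequence.

Planted families are mutated copies of a template iORF overwritten
into intergenic windows (genome length and annotation coordinates are
preserved); an in-frame TAA guard immediately 5' of each start codon
pins the scanner to the intended coordinates, so every planted member
is re-found verbatim (re-checked by test, not assumed). Mutation is
site-independent substitution at `sub_rate` with a fraction `syn_bias`
of coding substitutions forced synonymous; start, amber, terminal stop
and the hairpin window are never touched, and a substitution that would
create an in-frame stop is redrawn as synonymous. The optional
conserved hairpin is a 12-bp stem / 6-nt loop written into the first
100 nt downstream of the amber, rejection-sampled to avoid stop codons.

The default benchmark: 13 genomes x 60 kb; 6 positive families
patterned on the known Pyl clusters (8-14 members over many genomes,
100-340 upstream codons, substitution rate 0.05 with synonymous bias
0.6, half with a conserved hairpin); 72 decoy families emulating
conserved spurious iORF clusters (2-4 members in 1-2 genomes, 2-30
upstream codons); 3 shadow-ORF and 2 RNA-overlap families that exist to
be pruned. A few thousand singleton decoy iORFs emerge from the random
background. Decoy *clusters* must be planted because independent random
genomes cannot produce cross-genome conserved families; this is the one
place the generator departs from "decoys emerge by themselves".

What passing the end-to-end test does and does not show: it shows the
pipeline separates families with the positives' signature (breadth
across organisms, long upstream regions, gene-like codon usage) from
decoys under a known generative process. It does not show performance
on real genomes, where annotation quality, repeat content, amino-acid
composition and structure are far richer than this generator emulates,
and where the built-in search backend approximates rather than
reproduces a production six-frame search tool.

## Problem sizes and numerics

Default problem sizes were chosen for a single CPU: the benchmark run
(extract ~3.5k iORFs, search, 78 surviving clusters, all features,
ranking, tree) completes in ~2.5 minutes; the null sampler draws 1e5
six-rank means in ~2 s by vectorized rejection sampling. Partition
functions for 100-nt sequences stay far below double-precision
overflow. Alignment score symmetry holds to 1e-9; folding
probabilities match enumeration to 1e-9; NJ reproduces additive
metrics to 1e-9. Degenerate inputs: empty training sets, empty rank
lists, n > N null requests, non-symmetric distance matrices, constant
feature columns and configs with unknown keys all raise immediately
with explicit messages; a constant feature normalizes to zero with a
warning rather than aborting.

## Known limitations

- The built-in folding model omits stacking and loop entropies; use the
  backend hook for thermodynamically realistic dot plots.
- The built-in homology backend approximates tblastn (exact-word
  seeding, Karlin-Altschul e-values on Smith-Waterman scores); supply
  external tabular hits for exact parity.
- Circular genomes are treated as linear.
- With only a handful of positive examples the fitted weights can
  overfit; there is deliberately no cross-validation machinery.
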