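# Methods

This note documents the modelling choices behind `lpifuse`: the feature
definitions, the selection and classification procedure, the synthetic
benchmark, and the numerical conventions — including every place where the
design was genuinely open and what we chose.

## Problem setting

The data form a bipartite graph: lncRNA nodes, protein nodes, and
experimentally validated interaction edges. Prediction is framed as binary
classification of (lncRNA, protein) pairs, with known interactions as
positives. No public resource defines negatives for this task, so the
package offers two explicit policies: `all` (every non-edge; heavily
imbalanced, the realistic screening regime) and `balanced` (a
seed-reproducible uniform sample of non-edges of the same size as the
positive set; faster, and appropriate for method development). All
evaluation numbers are tied to this choice, which is why both the policy
and the seed are recorded in every output.

Input preprocessing drops pairs whose lncRNA or protein has no sequence
record, then iteratively removes nodes of degree ≤ 1 until a fixed point.
A single pass would not suffice: removing one node can push its neighbour
to degree 1. Degree-1 nodes are removed because their single edge carries
no correlation structure for a network feature to exploit.

## Feature blocks

**Topology (`LDNet`).** The feature of pair (l_i, p_j) is the
concatenation of l_i's edge indicators to every protein except p_j (in
protein order) and p_j's edge indicators to every lncRNA except l_i (in
lncRNA order): N + M − 2 binary values. The pair's own edge is excluded by
construction; additionally, during cross-validation the positive edges of
the evaluation fold are zeroed in a copy of the adjacency *before any
feature row is built*, for training and test rows alike. Without this
masking a test pair's label would sit inside other rows of the feature
matrix and inflate every metric. Masked evaluation is the honest protocol
and may yield lower scores than an unmasked one.

**K-PSSM-composition (`KPSSM`).** The protein's position-specific scoring
matrix (PSI-BLAST ASCII format, first 20-column log-odds block) is split
into k contiguous row segments; within each segment the rows are summed
per residue type, giving 20 sums of 20-vectors = 400 values per segment.
Default k = 1 (the plain PSSM-composition); k is exposed for users who
want positional resolution. The transform is linear in the PSSM scores.
Rows whose residue is non-standard (X) contribute to no residue group.

**CTD (`CTD`).** Thirteen physicochemical properties each partition the
20 amino acids into 3 groups. Per property we report: group fractions
(C, 3), unordered adjacent-transition fractions between distinct groups
(T, 3), and, per group, the positions of the 1st, 25%, 50%, 75% and 100%
occurrence as percent of sequence length (D, 15) — 273 dimensions total.
The D quantile is the ceil(q·n)-th occurrence among n group members; an
absent group yields five zeros, which keeps D's five values trivially
non-decreasing. X residues are removed before computation. The grouping
table is shipped as `data/ctd_groups.tsv` (the 13-property set used by the
iFeature toolkit: seven hydrophobicity scales plus normalised van der
Waals volume, polarity, polarizability, charge, secondary structure,
solvent accessibility) and can be swapped for any table with the same
layout; the code validates that each row partitions the 20 residues
exactly.

**Sequence information (`SEQ`).** Overlapping 1/2/3-gram counts with
additive smoothing ε (default 10⁻⁶, any positive value allowed):
p(x) = (N_x+ε)/L, p(x,y) = (N_xy+ε)/(L−1), p(x,y,z) = (N_xyz+ε)/(L−2).
Windows containing an ambiguous base are skipped and the denominators use
the effective window counts, so the distributions normalise at ε = 0.
From these, per-symbol information quantities in bits:

* MI(x,y) = p(x,y)·log₂[p(x,y)/(p(x)p(y))], with p(x,y) symmetrised as
  the *average* of the two ordered dinucleotide counts for x ≠ y. The
  average (rather than the sum) keeps the pair distribution normalised
  while making MI(x,y) = MI(y,x) exact; summing would double off-diagonal
  probabilities and produce MI ≈ 0.125 bits even on i.i.d. uniform
  sequences.
* H(x|z) = −[p(x,z)/p(z)]·log₂[p(x,z)/p(z)] and
  H(x|y,z) = −[p(x,y,z)/p(y,z)]·log₂[p(x,y,z)/p(y,z)] — per-symbol forms,
  not summed over the alphabet.
* MI(x,y|z) = H(x|z) − H(x|y,z) and MI(x,y,z) = MI(x,y) − MI(x,y|z); the
  chain identity MI(x,y,z) + MI(x,y|z) = MI(x,y) therefore holds to
  machine precision by construction and is used as a consistency check.

The 19-dim MI block is 16 pairwise MI values over ordered base pairs in
alphabetical order followed by the mean, min and max of the 64 triplet MI
values; this layout matches the block's published dimensionality while
exercising both the pairwise and the triplet definitions. The log base is
a global scale factor and is irrelevant after per-column scaling; base 2
is used throughout. One limit worth knowing: on a homopolymer the pair
MI values vanish as ε → 0, but triplet terms involving never-seen symbols
retain an O(1/L) residual because the smoothed ratio p(x,z)/p(z) tends to
L/(L−1), not 1.

The composition part is the 16 overlapping dinucleotide frequencies
(counts/(L−1), alphabetical); a 20-dim variant with the 4 mononucleotide
frequencies prepended is available behind a flag but is not the default,
so the combined sequence block stays at 19 + 16 = 35.

**Expression (`EXPR`).** The lncRNA's 24-tissue expression row; a missing
lncRNA yields zeros with a warning rather than an error, because absence
from an expression atlas is routine. `extract_node_features` applies
log1p by default: expression values are heavy-tailed, and min-max scaling
of raw values compresses nearly all rows into a corner of [0, 1], which
starves kernel methods (including the RFE criterion) of resolution.

## Fusion, scaling and selection

Blocks are concatenated in the fixed order LDNet, KPSSM, CTD, SEQ, EXPR
with recorded column spans. Columns are scaled to [0, 1] with min/max
fitted on training rows only; constant training columns map to 0 and test
rows may leave the interval.

SVM-RFE ranks features by recursive elimination. Each iteration trains a
kernel SVM (defaults: RBF, C = 16, γ = 0.0078 — the selector's published
configuration, distinct from the final classifier's parameters) and scores
every surviving feature by DJ(f) = ½(αᵀKα − αᵀK₍₋f₎α) over the support
vectors, where K₍₋f₎ is the kernel without feature f. For the RBF kernel
K₍₋f₎ = K·exp(γ·d_f²) elementwise, which the implementation exploits; for
the linear kernel DJ reduces to w_f²/2. The lowest-scoring features are
removed and appended to the tail of the ranking; ties break toward
removing the lower column index (deterministic). `step` removes that many
features per iteration, or that fraction of survivors when in (0, 1);
step = 1 is the classic algorithm, fractional steps trade ranking
resolution for speed (5% per iteration approximates step = 1 well at a
fraction of the cost and is what the recovery experiment uses at
~850 columns).

Correlation bias reduction: features whose pairwise |Pearson r| ≥ 0.9 (on
the scaled training matrix; the published threshold) are grouped by
connected components, and at most one member of a group is eliminated per
iteration — the others re-enter the next iteration with recomputed
criteria. This implements the published intent (correlated groups mask
each other's importance) as *deferred elimination*; the original
description leaves the exact sub-procedure open, and this reading is the
simplest one that guarantees the group constraint. The constraint applies
in every iteration, including the final clean-up.

The selected subset size is not published; by default it is chosen per
training split by inner cross-validated AUC over
{25, 50, 100, 200, 400, all}.

## Classifier and evaluation

The classifier is an RBF-SVM. (C, γ) are chosen by grid search maximising
mean inner-CV AUC; ties prefer smaller C, then smaller γ. The default
ladders are powers of 4 (C: 2⁻⁵…2¹⁵, γ: 2⁻¹⁵…2³) with the published
optimum (C = 256, γ = 0.002) appended, since 256 = 2⁸ does not lie on the
odd-exponent ladder.

Cross-validation is stratified by label and seeded. Per fold: topology
features are rebuilt with the fold's positive edges masked; scaler, RFE
ranking, subset size and grid search are fitted on training rows only;
test rows are scored by decision value. Pooled curves come from
concatenated out-of-fold scores. Scalar metrics (SE, SP, PR, ACC, F1,
MCC) are evaluated at decision threshold 0; a zero denominator yields 0
with the metric flagged rather than an exception, so degenerate folds
still pool. AUC is the trapezoidal ROC area (identical to the
Mann–Whitney pair statistic, which the tests verify to 10⁻¹²); AUPR is
the step-wise average-precision sum, avoiding the optimistic bias of
trapezoidal interpolation in PR space.

## The synthetic benchmark

`lpifuse.synth` generates all five input kinds in the exact file formats
the readers consume. Sequences are i.i.d. uniform, PSSMs are integer
log-odds in [−10, 10] biased toward the true residue, expression is
log-normal with 24 tissue columns. Defaults: 100 lncRNAs × 20 proteins at
edge density 0.15 (~300 positives, ~600 labeled pairs under the balanced
policy) — small enough for the full pipeline to run in minutes on one
CPU, large enough for stable recovery statistics.

The planted benchmark draws each edge from
Bernoulli(sigmoid(b0 + s·w·(u_i + v_j))) where u, v are standard-normal
node latents, s is `signal_strength`, w = 2.0 is a fixed loading, and b0
is calibrated by bisection so the expected density matches the request.
The loading is set so that the recovery regime (s = 3) has a
Bayes-optimal AUC near 0.99: the planted association should dominate the
Bernoulli label noise, so that failure to recover it indicts the
pipeline, not the generator. u_i is additionally expressed through two
observable channels: it tilts the lncRNA's base composition toward G/C
(logit tilt 0.4 per unit latent), so the four G+C dinucleotide
composition columns track it through independent multinomial sampling
noise, and it shifts the log-mean of expression columns 0–1 (loading 0.8,
noise SD 0.5 per column). The documented planted columns are therefore
those 4 + 2 columns; the topology block inherits the same signal through
the shared latents. The planted set is deliberately few, individually
strong, and only moderately redundant: a ranking cannot be expected to
retain many near-copies of one factor, since discarding redundant copies
is exactly what a good selector does. At s = 0 the labels are independent
Bernoulli draws and the pipeline's pooled AUC sits at chance — the null
control.

What passing these tests shows — and does not show. Recovery of the
planted signal demonstrates that feature extraction, masking, scaling,
selection and classification are wired correctly and leak-free. It does
not show that the features capture real lncRNA biology: the generator has
no secondary structure, no binding motifs, no GC/repeat structure beyond
the planted tilt, and no realistic PSSM evolution. Recovery fractions for
the partially redundant planted columns also vary across generator seeds
(RFE's choice among near-redundant copies is seed-dependent); the shipped
recovery experiment is anchored at the benchmark's default seed.

## Numerical conventions and degenerate inputs

* ε > 0 required for k-gram smoothing; tests take ε → 0 limits with 10⁻¹².
* Sequences shorter than 3 unambiguous bases are rejected for k-gram
  models; shorter than 2 standard residues (after X removal) for CTD.
* Duplicate interaction lines collapse to one edge with a warning
  (adjacency is binary); pairs naming unknown IDs are dropped and counted.
* Single-class training sets, empty networks after filtering, and
  mismatched block pair lists raise validation errors rather than
  producing silent nonsense.
* Constant feature columns scale to 0; Pearson correlations involving
  them are treated as 0 in CBR grouping.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fold assignment, negative sampling and
  every generator are bit-reproducible given their seed.

## Known limitations

* The degree filter's published node counts cannot be checked because the
  original pair list is not deposited; only the filter's contract
  (fixed point, minimum degree 2, idempotence) is tested.
* The exact published CTD grouping and the published 19-dim MI layout are
  not recoverable from their sources; dimensionalities and internal
  invariants are contractual, specific values are not.
* The CBR sub-procedure is a faithful reading, not a line-by-line port of
  the original MATLAB release.
* Negative-pair construction for the real benchmark is undefined
  upstream; absolute metric values therefore depend on the chosen policy
  and are not comparable to published tables.
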