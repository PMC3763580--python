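# Methods

`cytosel` implements a binary protein-family classifier built for the
cytokine-identification setting: very few positive sequences against a
large, diverse negative background. The pipeline has four stages —
sequence curation, CTD feature extraction, hybrid resampling, and a
clustering-based selective ensemble — evaluated with
sensitivity/specificity/geometric-mean metrics.

## Sequence model and curation

A protein is a string S = R₁…R_L over the 20-letter amino-acid alphabet.
Strict parsing rejects ambiguous residues (B, J, O, U, X, Z); lenient
parsing drops them and shrinks L, because every feature below is defined
only over the canonical alphabet. The curation utility implements the
longest-per-family selection rule used to build non-redundant negative
sets: one representative per protein family (the longest member, ties
broken by lexicographically smallest id so the choice is order-independent),
with families belonging to the positive class excluded. No similarity-based
redundancy reduction (CD-HIT-style) is provided: no identity threshold is
part of the method description, so the utility stops at the two stated
rules.

## CTD features

Each of 8 physicochemical properties — secondary structure, solvent
accessibility, normalized Van der Waals volume, hydrophobicity, charge,
polarizability, polarity, surface tension — partitions the alphabet into
3 groups. The packaged table uses the canonical three-group CTD
divisions from the protein feature-extraction literature, anchored to
the secondary-structure helix group {E,A,L,M,Q,K,R,H}. The table is
data (`data/property_groups.yaml`), validated on load (each property's
groups must partition the alphabet) and user-overridable, so a different
division scheme can be substituted without code changes.

Four families, all in [0, 1]:

* **composition (20D)** — vᵢ = nᵢ/L; sums to 1.
* **content (24D)** — per property and group, group count / L; each
  property's triple sums to 1.
* **transition (24D)** — bivalent frequency: for each unordered group
  pair, the number of adjacent residue pairs crossing the two groups (in
  either direction) divided by L. The denominator is deliberately L, not the L−1
  some CTD variants use — documented so users can compare conventions. L = 1 yields all zeros with a warning.
* **distribution (120D)** — for each property, group, and chain fraction
  q ∈ {first, 25%, 50%, 75%, 100%}: the 1-based position of the k-th
  group occurrence divided by L, k = 1 for "first" and k = ⌈q·n_g⌉
  otherwise. The ceiling makes q = 1.0 the exact last occurrence and
  q = 0.25 coincide with the first occurrence when n_g ≤ 4. A group
  absent from the sequence contributes five zeros — the only convention
  that stays in [0, 1] without inventing a position.

The full 188D vector is composition + content + transition +
distribution, in that order; the 120D distribution block is the core
representation.

## Hybrid resampling

With ~1:84 imbalance, training directly rewards majority-class
prediction. The sampler rebuilds a near-balanced set from both sides:

* **SMOTE oversampling** of the minority class: synthetic points
  x + u·(x_nn − x), u ~ U[0,1], x a random real minority row and x_nn
  one of its k nearest minority neighbours (k = 5 default, Euclidean).
  Synthetic rows are flagged in the output provenance.
* **K-means cluster undersampling** of the majority class: Lloyd's
  algorithm with K = target size, squared-Euclidean assignment (ties to
  the lowest cluster index), at most t iterations (default 50), and the
  member closest to each centroid kept — every retained majority row is
  a verbatim input row, and cluster structure preserves coverage of the
  majority distribution. Initialization is a seeded k-means++ draw of K
  distinct input rows: uniform random seeding was tried first and
  routinely merged well-separated clusters (losing coverage, the one
  property the undersampler exists to provide), while D²-weighted
  seeding preserves it at the same cost. Empty clusters are re-seeded
  with the point farthest from its centroid. Default targets are 2000
  per class; if no majority target is given it defaults to ⌈λ·n⌉ with λ
  the undersample fraction.

Degenerate inputs: classes with fewer than 2 members are rejected; k is
clipped to n_minority − 1; duplicate rows that starve a cluster are
compensated by filling from the nearest unchosen rows so the output size
is exact.

## Selective ensemble

Eighteen heterogeneous base learners are fitted and summarised by a
binary result matrix R (R_ij = 1 iff learner i classifies sample j
correctly). By default R holds 5-fold out-of-fold predictions: scoring
on resubstitution rewards memorising learners (1-NN posts a perfect
row), and a committee selected on such rows transfers poorly; a
`resubstitution` mode is kept so the two scoring conventions can be
compared. Learners are clustered by K-means on the rows of R (K = 9,
capped at the pool size), grouping learners with similar error
patterns. The best learner per cluster, sorted by descending accuracy,
forms the candidate list; the committee starts with the top candidate
and each remaining candidate joins only if committee majority-vote
accuracy strictly rises and mean pairwise agreement strictly falls. The
target accuracy starts at 1.0 and relaxes in steps of 0.05 until the
committee meets it, with a stop once a full pass adds nothing or the
target falls below the achieved accuracy.

Diversity is measured as mean pairwise agreement of correctness flags —
the fraction of samples on which two learners' R entries coincide. The
add rule then promotes exactly the candidates whose mistakes complement
the committee's. For binary labels the committee vote is recoverable
from R alone (a wrong member necessarily votes the other label), so
selection needs no second prediction pass; exact vote ties follow the
most accurate member.

The pool maps the classic Weka line-up to scikit-learn: linear and RBF
margin classifiers, logistic regression, 1/5/10-nearest-neighbour,
decision trees at several depths/criteria standing in for the decision
table, conjunctive-rule, one-rule, CART, RIPPER and C4.5 inducers, a
constant predictor, an extremely-randomised tree, naive Bayes, a
50-tree random forest, a decision stump, and gradient boosting standing
in for functional trees. Scale-sensitive members standardise inputs (as
the classic SMO and instance-based implementations do by default).
Learners that fail to fit are dropped with a warning; at least two must
survive.

## Evaluation

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N, and GM = √(SN·SP).
GM is the geometric mean — the reading under which the worked SN/SP/GM
triples (93.7/92.9 → 93.3; 96.8/97.7 → 97.2) are internally consistent;
the plain product would give 87.0 and 94.6. Under extreme imbalance
ACC ≈ SP (the gap is w_pos·|SN − SP|, at most the positive-class
weight), which is why GM is the headline metric.

Cross-validation is stratified k-fold (default 10), seeded, with
held-out predictions pooled before computing metrics. Resampling happens
inside each training fold only — resampling before splitting leaks
synthetic copies of held-out minority points into training folds and
inflates SN. A `presample` option reproduces that literal
sample-then-validate order for comparison; its numbers should be read as
optimistic.

## Synthetic data

The generator emulates two sequence classes that differ in residue-group
usage: negatives i.i.d. uniform over the alphabet, positives with an
excess probability mass `bias` spread over a designated residue set
(default: the helix group, the anchor membership of the feature table).
Defaults are 50 positives vs 2000 negatives (1:40, a desk-scale proxy
for the ~1:84 regime), lengths uniform in 50–200 (typical small-protein
lengths), bias 0.5, fully determined by the seed.

What the generator does **not** emulate matters for interpreting
results. Because residues are i.i.d., the class signal lives almost
entirely in residue frequencies: composition and content features
separate the classes nearly perfectly (≈ 0.99 balanced accuracy at
bias 0.5), while the position-quantile distribution features move only
through O(1/L) finite-size effects against O(1/√L) sampling noise. The
120D distribution block is therefore only weakly informative on this
fixture (a 600-tree boosted model on 3000 sequences per class tops out
near 0.92 balanced accuracy), whereas on real protein families
distribution features also pick up positional structure the i.i.d. model
cannot produce. Consequently the desk-scale end-to-end run on 120D
features demonstrates the unsampled collapse under imbalance (held-out
GM far below 0.5) but does not reach the high sampled GM that the same
pipeline attains on strongly separable features — with a few dozen real
positives, SMOTE interpolation adds no new information. Passing tests on
this fixture validate the pipeline's mechanics and the sampling effect's
direction, not absolute performance on real sequence data.

## Numerical choices and limitations

* All randomness flows from explicit integer seeds; the hybrid sampler
  derives independent child seeds for SMOTE, K-means and the final
  shuffle from one plan seed.
* K-means assignment uses squared Euclidean distance; argmin ties go to
  the lowest cluster index.
* Committee and candidate ties (equal accuracy) resolve to the lower
  pool index; split votes resolve to the most accurate member.
* The undersampler with K equal to thousands of clusters is O(n·K·d)
  per iteration; the iteration cap t is the practical control.
* Binary classification only; multi-family cytokine classification is
  out of scope, as are profile/PSSM features and any web service.
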