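# cytosel

Identify cytokines — immune-signalling proteins — from primary amino-acid
sequence alone. The practical obstacle is extreme class imbalance: curated
benchmarks pair on the order of a hundred representative cytokines with
~10⁴ negative protein families (roughly 1:84), so a classifier trained
naively learns to say "not a cytokine" and posts near-perfect accuracy
while missing nearly every positive. `cytosel` packages the three-part
remedy as a reusable library and command-line tool:

1. **CTD feature extraction.** Each sequence S = R₁…R_L over the
   20-letter alphabet becomes a fixed-length vector from four families:
   20D composition (vᵢ = nᵢ/L), and — over 8 physicochemical properties
   that each split the alphabet into 3 groups — 24D group content, 24D
   bivalent (transition) frequency, and the 120D distribution block:
   normalized chain positions of the first/25%/50%/75%/100% occurrences
   of each group. The full set is 188D; the 120D distribution block is
   the core representation.
2. **Hybrid resampling.** SMOTE grows the minority class along
   nearest-neighbour segments (x + u·(x_nn − x), u ~ U[0,1]) while
   K-means cluster undersampling shrinks the majority class to one real
   representative per cluster (K = target size), yielding a near-balanced
   training set (default 2000/2000) that neither drowns in synthetic
   noise nor discards majority structure.
3. **Selective ensemble.** 18 heterogeneous base learners are fitted and
   summarised by a binary result matrix R (R_ij = 1 iff learner i got
   sample j right); learners are clustered by error pattern (K-means,
   K = 9) and a voting committee is grown by circulating forward
   selection: a candidate joins only when committee majority-vote
   accuracy rises and inter-member agreement falls. Prediction is a
   majority vote with the positive-vote share as a confidence score.

Evaluation uses sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP)
and their geometric mean GM = √(SN·SP) — the metric of record under
imbalance, where plain accuracy collapses onto SP.

Intended users: bioinformaticians screening proteomes for cytokine
candidates, and anyone needing the CTD + hybrid-resampling + selective-
ensemble recipe for a comparably imbalanced sequence-classification
problem. See `docs/methods.md` for the model details and limitations.

## Worked example

Synthesize a separable two-class dataset (positives enriched for the
helix-group residues EALMQKRH), extract 188D features, train with
resampling, and cross-validate:

```bash
cytosel simulate --n-pos 40 --n-neg 400 --bias 0.5 --seed 11 \
    --out-pos pos.fasta --out-neg neg.fasta --labels labels.tsv
cat pos.fasta neg.fasta > all.fasta
cytosel extract all.fasta --features 188d --labels labels.tsv --out features.csv
cytosel train features.csv --features 188d --resample \
    --pos-target 200 --neg-target 200 --seed 11 --model model.joblib
cytosel evaluate features.csv --folds 5 --seed 11 --resample \
    --pos-target 150 --neg-target 150 --out report.json
```

The train step prints the selected committee and its accuracy on the
(resampled) training set:

```
chosen classifiers: smo
achieved committee accuracy: 1.0000
```

and the evaluation step prints pooled held-out confusion counts and
metrics over the 5 folds (resampling is applied inside each training
fold only, so these are honest held-out numbers):

```
TP=39  TN=400  FP=0  FN=1
SN=0.9750  SP=1.0000  GM=0.9874  ACC=0.9977
```

Here 39 of the 40 positives are recovered (SN = 0.975) with no false
positives (SP = 1.0), giving GM = √(0.975 × 1.0) = 0.987. `predict`
applies a saved model to new FASTA and writes per-sequence labels with
the committee's positive-vote fraction. Every artifact gets a
`.meta.json` sidecar recording the full run configuration and seed.

The same operations are available as library functions
(`cytosel.extract`, `cytosel.hybrid_resample`,
`cytosel.SelectiveEnsembleClassifier`, `cytosel.crossvalidate`, ...).

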