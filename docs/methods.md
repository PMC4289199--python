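# Methods

## Model

`recspot` classifies 1–2.5 kb DNA regions as recombination hotspots or
coldspots from sequence composition alone. The underlying assumption is
biological: hotspot regions carry characteristic GC and dinucleotide
biases, so a discrete compositional representation plus a linear decision
boundary should separate the classes.

A sequence of length L over {A, C, G, T} is mapped to a pseudo nucleic
acid composition (PseNAC) vector with two parts:

1. **k-mer tiers** (k = 1…k_max). Tier k holds the `4^k` normalized
   overlapping k-mer frequencies, denominator `L − k + 1`, ordered
   lexicographically with A<C<G<T. Each tier sums to one.
2. **PseDNC block** (16 + ω entries). The 16 dinucleotide frequencies
   `f_m` are augmented with global sequence-order factors
   `g_j = mean_i Δ(R_iR_{i+1}, R_{i+j}R_{i+j+1})`, j = 1…ω, where
   `Δ(a, b)` is the mean squared difference of the six normalized
   structural properties of dinucleotides a and b (twist, tilt, roll,
   shift, slide, rise). The block is normalized jointly,
   `d_m = f_m/(Σf + wΣg)` and `d_{16+j} = w·g_j/(Σf + wΣg)`, so it sums to
   one and the weight w balances composition against order.

The shipped property table is reverse-complement symmetric (row AC equals
row GT, AG equals CT, and so on), which implies
`Δ(a, b) = Δ(revcomp(b), revcomp(a))`; the test suite asserts this on the
packaged constants only, since user-supplied tables need not satisfy it.

Feature ranking is SVM-RFE: fit a linear-kernel soft-margin SVM (libsvm
via scikit-learn's `SVC`) on the surviving features, eliminate the single
feature with the smallest squared weight, repeat. Strictly one feature is
removed per iteration. Ties on the squared weight eliminate the feature
with the larger layout index, so earlier-defined features survive longer
and the ranking is deterministic. An F-score ranker (the standard
two-class mean/variance ratio with unbiased within-class variances) is
provided as the filter-method baseline.

Model selection is a grid search over the regularization parameter C and
the retained dimension Dim (top-N of the ranking), scored by jackknife
(leave-one-out) accuracy; ties prefer the smaller N, then the smaller C
(parsimony). The final report carries Sn, Sp, Acc, MCC computed from the
hot/cold misclassification counts, and the ROC/AUC of the pooled jackknife
decision values (threshold sweep, trapezoid rule; equivalent to the
normalized Mann–Whitney statistic).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_max` | 5 | highest k-mer tier; tiers beyond 5 add mostly redundancy and grow as 4^k |
| `ω` (omega) | 10 | highest coupling lag; must satisfy ω ≤ L_min − 2 over the dataset |
| `w` (weight) | 0.05 | PseDNC order-vs-composition balance; w = 0 reduces the block to plain dinucleotide frequencies |
| `C` | grid 2⁻⁵…2¹⁵ | SVM soft-margin penalty, the single free SVM hyperparameter (linear kernel) |
| `N` (Dim) | grid 1…200 | number of top-ranked features retained |

ω = 10 and w = 0.05 are conventional values for the PseDNC family: large
enough that the order factors matter, small relative to the 1364 k-mer
features. The C used during RFE defaults to 32 and is configurable
independently of the evaluation grid.

## Evaluation protocol and leakage

By default the feature ranking is computed **once on the full dataset**
and the jackknife then refits only the SVM per fold. This mirrors the
single accuracy-vs-topN curve of the classical protocol but leaks
information from the held-out sample into the feature choice, so the
default estimates are optimistic. A `nested` mode re-ranks inside every
fold for leakage-free estimates at ~n× the cost.

Both biases are quantified on null data (no planted signal, n = 100 at
the default class ratio):

* the default protocol's pooled-decision AUC centers near 0.62
  (selection bias of full-dataset ranking);
* the nested protocol's AUC falls *below* 0.5 (0.3–0.45), because with no
  signal the per-fold decision values are dominated by the training fold's
  class-majority bias, which always tilts against the held-out sample.

The same fold-majority effect makes leave-one-out on *exactly balanced*
null data anti-learn catastrophically (Acc ≈ 0, AUC ≈ 0): removing one
sample always leaves the opposite class in the majority. Null checks are
therefore run at the benchmark-like imbalanced ratio (≈ 45:55), where the
majority class is stable across folds. Users evaluating their own data
should prefer the nested protocol for reporting, and should treat
pooled-jackknife AUC with care near chance level.

## Synthetic data

The generator emulates the compositional structure the classifier is
meant to detect, at the stated region scale: sequence lengths uniform on
1000–2500 nt, default class sizes 490 hot / 591 cold (the benchmark
ratio), uniform background. Cold sequences are i.i.d. draws from the
background; hot sequences come from a first-order Markov chain whose
transition matrix up-weights the constituent dinucleotides of the planted
k-mers (default: CG × 3.0) and applies an optional GC shift, then
renormalizes rows. A first-order dinucleotide bias was chosen over motif
insertion because every feature family the encoder computes responds to
dinucleotide statistics — the signal is detectable by the method under
test without being trivially separable by any single feature.

What the generator does **not** emulate: real yeast hotspot sequence
statistics beyond dinucleotide/GC structure — no repeats, no consensus
motifs, no chromatin context, no position effects, no length–class
correlation. Passing the planted-recovery tests therefore shows the
pipeline recovers compositional signal it is pointed at; it says nothing
about absolute accuracy on real recombination data.

"Planted features" are defined as the k-mer features containing a planted
k-mer as a substring (all tiers up to k_max) plus the matching PseDNC
dinucleotide components; for CG at k_max = 3 that is 10 features
(CG, ACG…TCG, pse:CG).

## Study conditions for tests and the acceptance script

Desk-scale conditions, chosen once: encoder k_max = 3 and ω = 10
(D = 110 features), C grid {1, 32}, N grid {4, 8, 16, 32, 64}; planted
runs use 50 hot / 60 cold with CG enrichment 3.0, null runs n = 100 at
the 45:55 default ratio; five replicate seeds each. Stochastic outcomes
(accuracy, AUC) are asserted on the mean over replicates. Under these
conditions the planted pipeline is at ceiling (jackknife Acc = 1.0,
recovery ≥ 80% of planted features in the top 20) and the null AUC sits
at the protocol's characteristic ~0.62.

## Numerical choices and degenerate inputs

* Sequences must be pure A/C/G/T; ambiguity codes are rejected by default
  (an opt-in skip flag drops offending records with a warning), because
  silently masking N's would corrupt the frequency normalizations.
* Class prediction thresholds the raw SVM decision value at 0; hotspot iff
  strictly positive. No probability calibration is applied anywhere.
* MCC returns 0 (logged) when a contingency marginal is empty; constant
  decision values yield AUC 0.5 with a warning.
* A jackknife fold that loses an entire class (only possible when a class
  has a single sample) predicts the fold majority, logged.
* Zero within-class variance in both classes gives a feature an infinite
  F-score (most discriminative) when the class means differ, 0 otherwise.
* Linear SVM fits are deterministic for fixed data, so rankings and
  accuracy surfaces reproduce bit-for-bit; duplicated feature columns are
  resolved by the deterministic tie rule.

## Known limitations

* SVM-RFE is O(D) SVM fits; at the full D = 1390 with hundreds of samples
  the ranking is minutes-scale. The elimination loop is strictly
  one-at-a-time by design (chunked elimination would change the ranking).
* The default evaluation protocol leaks (see above); its numbers are
  comparable to the classical protocol, not unbiased estimates.
* Only DNA (no RNA, no ambiguity codes) and only the dinucleotide
  six-property table; trinucleotide physicochemical extensions are out of
  scope.
* The jackknife pooled-ROC construction assumes decision values are
  comparable across folds; near chance performance this assumption fails
  in a structured way (see the leakage section).
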