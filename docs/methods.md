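# Methods

## Feature representation

A protein sequence of length `L` is represented over gapped dipeptides:
ordered pairs `(a1, a2)` of standard residues separated by `g`
intervening positions, `0 ≤ g ≤ Gmax`.  The default `Gmax = 13` gives
`400·14 = 5 600` features; it is configurable, and sequences shorter
than `g + 2` simply contribute zero to the gap-`g` block.

Weights are soft counts.  Each position is first converted to a
probability row `q[p, ·]` over the 20 residues, then

```
w(a1, a2, g) = Σ_{p=1..L−g−1} q[p, a1] · q[p+g+1, a2]
```

Three transforms produce `q`:

* `sigmoid` (default when a profile is available): the logistic
  `1/(1+e^{−s})` of the PSI-BLAST log-odds score `s`.  Rows are not
  normalised; weights reflect evolutionary plausibility rather than
  frequency.
* `percentage`: the profile's weighted observed percentages divided by
  100 and renormalised per position (an all-zero position falls back to
  uniform).
* `pseudo`: `(1−λ)`·one-hot + `λ/20`, requiring only the sequence.  The
  smoothing mass defaults to `λ = 0.2`; ambiguity codes (X, B, Z, U)
  get a uniform row with a warning.

When every `q` row sums to 1 the gap-`g` block sums to exactly
`L − g − 1` (one unit per admissible position pair) — a conservation
identity the tests exploit.  Profiles are read from the PSI-BLAST ASCII
dialect (44 fields per position row: index, residue, 20 log-odds, 20
percentages, information per position, relative weight); header text is
skipped by pattern so minor format drift across BLAST versions does not
break parsing.  The information-per-position column (second-to-last) is
kept and its mean serves as a profile-quality summary.  Obtaining
profiles is decoupled from the pipeline: a directory of precomputed
`<id>.pssm` files is consumed if given, and an optional wrapper can run
PSI-BLAST with either a conventional 2-iteration / e-value 0.001 preset
or an insensitive fast preset (BLOSUM80, word threshold 999, soft
masking, e-value 1e-5, gap open 9 / extend 2, 2 iterations).

## Correspondence analysis

The proteins × dipeptides table `N` (non-negative, no zero rows) is
analysed as a contingency table: `P = N/n`, masses `r = P1`,
`c = Pᵀ1`, standardized residuals `S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}`,
SVD `S = UΣVᵀ`.  Row principal coordinates `F = D_r^{−1/2}UΣ`, column
standard coordinates `Γ = D_c^{−1/2}V`, column principal coordinates
`G = ΓΣ`.  `Σσ_i²` equals the table's Pearson χ² divided by `n`, and
the mass-weighted centroid of `F` is the origin.

Numerical choices:

* All-zero columns (dipeptides absent from training) are dropped before
  fitting and recorded on the model; supplementary rows are restricted
  to the retained columns, and a row supported only on dropped columns
  is an error naming the row.
* Singular values below `max(1e−12·σ₁, dim·ε)` count as zero, so an
  exactly independent (rank-one) table has zero positive axes.
* Axis signs are arbitrary in CA; they are fixed by making the
  largest-magnitude column standard coordinate positive on each axis,
  so repeated fits are bit-identical.
* The retained dimension `k` is the smallest number of leading axes
  whose inertia share reaches the threshold (default 0.95), capped at
  the number of positive axes.

Supplementary (test) rows are projected through their profiles:
`coords = (row/Σrow)·Γ`, truncated to `k` axes.  On the positive axes
this reproduces a training row's principal coordinates exactly, which
the tests assert at 1e−10.

## Compact sets

Over the Euclidean distance matrix of the embedded points, a subset `C`
is compact iff `min external distance > max internal distance`, with
strict inequality (ties fail); the full set and singletons are
trivially compact and excluded from listings.

Enumeration is two-phase.  First the Kruskal merging-order tree is
built: edges are processed in non-decreasing weight (ties broken by the
lexicographic index pair; the verified output is provably and testably
tie-invariant even though the tree itself is not) and every edge that
joins two union-find components creates an internal node carrying that
edge's weight.  The merge heights coincide with single-linkage
clustering, and every compact set appears among the internal nodes'
leaf sets.  Second, each node is verified: its largest internal
distance — computed bottom-up from its children plus the cross-child
pairs; an equivalent least-common-ancestor charging scheme is kept
alongside and both must agree — is compared with the parent's merge
weight, which equals the set's minimum external distance.  Failed
candidates are contracted into their parents, leaving a laminar,
possibly non-binary tree.  A `2^N` brute-force enumerator provides an
independent oracle for testing (`N ≤ 15`).

## Classification and evaluation

Test points are embedded jointly with the training points (per-item
embedding is available as an option) and compact sets are enumerated
over the joint cloud.  A test point inside nontrivial compact sets
takes the largest one — uniqueness follows from laminarity — and is
assigned the label holding a strict majority among the set's *training*
members; test points never vote.  No containing set, no training
members, or no strict majority leaves the point unpredicted, and the
strictness is what preserves the tier's perfect-precision character.
The whole set `V` never votes (its majority would just be the global
mode), and singletons do not count as belonging to a compact set.
Unpredicted points fall back to the nearest training neighbour
(distance ties to the lowest training index; general `k`-NN is
implemented but `k = 1` is the default and the recommendation, since
choosing `k` per case is exactly the kind of tuning the method avoids).

Scoring: per class, precision `TP/(TP+FP)` and recall `TP/(TP+FN)`;
pooled accuracy `ΣTP/N`; `F = 2PR/(P+R)` from the pooled precision and
recall.  An unpredicted item is a false negative of its true class and
nobody's false positive, so the compact-set tier's precision is over
its own predictions while its recall is over everything — the
convention that makes "100 % precision at partial recall" a meaningful
row.  Cross-validation (default five folds) splits by a seeded uniform
permutation (stratified splitting available), refits CA on each
training fold, projects the test fold as supplementary rows, and pools
confusion counts across folds.

## Synthetic data

All fixtures are generated in-package, as pure functions of a seed:

* `worked_example_matrix` — the fixed six-item worked example with exactly
  three nontrivial compact sets and one failing candidate.
* `planted_compact_matrix` — block matrices whose blocks are compact by
  construction (within-block distances below a floor that all
  between-block distances exceed).
* `gaussian_cluster_dataset` — K isotropic unit-variance Gaussian
  clusters with centres on a circle whose neighbouring chord equals the
  requested separation; the default 5 × 40 points at separation 20 is
  the regime where the compact-set tier claims everything.
* `synthetic_protein_classes` — sequences drawn i.i.d. from a uniform
  residue background, with each class's signature dipeptides planted at
  Poisson-many extra positions so their expected count is `enrichment`
  × background.  Defaults: 3 classes × 30 sequences, enrichment 8,
  lengths 250–350 (typical protein lengths; chi-squared signal per
  signature column grows with length, so unrealistically short
  sequences would understate the separability of real corpora), 16
  signatures per class (tens of signature terms per class, matching the
  scale on which class-preferred dipeptides are reported for real
  localization data).

What the generators do *not* emulate: homology — real PSSM-weighted
features are strongly correlated across related proteins, which
concentrates CA inertia in far fewer axes than the i.i.d. background
noise here does — as well as realistic residue composition and
class-imbalance structure.  Passing the end-to-end recovery test
therefore shows that the implementation recovers planted
dipeptide-level class signal through the full feature → CA → CS+1-NN
stack; it does not certify accuracy on real proteomes.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
oracle equivalence on 200 random matrices of up to 10 items (the 2^N
oracle's comfort zone), CA identities on 200 random tables up to
8 × 11, the 200-point cluster simulation, and one 90-sequence
end-to-end run with the full 5 600-term vocabulary.  The whole suite
completes in well under a minute on one core.

## Known limitations

* Compact-set enumeration materialises the dense N × N distance
  matrix; fine for thousands of points, not for millions.
* The joint-embedding prediction mode lets test points influence each
  other's compact sets (never the labels, which come from training
  members only); the per-item mode removes this at k-fold cost.
* CA requires every protein to have positive feature mass; sequences
  shorter than two residues are rejected up front.
* The sigmoid transform treats PSSM log-odds columns independently;
  no attempt is made to model inter-position correlation.
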