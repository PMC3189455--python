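# Methods

## Structure representation

A protein chain is reduced to its C-alpha trace: one 3D point per residue,
labeled with one of the 20 standard amino-acid types. Nonstandard residues
(e.g. MSE) are dropped rather than translated, because the potential is
defined over exactly 20 types and any translation would be arbitrary; for
alternate locations the first-listed altLoc is kept (a deterministic choice
where the convention is otherwise unspecified); only the first model of
multi-model files is read. Residue ordering follows file order; the author
numbering is used only for gap reporting. Chain breaks are flagged when
consecutive C-alphas are farther apart than `max_gap` (default 4.5 Å, a
generous bound above the ~3.8 Å virtual bond of a continuous chain) or when
the author numbering jumps.

## Delaunay tessellation

The Delaunay tessellation of the C-alpha points (Qhull, via
`scipy.spatial.Delaunay`) partitions the convex hull into tetrahedra whose
four vertices are mutual nearest neighbors. Simplices are stored as sorted
1-based vertex tuples and the collection sorted lexicographically, making
tessellations byte-stable across runs. An optional maximum-edge cutoff
discards long boundary simplices; the default keeps everything, and the
cutoff is surfaced as an explicit parameter rather than a hidden constant
because the appropriate value is corpus-dependent. Degeneracy policy: truly
rank-deficient inputs (collinear/coplanar) are rejected with an error;
a cospherical degeneracy reported by Qhull triggers one seeded uniform
jitter of magnitude 1e-6 Å and a retry. Crystallographic coordinates are
essentially never degenerate; lattice-like synthetic fixtures can be.

## The four-body potential

For each unordered quadruplet composition (8855 multisets of size 4 over 20
types), the observed normalized frequency `f = count / total` over all
simplices of the training corpus is compared with the multinomial chance
rate `p = c · ∏ a_r^{t_r}` (`c = 4!/∏ t_r!`; `a_r` the corpus amino-acid
frequencies), giving the log-likelihood score `q = log(f/p)`.

Numerical choices:

* **Log base** — 10, recorded in the table. The base uniformly rescales all
  scores and downstream EC features and cannot change classifier decisions,
  but it must be fixed for reproducibility.
* **Unobserved compositions** — `log 0` is undefined, so zero-count keys are
  scored by a recorded policy: `"pseudocount"` (default) uses the add-one
  smoothed frequency `1/(total + 8855)`, giving a finite negative score for
  any key whose chance rate exceeds that smoothed rate; `"floor"` assigns a
  flat score (by default the minimum observed q). Stored `f` values remain
  the raw observed frequencies, so they sum to 1 over observed keys and
  observed-key scores are exactly `log(f/p)`.
* **Types absent from the corpus** — their `a_r` is 0 under the default
  (raw) frequencies, so every composition containing them has `p = 0` and
  can never be scored meaningfully; such keys get `q = 0` (no information).
  An optional `aa_pseudocount` adds mass to every type for tiny corpora.
  At the corpus sizes the generator produces, all 20 types are present and
  neither fallback is exercised.
* The table serializes to a delimited text file sorted by key; retraining
  on the same corpus is byte-identical.

## Computational mutagenesis

A residue's environment score sums `q` over its incident simplices; the
vector over the chain is the potential profile. A single-site mutant reuses
the **frozen wild-type tessellation** — only the amino-acid label at the
mutated vertex changes, so only incident simplices change their score. The
residual profile (mutant − wild type) is computed directly from those
incident simplices; its nonzero entries (EC scores) are confined to the
mutated position and its tessellation neighbors, which the test suite
checks exhaustively against a brute-force recomputation. Re-tessellating
the mutant geometry is deliberately not offered: the representation is
defined on the wild-type frame, and feature vectors keep full chain length
(zeros included) so the classifier input dimension is constant.

## Transduction

The strategies wrap any base classifier exposing continuous scores in
(−1, 1). For the default random forest, the score is `h = 2v − 1` with `v`
the forest's probability for the active class (the vote proportion with
fully grown trees), clipped infinitesimally inside the open interval;
`h ≥ 0` maps to active. Reliability uses the strict inequality `|h| > 0.8`.
T1 stops when hard labels are unchanged between iterations or after
`max_iter` (default 20 — the cap is a named safeguard with no canonical
value). T2a/T2b freeze an example's label once it enters L. T2b replenishes
Q from the pool uniformly at random without replacement under the config
seed, holding |Q| at `q_size` (default 80) until the pool empties;
leftovers that are never reliable still receive their final-iteration hard
labels, flagged as never-annotated, because evaluation needs a prediction
for every example. L, Q and P are asserted pairwise disjoint at every
iteration boundary.

## Evaluation

Smart partitions group mutants by mutated position, shuffle each group
(seeded, over a canonical `(position, mut_aa)` order so input row order is
irrelevant) and deal round-robin from a seed-dependent offset; per position
the fold counts differ by at most one. Confusion matrices are pooled over
folds (micro-average) before computing per-run accuracy, sensitivity and
specificity, and summaries are means and standard deviations across runs —
the fold-level aggregation convention is otherwise unconstrained, and
micro-averaging keeps every example weighted equally. Inside
cross-validation, T2b splits the test fold (seeded shuffle) into an initial
Q of `q_size` and the remaining pool P. A fold whose training side
collapses to one class aborts that run with a warning rather than skewing
the averages.

## Synthetic data

The generator stands in for external inputs and defines the study
conditions of the tests:

* **Backbones** — self-avoiding random walks with exact 3.8 Å steps,
  directional persistence, and a 4.0 Å self-avoidance radius for
  non-adjacent residues. Walks rather than lattices keep points in general
  position (lattice Delaunay is degenerate). They emulate chain
  connectivity and packing density, not secondary structure, so passing
  tests demonstrate correct computation on realistic point geometry, not
  biological accuracy.
* **Corpora** — independent walks from per-structure subseeds; a
  composition bias option produces enriched amino-acid frequencies for the
  nonrandom-clustering smoke tests.
* **Mutant panels** — the `"ec-sum"` rule thresholds the residual-profile
  component sum at the `(1 − skew)` quantile over all 19N candidates, so
  the label signal lives in the features by construction (on a fixed
  tessellation the component sum is proportional to the EC score at the
  mutated site). `margin_sd` excludes candidates within that many standard
  deviations of the threshold, creating a separation margin; `noise` flips
  labels Bernoulli-wise. Two candidate-sampling schemes: `"uniform"`
  (stratified, hits the requested skew exactly, but can leave positions
  with a single mutant) and `"per-position"` (all eligible candidates of
  greedily chosen positions offering at least `min_per_position` of them),
  which reproduces the dense per-position structure of real mutagenesis
  panels — scanned positions carry on the order of a dozen mutants each —
  at a scaled-down ~6–7 mutants per covered position. The
  `"position-cluster"` rule instead marks a seeded subset of positions
  inactive-prone, giving coarser positional signal without needing a
  trained potential.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to finish in
minutes on one CPU while exercising every code path: corpora of 8–15
structures of 25–50 residues, an 80-residue target chain, panels of 300
mutants, 10-fold cross-validation with 1–2 runs, and forests of 100 trees.
The label-recovery checks use the noise-free `"ec-sum"` panel with
`margin_sd = 1.0` and per-position coverage — under those conditions
one-shot random forest and all three transduction strategies recover every
held-out label; with 10% label noise, accuracies drop to roughly the
high-80s and the incremental strategies track the one-shot ensemble.

## Known limitations

* The potential trained on synthetic corpora is statistically valid but
  biologically meaningless; reproducing a real potential requires a real
  structure corpus.
* Only single-site substitutions are represented; multi-site mutants,
  stability (ΔΔG) prediction, re-tessellation of mutant geometry, and
  weighted center-of-mass point placement are out of scope.
* Baseline learners beyond the bundled random forest scorer (boosting,
  SVMs, networks) are not re-implemented; any scikit-learn classifier can
  be adapted by wrapping it to the continuous-score contract.
* PDB reading covers single-model ATOM records; mmCIF and heteroatom
  chemistry are out of scope.
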