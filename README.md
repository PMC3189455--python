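# fourbody

Structure-based prediction of binary enzyme mutant activity from single-site
substitutions, for computational-mutagenesis and protein-engineering work.
The package implements the full representation-and-learning pipeline:

1. **Delaunay tessellation** of a protein's C-alpha trace (via Qhull), whose
   tetrahedral simplices define objective four-residue nearest-neighbor
   quadruplets.
2. **Four-body statistical potential**: for each of the 8855 unordered
   amino-acid quadruplet compositions, the log-likelihood score

   q<sub>ijkl</sub> = log ( f<sub>ijkl</sub> / p<sub>ijkl</sub> ),&emsp;
   p<sub>ijkl</sub> = c · a<sub>i</sub> a<sub>j</sub> a<sub>k</sub> a<sub>l</sub>,&emsp;
   c = 4! / ∏<sub>r</sub> t<sub>r</sub>!

   comparing the observed frequency f of the composition across a training
   corpus of tessellated structures with its multinomial chance rate p
   (a<sub>r</sub>: corpus amino-acid frequencies; t<sub>r</sub>: multiplicities).
3. **Computational mutagenesis**: a residue's *environment score* is the sum
   of q over its incident simplices; the per-chain vector is the *potential
   profile*. A mutant is modeled on the frozen wild-type tessellation by
   relabeling one vertex; the *residual profile* (mutant − wild type), the
   vector of environmental-change (EC) scores, is nonzero only at the mutated
   position and its tessellation neighbors and serves as the feature vector.
4. **Incremental transduction** over a base classifier with continuous
   confidence scores h ∈ (−1, 1) (random forest vote proportion by default):
   * **T1** — train on L, label all of Q, absorb it, iterate to convergence;
   * **T2a** — per iteration move only *reliable* examples (|h| > 0.8) from
     the test set Q into the labeled set L, until none qualify or Q empties;
   * **T2b** — T2a with Q held at a fixed working size (80) and replenished
     from a pool P, mirroring how wet-lab annotation accumulates over time.
5. **Evaluation**: position-balanced ("smart") k-fold cross-validation, so
   mutations at each sequence position appear on both sides of every split,
   with accuracy / sensitivity / specificity from pooled confusion matrices.

Real inputs (PDB structures, mutant panels with wet-lab activity labels) are
read from plain text; a seeded synthetic module generates self-avoiding-walk
backbones, training corpora and labeled mutant panels with controllable class
skew, separation margin and label noise, so the entire pipeline runs and is
tested offline.

## Worked example

```python
from fourbody import (
    SyntheticSpec, generate_corpus, generate_trace, generate_mutant_dataset,
    tessellate, train_potential, feature_matrix, cross_validate,
)

# 1. a training corpus of 15 synthetic C-alpha traces and the 4-body potential
corpus = generate_corpus(SyntheticSpec(n_residues=50, n_structures=15, seed=5))
table = train_potential((tessellate(t), t) for t in corpus)
n_obs = sum(1 for s in table.stats.values() if s.observed_count > 0)
print(f"potential: {table.total_quadruplets} simplices, "
      f"{n_obs}/{len(table.stats)} quadruplet types observed")

# 2. a wild-type target structure and 300 labeled single-site mutants
trace = generate_trace(SyntheticSpec(n_residues=80, seed=33))
tess = tessellate(trace)
mutants = generate_mutant_dataset(
    trace, table, 300, rule="ec-sum", skew=0.5, margin_sd=1.0,
    seed=13, tess=tess, coverage="per-position",
)
X, y = feature_matrix(trace, tess, table, mutants)
print(f"features: {X.shape[0]} mutants x {X.shape[1]} EC scores, "
      f"{(y == 1).mean():.0%} active")

# 3. 10-fold position-balanced cross-validation of incremental transduction
summary, _ = cross_validate(X, y, mutants, k=10, method="t2b", n_runs=2, seed=0)
print(f"T2b(RF): accuracy {summary.mean_accuracy:.2f}% "
      f"(std {summary.accuracy_std:.2f}), sensitivity {summary.mean_sensitivity:.2f}, "
      f"specificity {summary.mean_specificity:.2f}")
```

Output:

```
potential: 3518 simplices, 2583/8855 quadruplet types observed
features: 300 mutants x 80 EC scores, 50% active
T2b(RF): accuracy 100.00% (std 0.00), sensitivity 1.00, specificity 1.00
```

The potential line says the 15-structure corpus contributed 3518 tetrahedra,
populating 2583 of the 8855 possible quadruplet compositions (the rest are
scored by the recorded unobserved-key policy). Each mutant is an 80-component
EC-score vector, sparse outside the mutated site's neighborhood. On this
noise-free, margin-separated panel the T2b strategy recovers every held-out
activity label; with label noise or narrower margins accuracy drops
accordingly (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
fourbody simulate --out run/ --seed 5
fourbody train-potential run/corpus --out run/potential.tsv
fourbody featurize --structure run/target.pdb --mutants run/mutants.tsv \
    --table run/potential.tsv --out run/features.tsv
fourbody evaluate --matrix run/features.tsv --method t2b --k 10 \
    --n-runs 2 --out run/results
```

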