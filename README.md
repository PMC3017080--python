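# orfrate

Classify open reading frames (ORFs) into **high** vs **low** translation-rate
classes from sequence-derived and functional features, and identify which
features carry the signal.

Translation efficiency — the ratio of normalized ribosome-footprint read
density to normalized mRNA read density — varies widely between transcripts
and is a major reason protein abundance correlates only weakly with mRNA
levels. `orfrate` is a toolkit for asking, on any ORF collection with
measured (or simulated) translation rates: *which sequence and functional
properties separate efficiently translated ORFs from poorly translated
ones, and how well can the class be predicted from them?*

## What it computes

1. **Feature construction.** Each ORF is encoded as a named vector:
   - 64 codon usage relative frequencies;
   - network-neighborhood GO enrichment scores — for gene *g* and term *t*,
     `score = −log10 P(X ≥ x)` with `X ~ Hypergeom(N, K, m)`, where *N* is
     the ORF universe, *K* the term size, *m* = |{*g*} ∪ neighbors(*g*)| on
     the interaction network, and *x* the neighborhood/term overlap;
   - 132 protein descriptors: 20 amino-acid composition fractions plus
     composition–transition–distribution (CTD) blocks for secondary
     structure, solvent accessibility, hydrophobicity, polarizability,
     normalized van der Waals volume and polarity;
   - 24 one-hot values for the 3 nt flanking the start codon on each side;
   - 10 auxiliary values (CDS length, UTR lengths, folding free energies,
     protein abundance, half-lives, binding-protein counts).
2. **Class labels** by a median split of the continuous rates (low ⇔ rate ≤
   median).
3. **mRMR feature ranking**: greedy maximum-relevance/minimum-redundancy
   selection, `max_f [ I(f; y) − mean_{s∈S} I(f; s) ]`, with mutual
   information estimated on three-state discretized features.
4. **Classification and evaluation**: 1-nearest-neighbor with cosine
   distance `d(x,y) = 1 − ⟨x,y⟩/(‖x‖‖y‖)` under jackknife (leave-one-out)
   cross-validation; **incremental feature selection (IFS)** evaluates the
   top-*k* ranked features for *k* = 1…k_max and picks the subset at the
   accuracy peak.
5. **Point-biserial correlations** `r_pb = (M₁−M₀)/s · √(p(1−p))` report the
   direction of association between each selected feature and the class.

A deterministic synthetic-data generator (`orfrate.simulate`) emulates the
statistical structure of such a study — class-dependent synonymous codon
bias, a class-correlated gene module on a random interaction network with
module-specific GO annotation, noisy auxiliary features with missing
values — so the whole pipeline is testable without any external downloads.

## Worked example

```python
from orfrate import (
    SimulationConfig, generate_dataset, featurize, mrmr_rank,
    ifs, optimal_feature_set, point_biserial,
)

dataset = generate_dataset(SimulationConfig(n_orfs=120, seed=7, go_module_size=12))
matrix = featurize(dataset.records, dataset.network, dataset.annotations)
labels = dataset.truth.true_labels
print(f"{matrix.n_samples} ORFs x {matrix.n_features} features, "
      f"{labels.n_low} low / {labels.n_high} high")

ranking = mrmr_rank(matrix, labels, top_k=matrix.n_features)
curve = ifs(matrix, labels, ranking, k_max=60)
k_star, accuracy, features = optimal_feature_set(curve)
print(f"IFS peak: {accuracy:.1%} jackknife accuracy with {k_star} features")
for name in features[:5]:
    values, _ = matrix.column(name)
    print(f"  {name:<12} r_pb = {point_biserial(values, labels):+.3f}")
```

prints

```
120 ORFs x 270 features, 60 low / 60 high
IFS peak: 84.2% jackknife accuracy with 32 features
  rbp.count    r_pb = +0.476
  CGT          r_pb = +0.439
  GTC          r_pb = +0.301
  mrna.halflife r_pb = +0.455
  TTA          r_pb = -0.060
```

The generator planted signal in eight codon frequencies (via synonymous
codon-bias shifts), three GO terms and four auxiliary features; the ranking
puts planted features (`rbp.count`, `CGT`, `GTC`, `mrna.halflife`) at the
top, their positive `r_pb` matches the planted up-in-high-class direction,
and the peak accuracy far exceeds the ≈50% expected without signal.

The same workflow is available from the shell:

```bash
orfrate simulate --n-orfs 120 --seed 7 --out data/
orfrate run-all --cds data/cds.fasta --utr5 data/utr5.tsv --aux data/aux.tsv \
    --network data/network.tsv --annotations data/annotations.tsv \
    --rates data/rates.tsv --out report/
```

writing `ranking.tsv`, `ifs_curve.tsv` (+ a PNG of the curve),
`optimal_features.txt`, `point_biserial.tsv` and a `manifest.json` that
suffices to reproduce the run.

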