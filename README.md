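# netpclass

Network-based protein structural classification.

Protein domains with similar 3D structures often share function, and
hierarchical databases (CATH, SCOP) organise domains into structural
classes. `netpclass` addresses the supervised version of that problem: given
a domain's atomic structure, predict its structural class. Instead of
comparing raw coordinates, it converts each domain into a **protein
structure network (PSN)** — residues as nodes, an edge wherever two
residues' heavy atoms (C, N, O, S) come within a distance cutoff (4 Å
default, 6 Å variant) — and classifies proteins from network-level
descriptors of that graph. It is aimed at structural bioinformaticians who
want a uniform, leakage-free benchmark harness for structure-derived
features.

## The method

For a PSN G, the central descriptors are **graphlet counts**: the number of
occurrences c_i of every connected induced non-isomorphic subgraph type on
k nodes (1, 2, 6 and 21 types for k = 2, 3, 4, 5). Log features use
ln(c_i + 1); normalized features use c_i / Σ_j c_j. **Ordered graphlets**
additionally carry the total node order inherited from sequence positions:
each graphlet g expands into k!/|Aut(g)| ordered types (4 on 3 nodes, 38 on
4 nodes), so the feature couples 3D topology to sequence locality. Counting
is exact (ESU-style enumeration of every connected induced subgraph,
verified against brute-force oracles).

Baselines computed under the same harness: amino-acid composition (20-dim),
di-amino-acid composition (400-dim), the cutoff scanning matrix CSM
(contact counts at 151 cutoffs, 0.0–30.0 Å step 0.2), seven global network
statistics (`existing-all`), PCA-transformed and concatenated variants, and
the raw residue–residue minimum-distance matrix D (D_ij = min over
heavy-atom pairs) for a deep feed-forward classifier with seven hidden
layers.

Classification uses outer stratified 10-fold cross-validation; per fold, an
inner 10-fold search selects the L2 regularization strength from
[2⁻², …, 2²] for a one-vs-rest logistic regression, optionally after SMOTE
balancing of training folds, reporting accuracy and the multiclass Matthews
correlation coefficient (MCC). Methods are compared across PSN sets with
one-sided Wilcoxon signed-rank tests under a single Benjamini–Hochberg FDR
batch.

## Worked example

The built-in generator creates two structurally distinct synthetic classes
with identical sequence statistics — helix-like backbones (whose PSNs gain
i → i+3/i+4 contacts) and extended strand-like backbones (whose PSNs are
paths) — so composition is uninformative by construction while network
topology separates the classes:

```python
import netpclass as npc

specs = [
    npc.SyntheticClassSpec("helix", backbone_kind="helix", noise_sigma=0.3),
    npc.SyntheticClassSpec("extended", backbone_kind="extended", noise_sigma=0.3),
]
structures, table = npc.generate_dataset(specs, per_class_n=60, seed=7)
labels = [table[s.domain_id] for s in structures]

og34 = npc.compute_feature_matrix(structures, "orderedgraphlet-3-4")
results = npc.PSNClassificationModel(og34, labels).fit(seed=1)
print(results.summary())
```

```
Protein structural classification (cross-validated)
====================================================
PSN set:        -
Feature:        orderedgraphlet-3-4
Training mode:  proportional
Folds:          10    Seed: 1
----------------------------------------------------
Accuracy (%):    100.000 +/- 0.000
MCC:               1.000 +/- 0.000
----------------------------------------------------
 fold  accuracy  mcc  hyperparameter
    0     100.0  1.0            0.25
    ...
```

Ordered-graphlet features separate the two backbone families perfectly at
noise 0.3 Å (accuracy 100%, MCC 1.0 — the classes' PSN topologies barely
overlap), while the same protocol on `aacomposition` features hovers at
chance, since both classes draw sequences from the same distribution. The
same `fit()`/`summary()` shape drives the deep path:

```python
matrices = [npc.build_distance_matrix(s) for s in structures]
dl = npc.DistanceMatrixDLModel(matrices, labels).fit(seed=1)
print(dl.accuracy_mean)   # 100.0 on this benchmark
```

A command-line interface mirrors the library
(`netpclass synth | parse | psn | features | transform | integrate |
classify | dl | compare | run`), e.g.:

```bash
netpclass synth --classes helix,extended --n 60 --noise 0.3 --seed 7 --out data/
netpclass features --pdb-dir data/ --labels data/labels.tsv \
    --feature orderedgraphlet-3-4 --out og34.csv
netpclass classify --features og34.csv --labels data/labels.tsv --seed 1
```

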