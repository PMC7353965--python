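# Methods

## Overview

`netpclass` classifies protein domains into structural classes from network
representations of their 3D structure. A domain is converted into a protein
structure network (PSN): nodes are residues, and an edge joins two residues
whose minimum heavy-atom (C, N, O, S) distance is within a cutoff — 4 Å by
default, with 6 Å as a named variant for the wide-cutoff ordered-graphlet
feature. The weighted counterpart is the residue–residue minimum-distance
matrix D, with D_ij the minimum Euclidean distance over all heavy-atom pairs
of residues i and j.

PSNs are optionally screened by an admissibility filter — a single connected
component, diameter ≥ 6, and ≥ 100 nodes — applied as a separate pipeline
stage because classification can also be run without it. Classification
tasks ("PSN sets") are assembled from hierarchical class labels: a parent
class yields a task only if at least two of its child classes have at least
30 members each; smaller children are dropped.

## Features

* **Graphlet counts** (`graphlet-3-4`, `graphlet-3-5`): exact counts of
  connected induced non-isomorphic subgraphs on 3–4 or 3–5 nodes, reported
  as ln(c_i + 1) per type (the +1 guards zero counts; the base only rescales
  and is irrelevant to downstream linear classifiers). Normalized variants
  divide each count by the total instead.
* **Ordered graphlet counts** (`orderedgraphlet-3`, `orderedgraphlet-3-4`,
  plus normalized and 6 Å variants): graphlets whose nodes carry the total
  order inherited from sequence positions. Because the order is total, each
  order class of a graphlet g on k nodes is a distinct edge pattern on
  rank-labelled nodes, and g expands into exactly k!/|Aut(g)| ordered types
  (4 types on 3 nodes, 38 on 4 nodes). Ordered counting is what couples 3D
  topology to sequence locality — the package's central feature family.
* **Baselines**: amino-acid composition (20 components), ordered
  di-amino-acid composition (400 components, divided by the number of
  adjacent pairs so the vector is a distribution), the cutoff scanning
  matrix CSM (residue-pair contact counts at 151 cutoffs, 0.0–30.0 Å in
  0.2 Å steps), and `existing-all` (seven global PSN statistics: average
  degree, average distance, maximum distance, average closeness, average
  clustering, intra-hub connectivity, assortativity).
* **Weighted input**: the distance matrix itself, consumed by the deep
  feed-forward path.

Counting is exact, not sampled: connected induced subgraphs are enumerated
once each by ESU-style extension and classified through a precomputed
bitmask lookup; catalogs are canonicalised by the lexicographically minimal
adjacency encoding over node permutations, giving a deterministic type
order across runs and platforms. PSNs here are sparse and small (≲ 1000
nodes), so exactness costs little; every counter is verified against a
brute-force subset-enumeration oracle in the tests.

Two definitional choices deserve note. Intra-hub connectivity has no
universally fixed formula; here hubs are nodes with degree above mean + 1
s.d., and the statistic is the fraction of hub-incident edges with both
endpoints hubs (0 when no edge touches a hub). Assortativity is the Pearson
degree–degree correlation over edges, defined as 0 for regular graphs where
the correlation is 0/0.

## Supervised protocol

All hand-crafted features share one protocol, exposed as
`PSNClassificationModel(features, labels).fit(seed)`:

* outer stratified 10-fold cross-validation (fold sizes within one item,
  class proportions preserved up to rounding, deterministic under seed);
* per fold, an inner stratified 10-fold search over the regularization grid
  [2⁻², 2⁻¹, 2⁰, 2¹, 2²], ties broken toward the smallest value; grid
  values are passed as scikit-learn's `C` (the grid is symmetric in log
  space, so strength-vs-inverse conventions span the same set);
* one-vs-rest L2-regularized logistic regression on z-scored features
  (scaler fit on training folds only; regularized models need comparable
  scales across heterogeneous features);
* training mode `proportional` uses training folds as-is;
  `proportional+smote` first balances them with SMOTE — synthetic minority
  points v + u(w − v), u ~ U(0,1), w one of the k = 5 nearest same-class
  neighbours — applied inside inner CV folds as well, so hyper-parameter
  selection sees the same treatment as the final fit;
* metrics per held-out fold: accuracy (%) and the multiclass (Gorodkin)
  Matthews correlation coefficient, averaged over the 10 folds.

No held-out row ever reaches scaling, SMOTE, hyper-parameter selection or
fitting; the tests verify this by fingerprinting rows and logging every
training-side data access.

PCA transformation (centered, unscaled, matching `prcomp`-style defaults)
keeps at least 2 components and as few as needed to explain ≥ 90% of
variance, with a deterministic sign convention (largest-magnitude loading
positive). It is fit on the full feature matrix before cross-validation,
replicating the published procedure; this leaks the test distribution into
the transform, so a strict alternative — fitting PCA inside training folds —
is available by transforming within the protocol instead.

## Deep-learning path

The weighted-PSN path feeds the flattened upper triangle of D, padded or
truncated to a fixed size (pad sentinel 999.0 Å, distinguishable from any
real intra-domain distance), to a feed-forward network with one input
layer, **seven hidden layers** (ReLU) and a softmax output trained with
cross-entropy, using the same stratified 10-fold discipline, proportional
mode only. The network is built on scikit-learn's `MLPClassifier` (Adam,
early stopping on a 10% validation split of training data).

Architecture defaults are implementation choices, not literature facts: pad
size 128 (8128 inputs, sized to the 100–120-residue synthetic domains) and
hidden widths 256, 128, 64, 32, 16, 8, 4. All are configurable through
`DLConfig`; the seven-layer depth is the fixed design point.

## Method comparison statistics

Methods are compared across PSN sets by paired one-sided Wilcoxon
signed-rank tests (is method i superior to method j?), zero differences
dropped, exact null for n ≤ 25 and the continuity-corrected normal
approximation beyond. All ordered pairwise p-values form one
Benjamini–Hochberg FDR batch; cell (i, j) of the comparison matrix is the
q-value for i's superiority, with q < 0.05 the conventional threshold.

## Synthetic data

The generator emulates two structurally distinct backbone families with
identical sequence statistics:

* **helix** — anchors on a parametric helix (radius 2.3 Å, rise 1.5 Å per
  residue, 100°/residue). Four backbone-like pseudo heavy atoms per residue
  (N, CA, C, O) sit at fixed radial/axial offsets; the +2.0 Å axial
  carbonyl-oxygen offset gives the zero-noise chain i → i+3 and i → i+4
  contacts at 4 Å, the way real α-helices gain short-range heavy-atom
  contacts, so helix PSNs carry chords and short cycles.
* **extended** — a strand-like zigzag with 3.3 Å rise whose 4 Å PSN is a
  pure path (sequential contacts only).
* **mixed** — alternating helix/extended segments stacked along the chain
  axis, for variety in plumbing tests.

Residue counts are drawn uniformly from 100–120 (so filtered PSNs are
admissible), Gaussian noise of σ = 0.3 Å is added per coordinate, and
sequences are drawn uniformly from the 20-letter alphabet identically
across classes. Composition features are therefore uninformative by
construction while network features separate the classes — the benchmark
isolates exactly the structural signal the method claims to capture.

What the generator does **not** emulate: real bond geometry, side-chain
rotamers, tertiary packing, β-sheet hydrogen-bond ladders between distant
strands, or class-correlated sequence biases. Passing the benchmark shows
the pipeline recovers planted structural differences under noise; it does
not certify accuracy on real CATH/SCOP data, whose class boundaries are far
subtler.

## Problem sizes and numerical choices

The shipped benchmark uses 60 domains per class (120 total), chosen to
exercise the full 10-fold protocol with the minimum-class-size rule (≥ 30)
comfortably satisfied while keeping the whole suite desk-scale. The
acceptance script reruns catalog enumeration, both LR modes, the
composition control and the DL path on a fresh dataset at the same sizes.

Ties and degenerate inputs: "within cutoff" is inclusive (≤); equal
inner-CV scores pick the smaller regularization value; prediction ties pick
the smallest class index; all-zero count vectors map to all-zero features;
a zero-variance matrix is rejected by PCA; MCC of a degenerate
single-class confusion matrix is 0; all-zero paired differences give
Wilcoxon p = 1 with a warning. Multi-model PDB files keep the first model;
disordered atoms keep the highest-occupancy conformer (ties toward altloc
'A'); MSE is remapped to MET with the selenium dropped; other non-standard
residues are skipped with a warning.

## Known limitations

* Ordered graphlets are limited to 3–4 nodes, unordered to 2–5.
* The intra-hub connectivity definition is a documented stand-in (see
  above); published values computed with a different hub rule will differ.
* The DL path's layer widths and optimizer settings are package defaults,
  not tuned to any external benchmark.
* Large-scale database evaluation (thousands of real domains) is out of
  scope; the package is validated on analytic constants, brute-force
  oracles and the synthetic benchmark.
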