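# devtox

Developmental-toxicity QSAR models from 2D chemical structure.

Developmental toxicity — any interference with normal pre- or postnatal
development — is among the hardest endpoints to assess experimentally, and
regulatory frameworks such as REACH explicitly encourage *in silico*
(QSAR) alternatives. `devtox` is a toolkit for building and applying
binary structure–activity classifiers for this endpoint: a compound is
predicted as a developmental toxicant (**D**, merging FDA pregnancy
categories C, D and X) or a non-toxicant (**N**, categories A and B),
directly from a SMILES string or SDF file.

The package provides, end to end:

* **chem I/O** — SMILES/SDF parsing, salt/water curation (inorganic
  counter-ions and water fragments stripped, largest organic fragment
  kept), FDA-category → binary-class mapping;
* **2D descriptors** — constitutional atom/ring counts, functional-group
  counts, Burden-matrix extreme eigenvalues (BEH*wk*/BEL*wk*, property-
  weighted), Broto-Moreau/Moran/Geary topological autocorrelations
  (ATS/MATS/GATS), Kier–Hall electrotopological states (SsOH, SdssC,
  ShssNH, Gmin) and the cycle-information index Icycem — including the
  published 13-descriptor random-forest and 6-descriptor fuzzy-partition
  presets;
* **classifiers** — an Adaptive Fuzzy Partition (AFP) model written from
  scratch and a random forest (10 trees, depth 12), both with a
  statsmodels-style `Model(X, y).fit() → Results` interface;
* **descriptor selection** — the NoConstant90 pre-filter, a generic
  greedy/best-first wrapper search, and the Hybrid Selection Algorithm
  (genetic algorithm + stepwise refinement with a fuzzy-c-means
  class-purity fitness);
* **similarity & applicability domain** — a four-component Tanimoto
  similarity index (functional groups, atom counts, ring counts, hashed
  path fingerprints) and a three-tool AD battery: descriptor-range check,
  six nearest training neighbours, and a local prediction-error report;
* **validation** — rational (structure-sorted, class-preserving)
  train/test splitting, k-fold / leave-one-out / leave-several-out
  cross-validation, the seven standard classification metrics, and the
  similarity-group analysis comparing correctly and incorrectly
  predicted compounds.

## The models

**Adaptive Fuzzy Partition.** Descriptor space is partitioned
recursively: at each step the algorithm scans every (descriptor, cut)
candidate — cuts are midpoints between consecutive distinct training
values — and keeps the split maximising |O(left) − O(right)|, where the
subspace score O is the activation-weighted frequency of the toxicant
class. Each final subspace k becomes a fuzzy rule: per-axis trapezoidal
membership functions μ_ik (plateau q/w = 0.9 of the crisp interval,
support p/w = 1.2, so rules overhang their neighbours) combined with the
Min operator. A new compound P is classified by centroid
defuzzification,

    degree_c(P) = Σ_k act_k(P) · O_k(c) / Σ_k act_k(P),
    act_k(P) = min_i μ_ik(x_i),

and assigned to class c only when degree_c > 0.5. Compounds with any
descriptor outside the training range are reported as *not predictable*.
Defaults: ≤ 30 rules per class, ≥ 2 compounds per rule, ≤ 4 cuts per
axis.

**Similarity index.** For two molecules, four Tanimoto sub-indices are
computed — functional-group counts (FGs), the 13 atom counts (Cs), the
13 ring counts (Rs), each via u·v/(‖u‖²+‖v‖²−u·v), and a 1024-bit
depth-7 linear-path fingerprint (FPs) via c/(a+b−c) — and combined as
the weighted mean S = Σ wᵢ·subᵢ / Σ wᵢ (default weights 1,1,1,1), so
S ∈ [0,1] with S = 1 exactly for identical structures.

## Worked example

```python
from devtox.fixtures import toy_molecules
from devtox.descriptors import AFP_DESCRIPTORS, build_matrix
from devtox.afp import AdaptiveFuzzyPartition
from devtox.similarity import k_nearest

toys = toy_molecules()                       # 42 labelled toy structures
X = build_matrix(toys, list(AFP_DESCRIPTORS))
results = AdaptiveFuzzyPartition(X, toys.labels()).fit()

pred = results.predict_one(X.loc["aspirin"].to_dict())
print(pred.degrees, "->", pred.assigned_class)
for nb in k_nearest(toys["aspirin"], toys, k=3, include_self=False).neighbors:
    print(nb.id, round(nb.breakdown.s, 3), nb.experimental_class)
```

prints

```
{'D': 0.778, 'N': 0.222} -> D
salicylic_acid 0.733 D
benzocaine_like 0.719 D
nitrosalicylic_acid 0.673 D
```

i.e. aspirin activates toxicant-leaning rules with a defuzzified
toxicant degree of 0.78 (> 0.5, so class D), and its three most similar
training compounds — all experimentally toxicant-labelled — have
similarity scores around 0.7, placing it comfortably inside the
applicability domain.

The statistics engine renders the standard seven-metric table; for a
test set with TP = 39, TN = 10, FP = 7, FN = 2 it prints accuracy 84%,
FP% 41%, FN% 5%, PPV 85%, NPV 83%, sensitivity 95%, specificity 59%.

The same flow is available from the shell:

```
devtox fixtures toy-set --out toys.smi --labels-out labels.tsv
devtox train   --structures toys.smi --labels labels.tsv --model afp --out afp.json
devtox predict --input toys.smi --model afp --model-file afp.json \
               --train-structures toys.smi --train-labels labels.tsv --out preds.tsv
devtox validate --table table.tsv --model rf --scheme kfold --out stats.tsv
```

`predict` writes one row per input molecule (prediction, confidence,
remarks, six nearest neighbours); reruns on identical inputs are
byte-identical.

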