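# Methods

This note documents the models implemented in `devtox`, the numerical
and design choices behind them, what the synthetic fixtures emulate,
and the limits of what the test suite demonstrates.

## Problem setting

The endpoint is binary developmental toxicity. FDA pregnancy categories
are collapsed to two classes: A and B → non-toxicant (N); C, D and X →
toxicant (D). Because toxicant-class compounds dominate real
collections for this endpoint (roughly 2:1), classifiers trained on
such data are deliberately conservative — biased toward predicting
toxicity — and the toy fixture reproduces that imbalance (about 69%
class D).

Only 2D descriptors are used: 3D descriptors require geometry
optimisation, which breaks reproducibility from a bare SMILES input.
All descriptors here are functions of the molecular graph alone, so a
given structure always yields exactly one prediction.

## Curation

Multi-fragment inputs (salts, hydrates) are reduced by removing every
fragment that contains no carbon, any single-atom charged fragment, and
water; the largest surviving organic fragment is kept. This
operationalisation covers the counter-ion and hydrate cases
(Cl⁻, K⁺, H₂O) without stripping genuinely organic counter-ions.
Curation is idempotent, and a record reduced to nothing is dropped with
a logged reason rather than silently.

## Descriptors

* **Atomic properties.** Mass, polarizability, van der Waals volume and
  Sanderson electronegativity are tabulated per element
  (`atomdata.py`, table version 2024.1) and used scaled relative to
  carbon, the convention of the 2D-descriptor literature.
* **Burden eigenvalues.** The Burden matrix of the H-depleted graph has
  the carbon-scaled atomic property on the diagonal and
  0.1/0.2/0.3/0.15 for single/double/triple/aromatic bonds off-diagonal
  (+0.01 when an atom of the bond is terminal), 0.001 for non-bonded
  pairs. BEH*wk* / BEL*wk* are the k-th largest / smallest eigenvalues.
  Exact numeric agreement with closed commercial descriptor software is
  *not* claimed — formulas follow the standard published definitions.
  Two symbol/description conflicts in the published descriptor lists
  are resolved in favour of the symbol's systematic reading: BELv1 and
  BELv8 are computed as *lowest* eigenvalues (the BEL prefix) although
  the accompanying prose says "highest", and BELp2 as rank-2
  polarizability-weighted although its prose line duplicates the BELe1
  description.
* **Autocorrelations.** ATS (Broto-Moreau) sums w_i·w_j over unordered
  atom pairs at topological distance = lag; MATS (Moran) and GATS
  (Geary) are the standard spatial-autocorrelation coefficients over
  the same pair sets. A lag with no atom pairs yields 0 for ATS
  (an empty sum) but leaves MATS/GATS undefined (NaN), as does a
  zero-variance weight vector.
* **E-states.** Intrinsic state I = ((2/L)²·δᵛ + 1)/δ with L the
  principal quantum number, δᵛ the valence electrons minus attached
  hydrogens, δ the heavy-atom connectivity (taken as 1 for an isolated
  heavy atom so the limit case stays defined); the perturbation term is
  Σ_j (I_i − I_j)/(d_ij + 1)². Atom-type sums use SMARTS definitions:
  SsOH over hydroxyl oxygens, SdssC over non-aromatic =C< carbons,
  ShssNH over non-aromatic –NH– nitrogens; Gmin is the molecular
  minimum. The implementation is independent of RDKit's E-state module,
  which the test suite uses as a cross-check oracle.
* **Icycem.** The vertex cycle matrix convention is SSSR membership
  rows: atoms are grouped by identical ring-membership vectors and the
  index is the Shannon mean information −Σ(n_g/n)·log₂(n_g/n) over
  group sizes. Acyclic molecules and fully cycle-equivalent molecules
  (e.g. benzene) both score 0. The underlying matrix convention is not
  uniquely fixed in the descriptor literature; this choice is
  documented rather than canonical.
* **Path fingerprints.** Every simple linear path of 1–7 atoms is
  enumerated, labelled with element symbols (lower-case for aromatic)
  and bond symbols, canonicalised as min(forward, reverse), hashed with
  an 8-byte BLAKE2b digest and reduced modulo 1024. One bit per path,
  no folding — chosen for bit-exact reproducibility across platforms
  and runs.
* **Missing values.** A descriptor that is structurally undefined for a
  molecule (eigenvalue rank above the atom count, autocorrelation at an
  unpopulated lag) is NaN in the matrix. Model layers refuse NaN at
  training time and report NaN-bearing queries as outside the
  applicability domain, rather than imputing.

## Adaptive Fuzzy Partition

Training is an exhaustive, deterministic best-first partition of
descriptor space. Cut candidates are midpoints between consecutive
distinct sorted values within a node; split quality is the absolute
difference of the two children's toxicant-class frequencies; ties break
by descriptor column order, then lower cut. A branch stops when every
axis has used its 4 cuts, a child would fall below 2 compounds, no cut
improves, or the 30-rules-per-class budget is reached (best-first, so
the highest-quality splits are applied first).

Each leaf interval [lo, hi] of width w is fuzzified with a trapezoid
centred on the interval: plateau width q = 0.9·w, support width
p = 1.2·w, so each rule's support overhangs its neighbour by 0.1·w and
the rule scores can "see" neighbouring subspaces. An interval edge that
coincides with the training minimum or maximum stays crisp (membership
1 up to the boundary, 0 beyond); this realises the range-based
applicability domain exactly: queries strictly outside any training
range are not predictable. Rule class scores are activation-weighted
class frequencies over all training vectors with positive activation
(the published combining equations appear only as images in the source
material; the implementation follows their verbal definitions —
weighted average of activity values, classic centroid defuzzification).
With indicator encoding the two class scores of a rule sum to one, so
the defuzzified degrees sum to one and the 0.5 assignment threshold is
met by exactly one class unless the degrees tie at 0.5, in which case
no class is assigned.

Compounds the model declines to predict are excluded from confusion
counts (and reported separately): this mirrors the original workflow,
which removed the one test compound outside the model's descriptor
range before computing its statistics.

## Random forest

A stock ensemble (scikit-learn) pinned to the published configuration:
10 trees, maximum depth 12, seeded. Feature-subsampling settings beyond
trees/depth are library defaults. The value of this layer is the
contract (configuration, column checking, vote fractions, seeded
determinism, JSON sidecar), not the tree induction. Retraining
equivalence against the original models is not claimed: their
descriptor values came from closed software and are not bit-exactly
reproducible.

## Hybrid Selection Algorithm

Fitness of a descriptor subset: rows are standardised, split 75/25 into
sub-training and validation parts; fuzzy c-means (m = 1.5, tolerance
0.001, ≤ 30 iterations, 6 clusters) runs on the sub-training part;
each cluster's purity is its largest membership-weighted class
fraction; the index is the membership-weighted mean over clusters,
averaged between the sub-training part and the validation part scored
against sub-training majority classes. The index is bounded in [0, 1],
≈ max-class-fraction on uninformative subsets, → 1 on cleanly separated
classes. Because a single random split estimates it with sd ≈
0.02–0.03 — the same order as the stepwise thresholds — the fitness is
averaged over 5 partitions and is deterministic per subset (the
partition seed derives from the subset mask), so identical subsets
always score identically within a run.

GA phase: population 10, 8 initially active descriptors per chromosome
(uniform random without replacement), fitness-proportional selection,
single-point crossover at rate 0.8, bitwise mutation at 0.05, worst 10%
rejected per generation with the best chromosome kept (elitism), 10
generations. Stepwise phase on the best chromosome: accept an addition
when the fitness delta ≥ +0.02, accept a removal when the delta ≥
−0.02 (i.e. removals may cost up to 0.02 — a parsimony pressure),
repeated until no move qualifies; a visited-set guard prevents
add/remove cycles.

A consequence worth stating: on a table whose informative columns are
*redundant* (both shifted the same way, either sufficient alone), the
−0.02 removal rule will legitimately prune one of them. The
planted-recovery benchmark therefore uses the complementary-mechanism
generator (below), where each informative descriptor carries a
different sub-population's signal and pruning either one costs real
fitness. The multilevel-self-organisation selector used for the
original 13-descriptor list is not reimplemented (its algorithm lives
in references outside the source material); that list ships as the
`RF_DESCRIPTORS` preset instead.

## Similarity and applicability domain

The four sub-indices each lie in [0, 1]; the combined score is their
weight-normalised mean with configurable weights defaulting to
(1, 1, 1, 1) — the original weight values were never published, only
the requirement that S stay in (0, 1). Two all-zero count profiles
score 1 (identical absence), a documented convention. Neighbour
retrieval is an exact top-k sort with deterministic tie-breaking
(score descending, id ascending); a query is never its own neighbour
unless explicitly included.

The AD battery annotates rather than vetoes: the range check (closed
interval on training min/max), the six nearest neighbours, and the
local-error report (flagging above all false-negative neighbours —
"the model under-predicts toxicity nearby") all feed a free-text
remarks field, and a CLI flag can optionally convert out-of-domain
predictions to "not predictable". Training-set predictions used for
the local-error report are in-fit by default.

## Rational split

Compounds are sorted by a structural key — highest-priority matching
functional group (catalog order), halogen count, aromatic-ring count,
total bond order, ring count, atom count, id — and the test set is
drawn systematically (evenly spaced positions) from each toxicity
class's sorted list. The overall test size is floor(fraction·n),
allocated to classes by largest remainder; at n = 292 and 20% this
gives 58 test / 234 training compounds. The original class hierarchy
(from external software) is not enumerated anywhere public, so the
catalog-priority key is this package's own documented stand-in; the
published per-class test counts (17/41) differ by one compound from
largest-remainder arithmetic (18/40), which is within the ambiguity of
that unpublished hierarchy.

## Synthetic fixtures

`make_table` draws class labels at a configurable balance (default
0.31 non-toxicants, mirroring the endpoint's 91:201 ratio) and plants
`n_informative` columns whose class-conditional means differ by
`effect_size` standard deviations (default 3, the cleanly-separable
benchmark condition); remaining columns are label-independent noise.
`make_mechanism_table` instead splits the toxicant class evenly among
the informative columns and shifts only that sub-population per column
— no single column separates, emulating multiple independent toxicity
mechanisms. `toy_molecules` is a fixed set of 42 public-knowledge
structures (about 69% class D, with salt/hydrate entries to exercise
curation); its labels are illustrative, chosen to produce a plausible
class structure, not regulatory assignments.

What the fixtures do **not** emulate: real descriptor correlation
structure, activity cliffs, measurement noise in toxicity calls, and
the heterogeneity of a 292-compound regulatory data set. Passing tests
therefore demonstrate algorithmic correctness and the qualitative
phenomena (e.g. correctly predicted compounds sit nearer the training
set in similarity space), not field performance on new chemicals.

## Numerical choices and degenerate inputs

* Percent rendering is round-half-up to integer percent, matching
  printed-table granularity; metrics with zero denominators are NaN
  ("undefined"), never silently 0.
* The correct-vs-incorrect similarity comparison uses a two-sided
  Student's pooled-variance t-test by default (Welch optional); the
  original report does not state the variant, so the printed p-value is
  not treated as a reproduction target.
* Fuzzy c-means restarts (up to 5 re-seeds) on degenerate collapses; a
  point coinciding with a centroid gets crisp membership there.
* Single-class training input yields a degenerate one-rule AFP model;
  the random-forest layer rejects it.
* All stochastic components (RF, GA, FCM, CV folds, synthetic tables)
  are seeded; AFP training and the similarity stack are fully
  deterministic.

## Problem sizes

The benchmarks use n = 200 tables (160/40 held-out) for classifier
accuracy, n = 120 × 20 descriptors × 10 seeded runs for selection
recovery, and the 42-molecule toy set (26 with the full 13-descriptor
preset computable) × 10 seeded splits for the applicability-domain
contrast — sizes chosen so the full suite runs in well under a minute
of compute per experiment while keeping the measured rates stable
across seeds.

## Known limitations

* Descriptor values are standard-formula implementations, not bit-exact
  matches of the commercial packages that produced the original
  training matrices; consequently the original models cannot be
  reconstructed, only the algorithms.
* The AFP cut search is exhaustive and greedy; XOR-like interactions
  are partitioned suboptimally (guaranteed ≥ 3 rules, but not a perfect
  fit, given the 2-compound minimum per rule).
* The similarity weights and the functional-group hierarchy of the
  rational split are configurable stand-ins for unpublished originals.
* More than two classes are accepted by the data model but the AFP
  split criterion and score encoding are tuned for the binary case.
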