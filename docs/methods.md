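# Methods

This note records the models and procedures implemented in `ctibench`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Labels and preprocessing

Interaction records pair a compound (SMILES) with a protein (20-letter
amino-acid sequence) and an affinity under one of three measures.
Binarization thresholds, exposed in `io_data.Thresholds`:

| measure | hit (label 1) | non-bind (label 0) |
|---|---|---|
| KiBA score | value ≤ 3 | value > 3 |
| Kd (µM) | value < 10 | value ≥ 10 |
| binary | pass-through | pass-through |

KiBA scores grow with *weaker* binding, hence the ≤ direction; the Kd rule
is strict-less-than on the hit side, so exactly 10 µM is a non-bind.

Preprocessing removes: sequences > 1400 residues (the fixed height of every
target matrix), SMILES > 348 characters (the fixed height of the one-hot
encoder — public corpora quote both 348 and 350 as the cut; we filter at
348 so every surviving record is encodable), unparseable SMILES, and
duplicate (canonical SMILES, sequence, label) triples. Canonicalization
precedes deduplication so alternative spellings of one molecule collapse.
The operation is idempotent.

## Negative sampling

Targets in binding databases often have no recorded non-binders. For a
target *t* with binder set C_t (size m) and candidate set C′_t (size n),
every candidate's distance-to-set is `min_j (1 − Tanimoto(d_j, d′_i))` and
the k most distant candidates are paired with *t* as negatives. The
selection is required (and property-tested) to agree exactly with an
exhaustive O(n·m) evaluation.

Open parameters and our choices:

* **Fingerprint** — Morgan, radius 2, 2048 bits (the de-facto default for
  similarity work); configurable in `NegativeSamplingSpec`.
* **k per target** — default `min(n, round(2.5 m))`, which places the
  global negative:positive ratio inside the 1.9–3 band observed on
  benchmark folds; override with an explicit `k`.
* **Ties** — broken by lexicographic compound id, so runs are deterministic.
* **Tanimoto of two all-zero fingerprints** — defined as 1 (identical
  vectors), so featureless candidates rank last, never first.
* Generated negatives are guaranteed not to duplicate a positive pair *of
  the same target*; candidates may bind other targets (the per-target
  formulation decides only against the given target's binder set).

## Rotatable-bond filters

`rotatable_bond_profile` uses strict rotatable-bond counting (single,
non-ring bonds between two non-terminal heavy atoms; amide C–N excluded)
and counts all heavy-atom bonds in the denominator. LRB keeps
`n_rotatable ≤ 10` (inclusive); RRB keeps `rbf ≤ 0.184` (inclusive). A
compound with no bonds has RBF 0 by convention (trivially rigid, passes
RRB). Both filters are idempotent and order-preserving.

## Splitting scenarios

**Warm-start** (shared entities across folds): each entity's records are
shuffled with the seeded generator and dealt round-robin from a per-entity
random starting fold. Any entity with ≥ n_folds records therefore appears
in every fold, and fold sizes are balanced to within the number of
entities. The per-entity random offset avoids all entities dumping their
first record into fold 0.

**Cold-start** (disjoint entities across folds): entities sorted by
descending record count (ties by id) are assigned whole to folds visited
cyclically; a fold already at or over capacity is skipped. Capacity
defaults to `ceil(N / n_folds) × 1.007` — the 0.7 % slack generalizes the
printed budget of 34,000 used for a 337,526-record corpus at 10 folds. An
entity larger than the capacity cannot fit anywhere; it is assigned alone
to the emptiest fold and flagged in `FoldAssignment.oversized_entities`.

**Mutation-aware**: train = wild-type records, test = mutant records.
The similarity report lists each mutant target's 10 most similar wild-type
targets with their training record counts.

**Sequence similarity**: global Needleman–Wunsch alignment (Biopython's
`PairwiseAligner`), default scoring match 1 / mismatch 0 / gaps 0,
normalized by the larger self-alignment score. This yields a symmetric
score in [0, 1] with 1.0 exactly on identity, and > 0.95 for a single-point
mutant of a ≥ 100-residue protein — the semantics the mutation report
relies on. Substitution matrices can be supplied through the `scoring`
config; normalization then uses the larger self-score, which keeps the
range and symmetry.

**Label reversal**: for every compound present in both sets, the validator
checks that its test labels are disjoint from its train labels and reports
per-compound train/test occurrence counts per label.

## Compound features

* **SMILES one-hot** — (348, 98). The 98-symbol table is frozen: the 94
  printable non-space ASCII characters plus 4 reserved columns (the
  encoder's fixed width leaves room for future tokens). Two-letter element
  symbols are encoded character-wise. Unknown characters raise; silent
  remapping would corrupt one-hot semantics. Encoding is applied to the
  canonical SMILES, and `true_length` is recorded for masking.
* **2D fingerprint** — Morgan(1024) ⊕ MACCS(167) ⊕ RDKit topological(1024)
  ⊕ AtomPair(1024) = 3239 bits, with segment offsets recorded.
  "RDKit-2D at 1024" is read as the topological (path-based) bit
  fingerprint folded to 1024 — the descriptor set has no natural 1024
  length.
* **Conformer fingerprints** — (3, 2048). Conformers come from ETKDG
  distance-geometry embedding with a fixed seed, force-field minimized
  (MMFF, falling back to UFF), energy-sorted, first 3 kept. Each conformer
  is hashed by an iterative shell fingerprint written in-package: level-0
  identifiers hash per-atom invariants; at level L each atom's identifier
  is rehashed (CRC32 over packed integers, independent of the interpreter's
  hash seed) with the sorted identifiers and bonded-flags of all atoms
  within L × 1.718 Å; all identifiers from 5 levels fold into 2048 bits.
  This follows the growing-spheres idea behind extended 3D fingerprints.
  Rows beyond the generated conformer count stay zero.
* **Atom graph** — nodes in canonical atom order with 34-d features:
  atom type 10 (C,N,O,F,P,S,Cl,Br,I,other), heavy-atom degree 7 (0–6,
  clamped with a log warning), formal-charge flag 1, hybridization 6
  (SP…SP3D2, other), possible-chiral-center flag 1, radical flag 1,
  aromatic flag 1, CIP R/S 2, attached hydrogens 5 (0–4, clamped).
  Degree counts all heavy neighbors by default; `degree_mode="carbon"`
  restricts to carbon neighbors for the alternative reading of
  "number of carbons attached".

## Target features

* **One-hot** — (1400, 20) over the canonical alphabet; non-canonical
  residues raise.
* **Physicochemical PCA** — a 20 × P amino-acid property table (P ≥ 20;
  nominally 512 AAindex-style columns) is z-scored per column and reduced
  to 20 principal components, fitted on the 20 residue rows so the mapping
  is a sequence-independent lookup. Component signs are fixed by making
  each component's largest-magnitude loading positive. Because z-scoring
  centers the 20 rows, the table's rank is at most 19: the 20th component
  carries numerically zero variance and is kept only to preserve the
  stated 20-dim width; the rank precondition therefore demands rank ≥ 19.
  The shipped property table is generated synthetically (`synthetic.
  synthetic_property_table`, 20 × 512, seeded latent-factor structure) so
  tests need no download; it is labelled synthetic and is not measured
  physicochemical data.
* **Residue interaction graph** — consumed as a typed contact list
  (computing geometric contact typing from 3D structures is out of scope).
  Edge weights come solely from the dissociation-energy table: disulfide
  167, ionic 20, hydrogen 17, π-cation 9.6, π-π 9.4, van der Waals 6
  (kJ/mol-scale constants used as relative interaction strengths).
  Self-loops and unknown types raise; duplicate undirected contacts
  collapse.
* **External embeddings** — per-target vectors are loaded from TSV and
  validated against the declared scheme width (768 BERT-style, 1900
  UniRep-style, or custom); the toolkit never runs the language models.

## Model architectures

All layers are NumPy with explicit forward/backward passes (float32).

**Graph attention (GATv2-style, single head).** Scores
`e_ij = aᵀ LeakyReLU(W_l f_i + W_r f_j)` (slope 0.2), softmax over each
node's neighborhood, update `f′_i = σ(Σ_j α_ij W_r f_j)`. Applying the
linear map before the nonlinearity gives dynamic attention; the update
uses the neighbor-side map W_r. Choices: σ is ELU (configurable);
isolated nodes receive a self-loop so the softmax is defined (padded
residue rows would otherwise produce 0/0); when the graph is weighted,
edge weights multiply the attention scores before the softmax
(`edge_weight_mode="none"` disables). The vectorized layer is
property-tested against a scalar loop oracle at 1e-6.

**Conv/pool towers.** Single-channel 2D stages following
`floor((H − K + 2P)/S) + 1`:

* physicochemical target tower: (1400, 20) → conv (603, 8) p=1 →
  (800, 15) → pool (201, 4) stride 1 → (600, 12) → conv (303, 7) p=1 →
  (300, 8) → pool (101, 4) stride 1 → (200, 5) → flatten 1000;
* conformer tower: (3, 2048) → conv (3, 501) p=1 → (3, 1550) →
  pool (3, 5) with *kernel-sized* stride → (1, 310). A stride-1 pool
  cannot produce the 310-wide output this tower is defined by, so
  non-overlapping pooling is used for this tower only.

**Fingerprint MLP.** 3239 → 2048 → 512 → 128, ReLU on the hidden layers,
affine output.

**Graph-attention target encoding.** Two attention layers (widths 8 then
4) over the 1400-row padded residue graph; flattening gives 5600-d.

**Global-window target tower.** Residues are looked up in a trainable
embedding table (row 0 = pad); per window size a filter bank slides over
the sequence and a global max-pool keeps each filter's best response;
windows extending into padding are masked and can never win the max.
The table initializes either uniformly at random or from the L2-normalized
projected physicochemical vectors (`phys_init_embeddings`).

**Pair classifier and training.** Compound and target towers each emit a
128-d representative vector; the 256-d concatenation passes through FC
layers (default 256 → 64 → 2) to a softmax. Loss is binary cross-entropy
with probabilities clipped to (1e-7, 1 − 1e-7); the optimizer is SGD with
classical momentum (defaults lr 0.01, momentum 0.9, batch 32 — the head
widths and optimizer settings are not pinned by any reference and live in
`TrainConfig`). The seed fully determines initialization and batch order;
zero epochs returns the initialization; a non-finite loss aborts with
diagnostics. Tower inputs should be column-standardized
(`standardize_features`): raw fingerprint bit vectors put plain SGD near
its stability edge, while standardized inputs train to convergence at the
default learning rate.

**No-signal control.** The sanity control for a learnable dataset is a
*label-ambiguous* copy: every pair duplicated once with each label. Its
irreducible cross-entropy is exactly ln 2 whatever the model capacity, so
convergence to ln 2 is a capacity-independent check; an independently
shuffled-label copy would not serve here, because a high-capacity network
can memorize arbitrary labels on distinct inputs.

## Evaluation

Threshold metrics use 0.5 on the positive-class probability (the 2-neuron
softmax output). AUPR is step-integrated (average precision) — trapezoidal
integration differs in the third decimal and is not used; AUROC is
trapezoidal. Degenerate confusion matrices (single-class predictions or
labels) define MCC as 0 rather than NaN; single-class test labels leave
AUPR/AUROC undefined and such folds are flagged and excluded from the
cross-validation aggregate for those two metrics. The random baseline
draws labels Bernoulli(prevalence) and scores uniform(0, 1); its AUPR
converges to the prevalence and its MCC to 0.

## Synthetic data

The generator emulates the *structure* of CTI corpora, not their physics:

* compounds from a fragment grammar (rings, chains, polar groups) —
  always parseable, canonical, with rotatable-bond counts spanning rigid
  to > 10;
* targets as uniform random sequences (80–200 residues by default);
  mutants as single-point substitutions of a generated wild-type, which
  puts their alignment similarity above 0.95 for ≥ 100-residue proteins;
* labels from a planted co-occurrence rule — a trifluoromethyl
  substructure on the compound side and a rare 5-mer motif on the target
  side — so both compound-side and target-side extractors can in
  principle learn the signal; optional label noise and a prevalence
  control; affinities drawn consistently with the label under the chosen
  measure's threshold;
* random typed residue contacts (disulfide only between cysteines).

What passing tests on this data do **not** show: generalization to real
chemistry (fragment-grammar molecules are far simpler than medicinal
compounds), realistic affinity distributions, sequence homology structure,
or true contact geometry. The fixtures exercise the machinery, not the
science of any particular corpus.

Default desk-scale problem sizes: ~200 pairs over 40 compounds × 12
targets for learnability checks, 100,000 draws for the random baseline,
1,000 random instances (n, m ≤ 30) for the negative-sampling oracle sweep.
These sizes make the full suite complete in about a minute while keeping
every check statistically meaningful at its stated tolerance.

## Known limitations

* The neural layers are CPU NumPy; they are reference implementations for
  correctness and desk-scale experiments, not a training framework for
  337k-record corpora.
* The conv/pool and graph-attention towers expose untrained forward passes
  (their architectural geometry is the testable content); end-to-end
  gradient training covers the dense towers and head.
* The conformer shell fingerprint is this package's own implementation of
  the growing-spheres idea; its bit assignments are not interchangeable
  with any external tool's output.
* Contact typing, protein language models and structure prediction are
  consumed as files, never computed.
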