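# Methods

## Problem setting and assumptions

`posescore` treats binding-pose prediction as supervised rescoring: a
docking program proposes up to 20 poses per complex, and a classifier is
trained to recognize which of them are near-native. Two structural
assumptions run through the package:

1. **Common frame.** Docked poses, the crystal reference, and the receptor
   share one coordinate frame. No superposition is performed anywhere —
   neither before RMSD nor before featurization. For re-docking this holds
   trivially; for cross-docking it assumes receptors were aligned upstream.
2. **Heavy atoms only.** Hydrogens are discarded on input. Attached-H
   counts used by the connectivity typing come from implicit-valence
   completion of the heavy-atom bond graph, never from explicit H atoms,
   so results do not depend on whether input files carry hydrogens.

## Symmetry-corrected RMSD

The label-defining quantity is the minimum in-place heavy-atom RMSD over
all isomorphisms of the element-colored bond graphs of pose and reference.
Bond orders are deliberately excluded from the coloring: perceived orders
differ across file dialects and toolkits, and a coloring that used them
would make the label depend on the parser. Enumeration is capped at
10,000 mappings; beyond the cap a per-element Hungarian assignment on the
distance matrix is used (a lower bound; a warning is emitted). For
drug-like molecules the cap is never reached — benzene has 12
automorphisms, and even highly symmetric fragments stay far below 10⁴.

A pose is near-native iff RMSD < 2.0 Å, *strictly*: a pose at exactly
2.0 Å is a decoy. Crystal poses are assigned RMSD 0 by definition.

## Atom typing and the two vocabularies

Each atom's connectivity type is the key
`element;total-valence;heavy-neighbors;attached-H;aromatic;ring`
(RDKit valence model). The pair-count features are then counts of
(protein type, ligand type) pairs within 6.0 Å, **inclusive** — the
boundary convention is chosen for determinism and matches common
implementations.

* **Protein side (22 types).** Derived, not curated: all distinct keys
  over {C, N, O, S} occurring in capped amino-acid templates
  (acetyl-X-N-methylamide, so backbone atoms carry in-chain valences).
  The template set covers the protonation states structure-preparation
  pipelines assign — physiological side-chain charges plus protonated
  histidine and the neutral guanidine form of arginine — and yields
  exactly 22 distinct types. The same templates provide the
  (residue, atom name) → type lookup used for PDB atoms, and the
  hydrophobic/donor/acceptor annotations used by the energy terms.
* **Ligand side (71 types).** The reference ligand corpus behind the
  published 71-type vocabulary is external data, so the package ships a
  synthetic stand-in: the set of distinct keys over the 9-element ligand
  alphabet occurring in a built-in corpus of ~110 hand-written drug-like
  fragments, which has exactly 71 members. Atoms whose type falls outside
  either vocabulary are ignored with a logged tally, so the stand-in
  changes which rare atoms are counted, not the feature geometry
  (22 × 71 = 1562 columns either way).

## Energy terms

The five empirical terms are evaluated on the surface distance
d = r − (Rᵢ + Rⱼ) for pairs within r ≤ 8 Å:
gauss1 = exp(−(d/0.5)²); gauss2 = exp(−((d−3)/2)²); repulsion = d² for
d < 0; hydrophobic = a 1→0 ramp over d ∈ [0.5, 1.5] Å restricted to
hydrophobic-carbon pairs (carbon with no N/O/S neighbor); H-bond = a 1→0
ramp over d ∈ [−0.7, 0] Å restricted to donor–acceptor pairs (N/O;
donors additionally carry ≥ 1 hydrogen). Radii (Å): C 1.9, N 1.8, O 1.7,
S 2.0, P 2.1, F 1.5, Cl 1.8, Br 2.0, I 2.2; unknown elements fall back to
1.8 with a warning. These are the published functional forms; bit-parity
with any particular docking build is not a goal — parity with the
per-pair formula oracle to 1e-9 is, and is tested.

## Similarity-constrained splits

Ligand similarity is Tanimoto over hashed path-based topological
fingerprints; protein similarity is a match-only global alignment score
(equal to the longest common subsequence length) normalized by the longer
sequence length. The normalization is a package choice: it bounds the
value in [0, 1] and penalizes length mismatch.

Clustered CV links two complexes when protein similarity ≥ 0.5, or
≥ 0.3 with ligand similarity ≥ 0.9, takes connected components of the
linkage graph, and packs them largest-first into the currently smallest
of k folds (ties among components broken by smallest member id). Using
components rather than a flat clustering makes the cross-fold guarantee
*structural*: no cross-fold pair can satisfy the linkage predicate, which
the tests verify exhaustively. The cost is balance — one dominant
component degrades fold sizes, which triggers a warning rather than a
silent rebalance.

## Model construction

Features with training-set variance < 0.01 (strict) are dropped; the rest
are standardized with training-set statistics only. Missing docking ranks
(crystal poses, pooled multi-program sets) are NaN; the boosted trees
handle NaN natively during training, but a rank-using model *refuses* to
score rows with missing ranks — silent imputation would quietly change
the model's meaning.

Hyperparameters are selected by mean AUROC (RMSE for the regressor) over
5-fold CV **grouped by complex**, so poses of one complex never straddle a
tuning fold. The search is a seeded random sampler (tuner seed 123, model
seed 2399, 60 evaluations by default) over a declared space: max_depth
3–10, learning_rate 10^[−3,−0.5], n_estimators 100–1000, subsample and
colsample_bytree 0.5–1, min_child_weight 1–10, gamma 0–5, reg_lambda
10^[−2,1]. The sampled configurations and scores are kept as a tuning
history so the search is auditable. No class reweighting is applied by
default. With fixed seeds and single-threaded histogram tree building,
two runs produce byte-identical serialized boosters.

## Evaluation conventions

* Scores are oriented higher-is-better (probability of near-native).
* Reported Rs is −spearman(score, RMSD), so a good method is positive;
  the binding-funnel analysis reports the per-complex |Rs| within nested
  RMSD windows [0–2], [0–3], …, [0–10] Å, requiring ≥ 3 poses with
  variation per window.
* Top-k selection breaks score ties by docking rank, then pose order, so
  SR_k is deterministic.
* Intra-target statistics skip complexes where they are undefined (single
  class, < 2 poses, constant input) and report the skipped count rather
  than zero-filling, which would bias averages toward failure.
* Crystal poses are removed from test-time sets by default: success rates
  should reflect the docking program's own poses.
* Bootstrap resamples complexes (not poses), 1000 draws; paired
  comparisons use the two-sided Wilcoxon signed-rank test with p = 1.0
  when all differences vanish.

## The synthetic generator

The generator emulates the *geometry* of a docking study, not its
physics. A pocket is 30–80 heavy atoms of amino-acid fragments (template
local geometry, so every atom carries a valid residue/atom name and hence
a valid type) placed on a hemispherical shell with centroids 6–8 Å from
the origin; the reference ligand — drawn from an 18-molecule built-in
library spanning all nine ligand elements — sits at the pocket mouth.
Poses are rigid rotations plus a constant 0.05 Å per-atom jitter plus a
translation whose magnitude is solved so the identity-mapping RMSD hits a
prescribed target exactly (rotation about the centroid leaves the mean
displacement at zero, so magnitudes add in quadrature). Near-native
targets are drawn from U(0.3, 1.8) Å and drift in a random direction;
decoy targets from U(2.6, 8.0) Å and drift *away from the pocket*. That
displacement is the planted signal: contact counts and energy terms
separate the classes, while the ligand-only control cannot — the jitter
is constant by design precisely so that internal ligand geometry carries
no label information. Docking ranks order poses by RMSD plus N(0, 1.5 Å)
noise: informative but imperfect, like a real docking score. Defaults
(20 poses per complex, 48% positive fraction) mirror a re-docking
campaign in which roughly half the generated poses are acceptable.

What passing tests on this generator shows: the featurizers, splitter,
trainer, and metrics implement their definitions correctly, and the
learning machinery recovers a known interaction signal while the negative
control stays at chance. What it does not show: performance on real
complexes, where pose decoys differ from near-native poses far more
subtly than by displacement out of the pocket, and where pocket chemistry,
ligand flexibility, and label noise are all harder.

## Problem sizes

The recovery study runs 200 complexes × 20 poses with a 150/50
target-level split and a 5-evaluation tuning budget — large enough for
stable AUROC estimates on the held-out 50 complexes while keeping the
whole study in the minutes range on one CPU. Unit and property tests use
12–40 complexes; the oracle-equivalence checks use 100 independently
seeded complexes; the split-constraint check uses a 500-complex similarity
structure.

## Known limitations

* The ligand-type vocabulary is a stand-in with the correct cardinality,
  not the published list; models trained here are not weight-compatible
  with implementations using the original vocabulary.
* Protein atoms in nonstandard residues (and atoms like OXT) are ignored
  by the typed featurizers (tallied, not errored).
* The Hungarian fallback beyond the automorphism cap is a lower bound on
  the true symmetry-corrected RMSD.
* The hyperparameter sampler is random search, not a sequential
  model-based optimizer; with the same budget and fixed seeds it is
  reproducible and competitive, but selected configurations will differ
  from any specific sequential tuner.
* No protonation, charge assignment, or structure repair is attempted;
  inputs are taken as prepared.
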