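# Methods

## Problem and approach

`mmgx` predicts molecular properties and activities from SMILES while making
the model's reasoning inspectable at the substructure level. The same
molecule is presented to the network as up to four graphs of different
granularity, each graph is learned by its own backbone, and the attention a
virtual "super node" pays to each graph node during readout is re-used as an
explanation signal.

## Graph representations

Every representation is a reduction `R^x(G) = G^x(V^x, E^x)` of the
atom-level graph `G`; each reduced node records the set of atom indices it
covers (`atom_map`), which is what allows attention to be projected back
onto atoms.

- **Atom graph (A).** Heavy atoms / bonds. Node features: element one-hot
  over {C, N, O, S, F, Cl, Br, I, P, other}, degree one-hot (0–5), formal
  charge, aromatic flag, hybridization one-hot, attached-H count, in-ring
  flag (26 slots). Edge features: bond-type one-hot {single, double, triple,
  aromatic}, conjugation, ring flag (6 slots). This is a standard
  AttentiveFP-style featurization.
- **Pharmacophore graph (P), ErG-style.** Nodes typed by six pharmacophoric
  properties (H-bond donor, acceptor, positive, negative, hydrophobic,
  aromatic) plus a ring flag and covered-atom count. Each SSSR ring
  collapses to one node (aromatic rings typed aromatic, carbocyclic
  aliphatic rings hydrophobic; fused rings are joined by edges); maximal
  acyclic all-carbon runs of >= 3 otherwise-untyped atoms collapse to one
  hydrophobic node; every other acyclic atom becomes its own node. Atoms
  with no assignable type become untyped "linker" nodes (all six bits zero)
  so the topology survives. The donor/acceptor/positive/negative SMARTS are
  package choices (the reduction itself only fixes the six classes) and can
  be overridden per call; edges are unweighted — we do not carry ErG's
  topological-distance weights.
- **JunctionTree graph (J).** Clusters are SSSR rings, non-ring bonds
  (atom pairs), and junction atoms (atoms shared by >= 3 clusters, the
  standard junction-tree threshold). Clusters sharing atoms are linked with
  weight = shared-atom count and a maximum spanning tree is taken per
  component, which guarantees the output is acyclic while preferring the
  strongest overlaps. Node features: kind one-hot (ring/bond/junction),
  size, aromatic flag.
- **FunctionalGroup graph (F).** Greedy non-overlapping matching of a
  predefined ~38-entry SMARTS vocabulary (largest match first, ties by
  vocabulary order), then untouched rings, then leftover bonds as atom-pair
  nodes; every atom ends up covered. Node features: group-identity one-hot
  (+ generic-ring and atom-pair slots), size, aromatic flag. The vocabulary
  is config-replaceable — no predefined list can be complete.

Reduced graphs carry no edge features (uniform edges); the edge-feature
path of the backbone is only used for A.

## Network

Per representation: a linear encoder to `embedding_dim`; then
`message_passing_steps` rounds of edge-aware GIN message passing —
messages `relu(h_src + e)` summed over neighbours, the aggregate passed
through a per-step linear layer and a GRU cell updating the node state —
then a readout in which a virtual super node, initialised to the mean node
state, attends over all real nodes (single-head GAT-style scoring with a
softmax per graph) for `readout_steps` rounds, its state updated by a GRU
on the attention-weighted context. The final round's attention coefficients
are the per-node importance weights. Molecule embeddings from all
representations of a scheme are concatenated and a two-layer head produces
the prediction (sigmoid for classification). When a scheme combines A with
reduced graphs, each reduced node's raw features are first extended with the
sum of the raw atom features it covers (*initial pooling*).

Design choices where the architecture description leaves freedom:

- a **single attention head** at the virtual node, so attention is directly
  one weight per node (a multi-head variant would need an extra combination
  rule);
- virtual links are directional (real node -> virtual node); the super node
  does not broadcast back into node embeddings, keeping node embedding and
  readout separable;
- **no weight sharing** across representations — each graph is learned
  independently and fused only by concatenation;
- GIN edge conditioning is additive in the message (the common edge-aware
  GIN variant);
- defaults: `embedding_dim` 256, 2 message-passing steps for A, 1 for
  reduced graphs (coarser graphs need fewer hops), 2 readout steps.

The tensor backend is a small in-package reverse-mode autodiff engine over
NumPy float64 arrays with PyG-style disjoint-union batching and segment
ops. float64 makes fixed-seed CPU runs bitwise reproducible. Losses:
binary cross-entropy on logits / MSE; optimizer: Adam. Regression targets
are standardized on the training fold and predictions de-standardized
before RMSE.

## Training protocol

Random 80/20 train+validation/test split (not stratified), 5-fold CV on the
non-test part; the test set is fixed across folds and the mean of per-fold
test metrics is reported (an across-fold ensemble would be the
alternative). Up to 300 epochs with early stopping after 30 epochs without
validation improvement (improvement = strictly better by >= 1e-5);
best-validation weights are restored. Fold k trains with seed
`master_seed + k`. Metrics: AUROC (classification), RMSE (regression).

Model comparison across datasets uses AvgRank (rank 1 = best, ties get the
mean rank) and AvgZScore. The z-score uses the **sample** standard
deviation across models per dataset (two models at 0.9/0.8 give ±0.7071);
`population_std=True` switches to the population convention. Signs are
flipped for lower-is-better metrics so larger is always better; z-scores
sum to zero per dataset by construction.

## Interpretation stack

Per graph: raw virtual-link attention → min-max normalization → projection
onto atoms (an atom covered by several nodes receives the **sum** of their
weights) → min-max again; across the graphs of a scheme the atom vectors
are combined by the elementwise **maximum**. A constant vector has no
contrast and is mapped to 0.5 everywhere (neutral importance) — the
degenerate case is otherwise undefined. Fold aggregation normalizes per
fold first and then averages the per-fold vectors (normalizing after
averaging is the noted alternative).

Three views:

1. **Single prediction** — per-atom green-intensity depiction plus the
   numeric vector as JSON.
2. **Node features** — mean per-graph attention and occurrence count of
   every node-feature value over a (optionally prediction-filtered)
   dataset, scatter-plotted mean vs count. Multi-hot nodes contribute their
   attention to each active feature. The per-graph (not combined) attention
   is used because the view is about reduced-graph feature names.
3. **Potential substructures** — molecules are fragmented by cutting
   acyclic single bonds only (rings stay intact; pieces of 3–20 heavy
   atoms; up to 2 simultaneous cuts) with three cut-bond generators: BRICS
   bonds, RECAP cleavage-pattern bonds, and an exhaustive all-acyclic-bond
   "grinder". A fragment occurrence is important when the median attention
   over its atoms strictly exceeds the P_f percentile (default 75) of the
   molecule's atom attentions. Per fragment type,
   `Score_frag = mean_n (M_frag(n) − M_mol(n))` where `M_mol` averages over
   **all** atoms of the molecule (the literal reading; averaging over
   non-fragment atoms is the alternative). Selected fragments must have
   important-percentage >= 50%, important-compound count >= the P_s
   percentile (default 70) of all fragments' counts, and positive score;
   a surviving fragment that is a substructure of another survivor with
   equal-or-higher score is then pruned as redundant.

A caveat on monotonicity: because the support cutoff is a *relative*
percentile and redundancy pruning depends on the surviving set, the final
selection is not globally monotone in P_f/P_s. What does hold (and is
tested): importance flags never grow when P_f rises, and the pre-pruning
kept set never grows when P_s rises.

## Synthetic binding logics

Each task is a boolean SMARTS expression (AND/OR/NOT). Five built-ins:
Logic6 `[FX1] AND [CX3]=O`; Logic7 `[R0;D2,D1][R0;D2][R0;D2,D1] AND
[CX3]=O`; Logic9 `[NX3;H2] AND [OD2](C)C AND
[cX3]1[cX3H][cX3H][cX3H][cX3H][cX3H]1`; Logic14 `([OD2](C)C OR NOT [OX2H])
AND [CX3]=O AND NOT [CX2]#[CX2]`; 3MR `*1**1`. Ground truth for a positive
molecule is the union of matched atoms of the positively required leaves,
one alternative mask per combination of leaf matches (capped at 32
alternatives); NOT-leaves are absence constraints and contribute no atoms.

The generator assembles molecules from a fragment grammar: a random
scaffold (alkyl chain C3–C8, benzene, cyclohexane, cyclopentane, pyridine)
plus random substituents from a fixed pool, with the logic's own trigger
pieces force-attached for intended positives and avoided for intended
negatives; candidates are rejection-sampled until the intended label is
confirmed by the evaluator itself, alternating classes for a ~50/50
balance. Defaults: 8–25 heavy atoms (typical drug-like size). What the
generator does **not** emulate: real chemotype diversity, activity cliffs,
assay noise, or label imbalance — a green end-to-end test establishes that
the architecture and interpretation stack can recover a known, cleanly
separable logic, not performance on pharmaceutical data.

Attention evaluation on positives predicted positive (probability >= 0.5):
AttAUROC (AUROC of the combined atom attention as a scorer of mask
membership) and AttACC (fraction of atoms whose thresholded attention,
>= 0.5 = important, matches the mask), each maximised over alternative
masks, averaged within fold and then across folds (std across folds
reported). Eq.-style metrics are applied to the final combined normalized
vector (applying them per fold before combining is the noted ambiguity).

## Numerical and degenerate-input conventions

- Min-max of a constant vector → 0.5 everywhere; atoms covered by no node
  get 0 before normalization.
- Percentiles use linear interpolation; the importance rule is strict
  (`>`), the support rule inclusive (`>=`).
- Duplicate molecules (same canonical SMILES, stereochemistry kept) with
  agreeing targets collapse to one record; conflicting targets (any
  disagreement for classification, > 1e-9 for regression) remove the whole
  group. Molecules with no bond or a single heavy atom are dropped;
  multi-fragment SMILES are kept but logged.
- AUROC is an error on single-class targets; attention masks covering no or
  all atoms are skipped as unscorable.
- Early stopping with zero improvement tolerance would never trigger on
  noisy metrics; the 1e-5 tolerance is deliberate.

## Scaled-down test defaults

The production defaults (embedding 256, 300 epochs, 5 folds) are kept on
the API. The test suite and the acceptance script shrink only scale —
embedding 16–48, 2–3 folds, <= 50 epochs, 120–2000 generated molecules —
so the whole suite runs on one CPU in minutes. These reductions change
runtime, not the contracts being checked.

## Known limitations

- Only the custom GIN+GRU/GAT-readout backbone is shipped; the encoder
  abstraction admits other backbones but none are implemented.
- The pharmacophore SMARTS and functional-group vocabulary are reasonable
  defaults, not a curated standard; both are config-exposed.
- No hyperparameter search, no GPU, no 3D conformers, no scaffold splits.
- The RECAP fragmenter is a cleavage-bond SMARTS approximation of the RECAP
  hierarchy (the reaction-based implementation does not expose atom sets).
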