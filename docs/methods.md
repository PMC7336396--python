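# Methods

This note documents the models, parameter choices and numerical conventions
behind `dtiwlnet`, and what the synthetic experiments do and do not show.

## The semi-bipartite network model

The data model is an undirected semi-bipartite graph: a bipartite
interaction layer (binary matrix Y, m drugs × n targets) and two complete
weighted intra-side layers given by similarity matrices S^D and S^T
(symmetric, unit diagonal, entries in [0, 1]). The two layers are
semantically different and are deliberately kept apart throughout:

- *Neighborhood* always means interaction edges. A drug's neighbors are its
  known targets and vice versa; similarity edges are never traversed when
  growing subgraphs, computing hop distances, or refining colors.
- *Similarity* enters only as (a) the ranking key when a subgraph hop must
  be truncated, (b) the weights of drug–drug and target–target cells in the
  encoded adjacency, and (c) the reliability score for negative sampling.

The similarity layers are treated as complete weighted graphs — no
threshold is applied to define discrete edge sets; a zero weight is simply
an absent edge. Validation symmetrizes similarity asymmetries up to 1e-6
(warning) and rejects anything larger; a non-unit diagonal is forced to 1
with a warning. All randomness everywhere flows from explicit integer
seeds; where a run has several stages, one root seed is fanned out via
`numpy.random.SeedSequence` (`stage_seeds`).

## Reliable negatives

Only positives are observed; negatives must be chosen among unknown pairs.
Each unknown pair gets s_ij = exp(−(s^DT_ij + s^TD_ji)), with s^DT_ij the
sum of S^T between t_j and every known target of d_i, and s^TD_ji the sum
of S^D between d_i and every known drug of t_j. The sums are raw — no
normalization by neighborhood size — so hub drugs/targets accumulate more
evidence against, which is the intended behavior. Scores lie in (0, 1],
equal 1 exactly for pairs with no relevant evidence, and the negative set
is the deterministic top of the descending ranking (ties broken by drug
then target identifier). The `ratio_alpha` knob sets positives/negatives:
1.0 balanced, 0.1 for the tenfold-negative regime, and the sentinel
`"all_unknown"` takes the entire complement.

## Subgraph extraction

Growth is breadth-first over interaction edges: anchors, then the full
first hop, then rounds in which the current frontier's unseen neighbors
form a pool ranked by similarity to the matching anchor (drugs by S^D to
the anchor drug, targets by S^T to the anchor target, compared directly on
the shared [0, 1] scale in one merged ranking; ties drugs-first, then by
identifier). Pool vertices are admitted until K is reached. Only the
mandatory first hop can overflow K; in that case the provisional subgraph
is ordered by Palette-WL and the lowest-ranked non-anchor vertices are
dropped. Subgraphs smaller than K are padded with all-zero placeholder
slots at the bottom ranks; placeholders carry no edges and are excluded
from refinement.

The anchor pair's own edge is always removed from the induced subgraph
before ordering and encoding. For positive training pairs this cell would
otherwise state the label outright; masking it (rather than dropping it)
keeps the vector length at exactly K(K−1)/2.

## Palette-WL ordering

Initial colors are the dense ranking of each vertex's geometric-mean hop
distance to the two anchors, √(d₁·d₂), computed over the induced
interaction edges; unreachable distances are capped at 2K. Both anchors,
and only they, have distance 0 and therefore color 1. Refinement iterates

    h(v) = c(v) + Σ_{u∈Γ(v)} log p(c(u)) / (1 + Σ_{u∈V} log p(c(u)))

with p(c) the c-th prime, then dense-reranks h, until the partition is
stable (at most 2·|V| iterations). The fractional term is strictly below
1, so a vertex can never overtake one with a smaller color: the initial
proximity order is preserved and refinement only splits ties. Residual
ties after convergence (automorphic vertices) are broken by initial color,
drug-before-target, then identifier — determinism and bijectivity are
contract requirements. Addends are summed in sorted order (`math.fsum`)
so results are bit-stable under any vertex storage permutation.

The two anchors are pinned to ranks 1 (drug) and 2 (target) even when
refinement could separate them: the encoded anchor cell must sit at the
same vector position in every subgraph for the classifier to compare
like with like. Since no other vertex shares initial color 1, this
touches only the anchors' relative order.

## Encoding and classifier

The ordered subgraph becomes a symmetric K×K matrix: 1 for induced
interaction edges, S^D / S^T for same-side cells, 0 for absent
interactions and padded slots, anchor cell forced to 0. The strict upper
triangle is flattened column-major ("vertically") into a K(K−1)/2 vector;
the flattening order is fixed and round-trips exactly.

The classifier is a fully-connected network with ReLU hidden layers
32/32/16 and a 2-class probabilistic output, implemented with
scikit-learn's `MLPClassifier` (for two classes its logistic output equals
a 2-way softmax). Only the architecture and activation are fixed by
design; the remaining hyperparameters are conventional, explicit and
overridable: adam, learning rate 1e-3, batch size 32, up to 100 epochs
with early stopping (patience 10, 10% validation split; disabled
automatically below 50 samples where a split is unreliable). Inputs
already lie in [0, 1], so no feature scaling is applied. Class weighting
is off by default — imbalanced regimes are evaluated as-is — but a flag
enables seeded minority oversampling.

## Evaluation protocol

Stratified 10-fold cross-validation over the assembled samples
(stratification guarantees positives in every fold at α ≤ 10%). For each
fold the test-fold positive edges are zeroed in the network before any
subgraph is extracted — train or test — so a test label can never leak
through topology; train-fold known edges remain. AUROC uses the
Mann–Whitney convention (ties half); AUPR is the step-wise
non-interpolated estimator (both via scikit-learn, verified in tests
against enumeration oracles). Summary is mean ± SD (ddof=1) across folds.

Baselines use similarity-weighted bipartite forms: PA = |T_d|·|D_t|;
CN = Σ S^D(d, D_t) + Σ S^T(t, T_d); Jaccard = CN/(|T_d|+|D_t|) with
0/0 → 0; Katz = Σ_{l=1..6} β^l (A^l) on the full (m+n)² weighted
adjacency with β = 0.01 (β well below the reciprocal spectral radius of
typical sparse inputs; both knobs configurable). The exact "modified"
CN/Jaccard variants used elsewhere in the literature are not published in
closed form; the adaptations here are documented choices, serving only as
comparison baselines. Heuristic cross-validation reuses the identical fold
splitter, so learned-vs-heuristic comparisons are paired fold-by-fold.

## Synthetic data: what it emulates, what it does not

`generate_network` draws unit latent vectors (dimension 8 by default) for
drugs and targets in a shared space; similarities are (1 + cos)/2 of
same-side latents, and the interaction probability of a pair is
logistic(assoc_strength · cos(u_d, v_t) + noise·ε + b). The intercept b is
calibrated by bisection so the realized density of Y matches the target
(±20%; the Bernoulli draw is repeated up to 25 times before declaring a
calibration failure). A held-out fraction (default 10%) of realized
interactions is zeroed in Y and returned as recoverable links. Defaults —
60 drugs, 80 targets, density 0.02, association strength 4, noise 0.1 —
give a sparse network (~95 interactions) whose guilt-by-association
structure mirrors the qualitative character of DrugBank-derived benchmark
data at a size where a full 10-fold CV runs in seconds.

What passing on this generator shows: the pipeline recovers planted
association structure from topology plus similarities, does not
manufacture signal from nothing (null control at association strength 0
sits at AUROC ≈ 0.5), and behaves in the expected direction under
negative-sampling and ablation changes. What it does not show: performance
on real chemistry — realistic similarity distributions (multi-modal,
heavy-tailed), hub degree distributions, assay biases and redundant
homologous targets are all absent, so absolute metric values here do not
transfer to real data.

The null control uses *random* negatives deliberately: reliability-ranked
negatives are an extreme subpopulation by construction, and a classifier
can separate them from random positives even on a signal-free network —
that is a property of the sampling scheme, not an artifact of the
pipeline. The reliable-vs-random comparison is run separately at α = 10%.

## Standard experiment conditions

The canned experiments (`dtiwlnet.experiments`, reused by
`scripts/acceptance.py`) all run at m=60, n=80, density 0.02, K=10,
10-fold CV: planted-signal recovery and ablation over 3 seeds with
balanced sampling, negative-sampling comparison over 3 seeds at α = 10%,
null control over 10 seeds. These sizes keep a complete run around half a
minute while leaving ~170–1000 samples per cross-validation, enough for
stable fold metrics.

## Known limitations

- Subgraphs larger than K are truncated, so the model may not see the full
  h-hop neighborhood of a high-degree pair; K trades coverage against
  input dimension (K(K−1)/2 grows quadratically).
- The fully-connected classifier consumes a flattened adjacency; it cannot
  exploit permutation symmetry beyond what Palette-WL ordering provides,
  and cannot ingest per-vertex side features.
- Reliability scoring assumes missing edges are mostly true negatives;
  in screening data missingness can be structured, which biases the
  negative pool.
- The refinement hash mixes colors only through interaction edges;
  similarity values influence ordering solely via the initial truncation
  ranking and the encoded cells.
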