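# dtiwlnet

Topology-based drug–target interaction (DTI) prediction. Given a sparse
binary drug–target interaction network enriched with drug–drug chemical
similarities and protein–protein sequence similarities, `dtiwlnet` scores
candidate (drug, target) pairs by *learning* the local network patterns that
surround interacting pairs, instead of relying on hand-picked heuristics
such as common neighbors or the Katz index.

It is aimed at computational drug-discovery practitioners who already have a
DTI matrix **Y** (m×n, binary) plus precomputed similarity matrices
**S**<sup>D</sup> (m×m) and **S**<sup>T</sup> (n×n) with values in [0, 1] —
e.g. Morgan-fingerprint dice similarities for drugs and normalized
Smith–Waterman scores for proteins — and want ranked interaction likelihoods
for unobserved pairs.

## Method

The three inputs define an undirected **semi-bipartite graph**
G = ⟨D, T, E, F, H⟩: drug vertices D, target vertices T, the known
interaction edges E = {(d_i, t_j) : y_ij = 1}, and complete weighted
intra-side edge sets F, H given by S<sup>D</sup> and S<sup>T</sup>.
For every candidate pair (d_i, t_j) the pipeline is:

1. **Reliable negative sampling.** Unknown pairs are scored
   s_ij = exp(−(s<sup>DT</sup>_ij + s<sup>TD</sup>_ji)), where
   s<sup>DT</sup>_ij sums the similarity of t_j to every known target of
   d_i, and s<sup>TD</sup>_ji sums the similarity of d_i to every known
   drug of t_j. High-scoring pairs — dissimilar to everything their partner
   is known to bind — are the most trustworthy negative training labels.
2. **Enclosing-subgraph extraction.** A K-vertex subgraph around the anchor
   pair: anchors, their first interaction hop, then further hops admitted
   in decreasing similarity to the anchors until K vertices are collected
   (overflow is truncated by the vertex ordering below). The anchor pair's
   own edge is always removed.
3. **Palette-WL vertex ordering.** Each vertex is colored by the rank of
   its geometric-mean hop distance √(dist(v, d_i)·dist(v, t_j)) to the two
   anchors, then colors are refined Weisfeiler–Lehman-style with an
   order-preserving prime-logarithm hash until the ranking is bijective.
   Structurally similar vertices of different subgraphs land at similar
   ranks, giving the classifier a consistent input geometry.
4. **Adjacency encoding.** The ordered subgraph becomes a K×K symmetric
   matrix (interaction edges → 1, drug–drug cells → S<sup>D</sup>,
   target–target cells → S<sup>T</sup>, anchor cell masked to 0) whose
   strict upper triangle is flattened column-wise into a K(K−1)/2 vector.
5. **Classification.** A fully-connected neural network with ReLU hidden
   layers of 32, 32 and 16 units maps the vector to an interaction
   probability. Evaluation is stratified 10-fold cross-validation reporting
   AUROC and AUPR, with test-fold positive edges removed from the network
   before any test subgraph is extracted.

Preferential attachment, similarity-weighted common neighbors and Jaccard,
and the Katz index are included as baselines, along with a seeded synthetic
network generator with planted guilt-by-association structure for
end-to-end testing without external data.

## Worked example

```python
from dtiwlnet import (SyntheticConfig, generate_network, SamplingConfig,
                      assemble_samples, cross_validate, heuristic_cross_validate)

net, held_out = generate_network(SyntheticConfig(seed=0))
print(f"network: {net.m} drugs x {net.n} targets, "
      f"{int(net.Y.sum())} known interactions, {len(held_out)} held out")

samples = assemble_samples(net, SamplingConfig(ratio_alpha=1.0, seed=1))
report = cross_validate(net, samples, K=10, n_folds=10, seed=2)
pa = heuristic_cross_validate(net, samples, "PA", n_folds=10, seed=2)
print(f"pipeline : AUROC {report.mean_auroc:.3f} +/- {report.sd_auroc:.3f}")
print(f"PA       : AUROC {pa.mean_auroc:.3f} +/- {pa.sd_auroc:.3f}")
```

prints

```
network: 60 drugs x 80 targets, 83 known interactions, 9 held out
pipeline : AUROC 0.934 +/- 0.045
PA       : AUROC 0.735 +/- 0.102
```

i.e. on a synthetic network where similar drugs genuinely tend to share
targets, learning from enclosing subgraphs separates held-out interacting
from non-interacting pairs far better (AUROC 0.934) than the degree-product
heuristic (0.735); ± values are SD across the 10 folds.

The same pipeline is available from the shell:

```sh
dti-wlnet simulate --m 60 --n 80 --density 0.02 --seed 0 --out-dir net/
dti-wlnet evaluate --interactions net/interactions.tsv \
    --drug-sim net/drug_sim.tsv --target-sim net/target_sim.tsv \
    --k 10 --folds 10 --seed 2 --out-dir run/ --report report.json
```

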