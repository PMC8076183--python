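# caspectral

Correspondence analysis (CA) of contingency and presence–absence tables,
treated as what it mathematically is: a spectral analysis of the bipartite
network the table encodes. One eigendecomposition yields three readings at
once — **ordination** (latent gradients), **spectral clustering** of the
projected similarity network, and a **graph embedding** in chi-square
geometry — and the package exploits the equivalence with a recursive
*cluster first, ordinate within clusters* procedure.

Intended users: ecologists doing gradient analysis or bioregionalization on
species-by-site matrices, economists working with country–product export
tables (the economic complexity index is exactly the first nontrivial CA
axis), and anyone analysing co-occurrence data as a bipartite network.

## The mathematics

For a nonnegative table *A* (n_r × n_c) with row margins *r* (diagonal
matrix D_r), column margins *c* (D_c) and grand total *n*, CA solves

```
D_r⁻¹ A D_c⁻¹ Aᵀ v = λ v        D_c⁻¹ Aᵀ D_r⁻¹ A u = λ u
```

with eigenvalues 1 = λ₁ ≥ λ₂ ≥ … ≥ 0. The leading pair is trivial
(constant scores). The same eigenpairs are:

* **Canonical correlations.** Listing the row score vᵢ and column score uⱼ
  once per edge gives vectors y_r, y_c of length n with
  λ = corr²(y_r, y_c): the axes are the score assignments that maximally
  correlate connected nodes — latent variables driving the links.
* **Relaxed normalized-cut labels.** Projecting the bipartite network onto
  its rows by stochastic complementation gives the similarity matrix
  S_r = A D_c⁻¹ Aᵀ; the generalized Laplacian problem
  (D_r − S_r) v = λ̃ D_r v has the same eigenvectors with λ̃ = 1 − λ. The
  multiplicity of λ = 1 counts connected components, and the mean of the
  top K eigenvalues scores a K-way partition.
* **Principal coordinates.** x_k = √λ_k · v_k embeds the nodes so Euclidean
  distances approximate chi-square distances between profiles; each axis
  explains a share λ_k / Σ_{j≥2} λ_j of the total inertia.

Whether an axis is read as a gradient or as cluster labels is decided from
the spectrum: eigenvalues near 1 followed by a sharp drop (the *eigengap*)
indicate weakly connected clusters; a smoothly decaying spectrum indicates
gradients. `recursive_scca` estimates K by the eigengap, splits the rows
with k-means on the K−1 leading nontrivial axes, and recurses until every
cluster reads K = 1 — at which point the within-cluster axes are clean
gradients.

Axis numbering follows the convention that the k-th *nontrivial*
eigenvector carries subscript k+1: "CA axis 1" is eigenvector 2. All
outputs label both indices.

## Worked example

Two weakly connected blocks, each hiding a band-diagonal gradient
(30×40 per block, within-band density 0.9, between-block noise 0.01):

```python
import numpy as np
import caspectral as cs

table, truth = cs.blocks_with_gradients(n_blocks=2, block_shape=(30, 40), seed=11)
spectrum = cs.ca_spectrum(table, k_max=21)
print("eigenvalues:", np.round(spectrum.eigenvalues[:6], 3))
decision = cs.eigengap_count(spectrum.eigenvalues)
print("eigengap K:", decision.K)
tree = cs.recursive_scca(table, seed=11)
for leaf in tree.leaves():
    print(f"leaf {leaf.node_id}: {len(leaf.members)} rows, K={leaf.K}, "
          f"sqrt(lambda_2)={np.sqrt(leaf.eigenvalues[1]):.2f}")
```

prints

```
eigenvalues: [1.    0.945 0.482 0.472 0.059 0.057]
eigengap K: 2
leaf 0.0: 30 rows, K=1, sqrt(lambda_2)=0.70
leaf 0.1: 30 rows, K=1, sqrt(lambda_2)=0.71
```

Read: four eigenvalues stand clear of the bulk. The value 0.945 close to 1
is the two-cluster structure (the largest gap follows it, so K = 2); 0.482
and 0.472 are the two within-block gradients. The recursion therefore
splits once into two 30-row leaves, each of which reads K = 1 and exposes
its gradient as a within-leaf axis with row–column correlation
√λ₂ ≈ 0.71. The recovered leaf axes track the planted row orders with
|Spearman ρ| ≈ 0.99, and on the pooled table
corr²(y_r, y_c) = 0.945199 = λ₂ to machine precision — the identity linking
the ordination and clustering readings.

The same analysis from the shell:

```sh
caspectral generate --family blocks-with-gradients --n-rows 60 --n-cols 80 \
    --p 0.9 --noise 0.01 --seed 11 --out fixture
caspectral run --input fixture.mtx --seed 11 --out results/
```

which writes `spectrum.csv`, `row_scores.csv`, `col_scores.csv`,
`cluster_tree.json`, `leaf_scores.csv` and a `log.json` containing the
eigengap decision trace for every recursion node.

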