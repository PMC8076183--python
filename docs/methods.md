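# Methods

## The eigenproblem and how it is solved

The CA operators D_r⁻¹ A D_c⁻¹ Aᵀ and D_c⁻¹ Aᵀ D_r⁻¹ A are row-stochastic
and not symmetric, so their direct eigendecomposition is numerically
fragile. `ca_spectrum` instead factorizes the symmetrized operator
M = D_r^{-1/2} A D_c^{-1/2} by SVD: singular values σ give λ = σ² (real,
in [0, 1] by construction), left/right singular vectors w, z map back to
the score systems via v = D_r^{-1/2} w, u = D_c^{-1/2} z. The two sides are
produced by one factorization and therefore satisfy the transition formula
D_c⁻¹ Aᵀ v = σ u exactly, not merely up to sign.

Eigenvalues are clipped into [0, 1] after verifying they lie within 1e−8
of the interval; a larger escape raises, since it indicates an invalid
table rather than rounding. The generalized Laplacian route
(D − S) v = λ̃ D v is implemented independently (`scipy.linalg.eigh` on the
dense pencil) and used in the test suite as a cross-check oracle for the
identity λ̃ = 1 − λ; it is not a second code path users need to choose
between.

Tables below 5% density (and larger than 50 on the short side) are held in
CSR storage; a truncated spectrum is then computed with ARPACK
(`scipy.sparse.linalg.svds`) using a fixed, deterministic start vector.
The truncated route agrees with the dense route to 1e−8 on the retained
axes.

## Score normalization

Two standardizations are offered because two natural constraint systems
exist and they are incompatible:

* `unit-variance` (default): Σᵢ rᵢ vᵢ = 0 and Σᵢ rᵢ vᵢ² = n. Under these,
  the per-edge score vectors y_r, y_c literally have zero mean and unit
  variance, so the axis eigenvalue is the squared plain Pearson correlation
  of the edge scores — the canonical-correlation derivation taken at face
  value.
* `unit-norm`: |v| = |u| = 1, the convention common in the graph-embedding
  literature.

Eigenvalues, rankings, cluster assignments and score correlations are
invariant to the choice (verified by test); only the scale of reported
coordinates changes.

**Sign convention.** Each row eigenvector is oriented so its
largest-magnitude entry is positive; near-ties (within 1e−9 relative, as
arise from exact symmetries) resolve to the lowest index. The paired column
vector is flipped together with the row vector so the transition formula
keeps a positive factor — orienting the two sides independently could
silently negate the row–column correlation.

**Total inertia.** The trivial eigenvalue is excluded, following classical
CA. The total is computed exactly as trace(MMᵀ) − 1 = Σᵢⱼ A²ᵢⱼ/(rᵢcⱼ) − 1,
so variation shares are correct even when only a truncated spectrum was
requested. Spectrum exports label the trivial axis explicitly so the
convention is visible in the output.

## Clustering decisions

* **Eigengap.** K is the number of eigenvalues (trivial included) preceding
  the largest consecutive drop within the first `max_k` (default 20,
  a practical window for visual spectra) eigenvalues. Ties break toward
  smaller K: splitting too finely produces artificial cuts, so the
  conservative reading is preferred. The heuristic is just that — a
  heuristic — so every pipeline run logs the examined spectrum prefix and
  gap position for each recursion node.
* **k-means.** Runs on the K−1 leading nontrivial *principal-coordinate*
  axes (√λ-scaled; the constant trivial axis could not affect the result
  and is dropped). 50 k-means++ restarts with a seeded RNG; best run by
  within-cluster sum of squares. Deterministic given the seed.
* **Recursion.** Each child is rebuilt as a standalone table from its row
  subset, with columns that became empty dropped — children must again be
  valid tables with positive margins. Child RNG seeds derive from the tree
  path via `SeedSequence(entropy=seed, spawn_key=path)`, so the whole tree
  is reproducible bit-for-bit and independent of traversal order. Nodes
  with fewer than `min_size` rows (default 3) become leaves regardless of
  their spectrum, with the reason recorded on the node.

## What the generators emulate

The synthetic families reproduce the qualitative spectral regimes of
bipartite co-occurrence data: pure noise (`random_bipartite`), a single
latent gradient (`gradient_band`), weakly connected communities (`blocks`),
and communities with internal gradients (`blocks_with_gradients`).
`binarize_rca` converts weighted tables to presences by the Balassa rule
RCA = (A_ij/r_i)/(c_j/n) ≥ 1 (threshold configurable), the standard
preprocessing for trade-type tables.

Defaults were fixed once, by measuring where each family lands spectrally:

* Blocks: 30×40 per block, within-block density p_in = 0.3, between-block
  noise 0.01. This puts block eigenvalues around 0.85–0.95 — close to but
  distinguishably below 1, the "weakly connected" regime — with the bulk
  near 0.2.
* Band: membership |i/n_r − j/n_c| ≤ bandwidth/2 with within-band density
  p_in = 0.9. The default bandwidth is 0.75: measured on 30×40 tables this
  gives λ₂ ≈ 0.50 (row–column correlation √λ₂ ≈ 0.71) with λ₃ ≈ 0.06, i.e.
  one strong gradient axis and a fast-decaying tail, so an isolated
  gradient block correctly reads K = 1 from the eigengap. Much narrower
  bands (e.g. bandwidth 0.2) push λ₂ toward 1 with slow decay — there the
  eigengap misreads a pure gradient as clusters, and the composite
  blocks-with-gradients family loses the separation of its four leading
  eigenvalues. Narrow bands remain available by argument and are used in
  the tests precisely to exhibit the arch effect at its strongest.
* Generators re-draw (bounded retries) until the network is connected —
  or has exactly `n_blocks` components when the between-block noise is
  zero — and all margins are positive, so every emitted table is a valid
  analysis input.

What the generators do **not** emulate: degree heterogeneity (real
species/site and country/product margins are heavy-tailed), nestedness of
the kind seen in trade data (triangular rather than band-diagonal
structure), spatial autocorrelation between sites, and abundance counts
(all stylized tables are binary). Passing recovery tests on these fixtures
therefore demonstrates correctness of the spectral machinery on planted
structure, not robustness to every feature of field data.

## The arch diagnostic

On gradient-dominated tables the second nontrivial axis is often close to
a quadratic function of the first — a well-known ordination artefact, not
extra structure. `arch_diagnostic` quantifies this as the R² of a
least-squares quadratic fit of one axis on another. On narrow-band fixtures
(60×60, bandwidth 0.2, p_in 0.9) measured R² exceeds 0.98 across seeds;
values above ~0.5 are a practical flag that the higher axis restates the
gradient. The package diagnoses the arch but deliberately does not detrend
it.

## Degenerate inputs and numerical edges

* Single-row or single-column tables return only the trivial axis, with a
  warning.
* Requesting more eigenpairs than min(n_r, n_c) truncates with a warning.
* Eigenvalues within 1e−8 of 1 count as unit eigenvalues for component
  counting (configurable); the tolerance is far above accumulated rounding
  at the tested sizes and far below the gap to genuine non-unit values.
* Within degenerate eigenspaces (repeated eigenvalues, e.g. exactly
  disconnected components) individual eigenvectors are basis-dependent;
  invariant quantities (eigenvalues, subspaces, component counts, cluster
  recovery) are what the tests assert there.
* Edge-score expansion requires integer counts (each cell repeats its
  score pair count times); non-integer weighted tables are analysed
  spectrally without the explicit edge expansion.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic tables
between roughly 20×25 and 200×300, sizes at which dense solvers are exact
and fast and the planted-recovery statistics (100 seeded fixtures per
claim) are stable. The sparse truncated path is exercised against the dense
path at 150×200 / 2% density.
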