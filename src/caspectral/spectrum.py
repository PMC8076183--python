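"""Correspondence analysis as an eigenproblem, three ways.

For a table ``A`` with row margins ``r`` (diagonal ``D_r``), column margins
``c`` (``D_c``) and grand total ``n``, correspondence analysis solves

    D_r^{-1} A D_c^{-1} A^T v = lambda v
    D_c^{-1} A^T D_r^{-1} A u = lambda u

The same eigenpairs admit three readings, each exposed here:

* **canonical correlation** — ``v``/``u`` are row/column scores whose
  edge-wise correlation is maximised, with ``lambda = corr^2(y_r, y_c)``
  (:func:`edge_scores`, :func:`score_correlation`);
* **normalized-cut clustering** — ``v`` are relaxed cluster labels of the
  one-mode similarity network ``S_r = A D_c^{-1} A^T`` obtained by stochastic
  complementation, since ``(D_r - S_r) v = (1 - lambda) D_r v``
  (:func:`project_similarity`, :func:`laplacian_generalized_eigs`);
* **graph embedding** — principal coordinates ``x_k = sqrt(lambda_k) v_k``
  place the nodes in Euclidean space with chi-square geometry
  (:func:`embed`).

Numerically the eigenproblem is solved through the symmetrized operator
``M = D_r^{-1/2} A D_c^{-1/2}`` and its SVD (``lambda = sigma^2``): the
row-stochastic operator above is not symmetric, while the SVD route
guarantees a real spectrum in [0, 1] and orthogonal score systems.

Indexing convention: the trivial eigenpair (``lambda_1 = 1``, constant
scores) is kept at position 1, so "CA axis k" is eigenvector ``k + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .incidence import IncidenceTable

__all__ = [
    "CASpectrum",
    "SimilarityGraph",
    "EdgeScores",
    "Embedding",
    "project_similarity",
    "ca_spectrum",
    "edge_scores",
    "score_correlation",
    "laplacian_generalized_eigs",
    "embed",
    "count_components",
    "arch_diagnostic",
]

#: eigenvalues within this distance of 1 count as "unit" (disconnected parts)
UNIT_EIGENVALUE_TOL = 1e-8


@dataclass(frozen=True)
class SimilarityGraph:
    """One-mode projection of the bipartite network.

    ``S_r = A D_c^{-1} A^T`` scores a pair of row nodes by the column nodes
    they share, each shared column discounted by its degree (stochastic
    complementation).  Row sums of the similarity matrix reproduce the node
    degrees, so the graph Laplacian ``D - S`` has zero row sums.
    """

    side: str
    similarity: np.ndarray | sp.csr_matrix
    degrees: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        S = self.similarity
        n = S.shape[0]
        if S.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        asym = abs(S - S.T)
        asym = asym.max() if not sp.issparse(S) else (asym.max() if asym.nnz else 0.0)
        scale = max(1.0, float(self.degrees.max()))
        if asym > 1e-8 * scale:
            raise ValueError("similarity matrix is not symmetric")
        rowsums = np.asarray(S.sum(axis=1)).ravel()
        if not np.allclose(rowsums, self.degrees, rtol=1e-10, atol=1e-8):
            raise ValueError("similarity row sums do not match degrees")

    def dense(self) -> np.ndarray:
        S = self.similarity
        return S.toarray() if sp.issparse(S) else np.asarray(S)

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = D - S (dense)."""
        return np.diag(self.degrees) - self.dense()


@dataclass(frozen=True)
class CASpectrum:
    """Eigenvalues and paired row/column score vectors of a CA solution.

    ``eigenvalues`` are sorted descending with the trivial value 1 first;
    ``row_scores[:, k]`` / ``col_scores[:, k]`` hold eigenvector ``k + 1`` in
    the 1-based convention (column 0 is the constant trivial solution).
    """

    eigenvalues: np.ndarray
    row_scores: np.ndarray
    col_scores: np.ndarray
    row_weights: np.ndarray
    col_weights: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    normalization: str
    total_inertia: float
    unit_tol: float = UNIT_EIGENVALUE_TOL

    @property
    def n_axes(self) -> int:
        """Number of nontrivial eigenpairs available."""
        return len(self.eigenvalues) - 1

    @property
    def n_components(self) -> int:
        """Connected components = multiplicity of the unit eigenvalue."""
        return int(np.sum(self.eigenvalues >= 1.0 - self.unit_tol))

    def scores(self, side: str) -> np.ndarray:
        if side == "row":
            return self.row_scores
        if side in ("col", "column"):
            return self.col_scores
        raise ValueError(f"side must be 'row' or 'column', got {side!r}")

    def weights(self, side: str) -> np.ndarray:
        return self.row_weights if side == "row" else self.col_weights

    def side_labels(self, side: str) -> tuple[str, ...]:
        return self.row_labels if side == "row" else self.col_labels

    def to_frame(self):
        """Spectrum summary: eigenvalue, its square root and inertia share."""
        import pandas as pd

        lam = self.eigenvalues
        shares = np.zeros_like(lam)
        if self.total_inertia > 0:
            shares[1:] = lam[1:] / self.total_inertia
        return pd.DataFrame(
            {
                "eigenvector": np.arange(1, len(lam) + 1),
                "ca_axis": ["trivial"] + [str(k) for k in range(1, len(lam))],
                "eigenvalue": lam,
                "sqrt_eigenvalue": np.sqrt(lam),
                "variation_share": shares,
            }
        )


@dataclass(frozen=True)
class EdgeScores:
    """Row and column scores listed once per edge (occurrence) of the table.

    For a weighted table a cell with count ``m`` contributes its pair of
    scores ``m`` times, so both vectors have length ``n``, the grand total.
    """

    y_r: np.ndarray
    y_c: np.ndarray
    axis: int

    def __post_init__(self) -> None:
        if len(self.y_r) != len(self.y_c):
            raise ValueError("edge score vectors must have equal length")


@dataclass(frozen=True)
class Embedding:
    """Principal-coordinate embedding of one side of the table.

    Column ``k`` (0-based) holds CA axis ``k + 1``, i.e. eigenvector
    ``k + 2`` scaled by the square root of its eigenvalue.  Euclidean
    distances between rows approximate chi-square distances between the
    corresponding profiles.
    """

    coordinates: np.ndarray
    variation_shares: np.ndarray
    eigenvalues: np.ndarray
    side: str
    labels: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis(self, ca_axis: int) -> np.ndarray:
        """Coordinates on a 1-based CA axis (axis 1 = eigenvector 2)."""
        if not 1 <= ca_axis <= self.n_axes:
            raise ValueError(
                f"CA axis {ca_axis} not available; have 1..{self.n_axes}"
            )
        return self.coordinates[:, ca_axis - 1]


# ---------------------------------------------------------------------------
# projections and eigenproblem


def project_similarity(table: IncidenceTable, side: str = "row") -> SimilarityGraph:
    """One-mode similarity network by stochastic complementation.

    ``side="row"`` gives ``S_r = A D_c^{-1} A^T`` (n_r x n_r); ``side="column"``
    gives ``S_c = A^T D_r^{-1} A``.
    """
    A = table.values
    if side == "row":
        inv = 1.0 / table.col_margins
        if sp.issparse(A):
            S = (A @ sp.diags(inv) @ A.T).tocsr()
        else:
            S = (A * inv) @ A.T
        S = (S + S.T) * 0.5  # symmetrize away rounding noise
        return SimilarityGraph("row", S, table.row_margins, table.row_labels)
    if side in ("col", "column"):
        inv = 1.0 / table.row_margins
        if sp.issparse(A):
            S = (A.T @ sp.diags(inv) @ A).tocsr()
        else:
            S = (A.T * inv) @ A
        S = (S + S.T) * 0.5
        return SimilarityGraph("column", S, table.col_margins, table.col_labels)
    raise ValueError(f"side must be 'row' or 'column', got {side!r}")


def _orient_signs(V: np.ndarray, U: np.ndarray) -> None:
    """Deterministic orientation: largest-|v| entry positive; ties -> lowest
    index (argmax already picks the first maximum).  The paired column vector
    is flipped with it so the transition formulas keep a positive factor."""
    for k in range(V.shape[1]):
        a = np.abs(V[:, k])
        # near-ties (float noise) resolve to the lowest index
        i = int(np.flatnonzero(a >= a.max() * (1 - 1e-9))[0])
        if V[i, k] < 0:
            V[:, k] *= -1
            U[:, k] *= -1


def ca_spectrum(
    table: IncidenceTable,
    k_max: int | None = None,
    normalization: str = "unit-variance",
    unit_tol: float = UNIT_EIGENVALUE_TOL,
) -> CASpectrum:
    """Solve the CA eigenproblem for an incidence table.

    Parameters
    ----------
    table
        Validated incidence table.
    k_max
        Number of eigenpairs to return, counting the trivial one; defaults
        to the full ``min(n_r, n_c)``.  Sparse tables use a truncated SVD of
        the leading ``k_max`` singular triplets.
    normalization
        ``"unit-variance"`` (default): scores scaled so each edge-score
        vector has zero mean and unit variance under the margin weights
        (``sum_i r_i v_i = 0``, ``sum_i r_i v_i^2 = n``).
        ``"unit-norm"``: plain Euclidean unit length ``|v| = |u| = 1``.
        Rankings, cluster output and score correlations are invariant to
        this choice.

    Returns
    -------
    CASpectrum
        Eigenvalues descending (clipped into [0, 1]) with paired, sign-fixed
        row and column scores.
    """
    if normalization not in ("unit-variance", "unit-norm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    r = table.row_margins
    c = table.col_margins
    n = table.total
    full = min(table.n_rows, table.n_cols)
    if k_max is None:
        k_max = full
    elif k_max > full:
        warnings.warn(
            f"k_max={k_max} exceeds min(n_r, n_c)={full}; truncating",
            stacklevel=2,
        )
        k_max = full
    if full == 1:
        warnings.warn(
            "single-row or single-column table: only the trivial axis exists",
            stacklevel=2,
        )

    ir = 1.0 / np.sqrt(r)
    ic = 1.0 / np.sqrt(c)
    A = table.values
    use_sparse = table.is_sparse and k_max < full - 1
    if use_sparse:
        M = sp.diags(ir) @ A @ sp.diags(ic)
        # deterministic start vector; ARPACK otherwise seeds randomly
        v0 = np.full(min(M.shape), 1.0 / np.sqrt(min(M.shape)))
        try:
            W, s, Zt = spla.svds(M, k=k_max, v0=v0, which="LM")
        except Exception as exc:  # pragma: no cover - solver failure surface
            raise RuntimeError(f"sparse SVD failed to converge: {exc}") from exc
        order = np.argsort(-s)
        W, s, Z = W[:, order], s[order], Zt[order, :].T
    else:
        M = (ir[:, None] * table.dense()) * ic[None, :]
        try:
            W, s, Zt = scipy.linalg.svd(M, full_matrices=False)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"SVD failed to converge: {exc}") from exc
        W, s, Z = W[:, :k_max], s[:k_max], Zt[:k_max, :].T

    lam = s**2
    if np.any(lam > 1.0 + 1e-8) or np.any(lam < -1e-8):
        raise RuntimeError("eigenvalues escaped [0, 1]; table not valid?")
    lam = np.clip(lam, 0.0, 1.0)

    V = ir[:, None] * W
    U = ic[:, None] * Z
    if normalization == "unit-variance":
        V = V * np.sqrt(n)
        U = U * np.sqrt(n)
    else:
        V = V / np.linalg.norm(V, axis=0)
        U = U / np.linalg.norm(U, axis=0)
    _orient_signs(V, U)

    # exact total inertia from trace(M M^T), minus the trivial eigenvalue —
    # available even when the spectrum is truncated
    if sp.issparse(A):
        M2 = A.copy()
        M2.data = M2.data**2
        trace = float((ir**2) @ M2 @ (ic**2))
    else:
        trace = float(np.einsum("ij,i,j->", np.asarray(A) ** 2, ir**2, ic**2))
    total_inertia = max(trace - 1.0, 0.0)

    return CASpectrum(
        eigenvalues=lam,
        row_scores=V,
        col_scores=U,
        row_weights=r,
        col_weights=c,
        row_labels=table.row_labels,
        col_labels=table.col_labels,
        normalization=normalization,
        total_inertia=total_inertia,
        unit_tol=unit_tol,
    )


# ---------------------------------------------------------------------------
# canonical-correlation view


def edge_scores(table: IncidenceTable, spectrum: CASpectrum, k: int) -> EdgeScores:
    """Per-edge score vectors for eigenvector ``k`` (1-based, ``k >= 2``).

    Each occurrence in the table contributes one entry: cell ``(i, j)`` with
    count ``m`` repeats the pair ``(v_i, u_j)`` ``m`` times, so both vectors
    have length ``n``.  Counts must be integers for this expansion.
    """
    if k < 2:
        raise ValueError(
            "k=1 is the trivial axis: constant scores have zero variance and "
            "no defined correlation"
        )
    if k > len(spectrum.eigenvalues):
        raise ValueError(f"eigenvector {k} not computed (have {len(spectrum.eigenvalues)})")
    A = sp.coo_matrix(table.values)
    counts = A.data
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise ValueError("edge expansion requires integer cell counts")
    m = rounded.astype(int)
    v = spectrum.row_scores[:, k - 1]
    u = spectrum.col_scores[:, k - 1]
    # row-major edge order for reproducibility
    order = np.lexsort((A.col, A.row))
    y_r = np.repeat(v[A.row[order]], m[order])
    y_c = np.repeat(u[A.col[order]], m[order])
    return EdgeScores(y_r=y_r, y_c=y_c, axis=k)


def score_correlation(scores: EdgeScores) -> float:
    """Pearson correlation of the per-edge row and column scores.

    Its square equals the eigenvalue of the axis the scores came from — the
    identity that motivates reading CA axes as maximally correlated latent
    variables.
    """
    y_r, y_c = scores.y_r, scores.y_c
    if np.var(y_r) <= 0 or np.var(y_c) <= 0:
        raise ValueError("edge scores have zero variance; correlation undefined")
    return float(np.corrcoef(y_r, y_c)[0, 1])


# ---------------------------------------------------------------------------
# normalized-cut view


def laplacian_generalized_eigs(
    graph: SimilarityGraph, k_max: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized eigenpairs of ``(D - S) v = t D v``, ascending in ``t``.

    This is the relaxed normalized-cut problem on the similarity network.  It
    is solved densely and independently of the SVD route, so the identity
    ``t_k = 1 - lambda_k`` makes it a cross-check oracle for
    :func:`ca_spectrum`.
    """
    L = graph.laplacian()
    D = np.diag(graph.degrees)
    try:
        vals, vecs = scipy.linalg.eigh(L, D)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"generalized eigensolver failed: {exc}") from exc
    vals = np.clip(vals, 0.0, None)
    if k_max is not None:
        vals, vecs = vals[:k_max], vecs[:, :k_max]
    return vals, vecs


def count_components(spectrum: CASpectrum, tol: float | None = None) -> int:
    """Connected components of the bipartite network, spectrally.

    Each disconnected cluster contributes one unit eigenvalue (a zero of the
    normalized Laplacian), so the count is the multiplicity of ``lambda = 1``
    within ``tol``.
    """
    if tol is None:
        tol = spectrum.unit_tol
    return int(np.sum(spectrum.eigenvalues >= 1.0 - tol))


# ---------------------------------------------------------------------------
# embedding view


def embed(spectrum: CASpectrum, n_axes: int | None = None, side: str = "row") -> Embedding:
    """Principal-coordinate embedding ``X = [sqrt(l_2) v_2, ..., sqrt(l_K) v_K]``.

    ``variation_shares[k]`` is that axis's eigenvalue divided by the total
    inertia (sum of all nontrivial eigenvalues; the trivial eigenvalue is
    excluded from the total, following classical CA practice).
    """
    avail = spectrum.n_axes
    if n_axes is None:
        n_axes = avail
    if n_axes == 0:
        raise ValueError("embedding needs at least one nontrivial axis")
    if n_axes > avail:
        raise ValueError(f"requested {n_axes} axes but only {avail} are available")
    lam = spectrum.eigenvalues[1 : n_axes + 1]
    scores = spectrum.scores(side)[:, 1 : n_axes + 1]
    coords = scores * np.sqrt(lam)[None, :]
    if spectrum.total_inertia > 0:
        shares = lam / spectrum.total_inertia
    else:
        shares = np.zeros_like(lam)
    return Embedding(
        coordinates=coords,
        variation_shares=shares,
        eigenvalues=lam,
        side=side,
        labels=spectrum.side_labels(side),
    )


def arch_diagnostic(embedding: Embedding, axis_a: int = 1, axis_b: int = 2) -> float:
    """R-squared of a quadratic fit of one axis on another.

    A higher-order axis that is nearly a quadratic function of the leading
    gradient axis is the classic "arch" (polynomial) artefact: it restates
    the same gradient and carries little new information.  Values near 1 flag
    ``axis_b`` as an arch of ``axis_a``.
    """
    x = embedding.axis(axis_a)
    y = embedding.axis(axis_b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) axis; arch diagnostic undefined")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot
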