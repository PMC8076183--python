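"""Stylized bipartite-network generators with planted structure.

Five families span the qualitative regimes a spectral analysis of an
incidence table can meet:

* ``random_bipartite`` — i.i.d. Bernoulli noise, no structure: one unit
  eigenvalue, the rest small;
* ``gradient_band`` — a band-diagonal table driven by a single latent
  gradient: one dominant nontrivial eigenvalue, smooth leading axis, and a
  higher axis showing the arch artefact;
* ``blocks`` — 2+ weakly connected random blocks: as many near-unit
  eigenvalues as blocks, nearly piecewise-constant ("nodal") leading axes;
* ``blocks_with_gradients`` — weakly connected blocks each hiding its own
  gradient: block eigenvalues near 1 followed by one gradient eigenvalue
  per block, separated from the bulk;
* ``binarize_rca`` — turns a weighted table (e.g. country-product export
  values) into presences via the Balassa revealed-comparative-advantage
  rule.

Every generator is a pure function of its parameters and seed, re-draws
until the network is connected (or has exactly the planted number of
components when the between-block noise is zero), and returns the planted
truth alongside the table for use as a recovery oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .incidence import IncidenceTable, load_incidence

__all__ = [
    "GeneratorSpec",
    "random_bipartite",
    "gradient_band",
    "blocks",
    "blocks_with_gradients",
    "binarize_rca",
]

# block-family defaults sized to land in the weakly-connected regime where
# block eigenvalues sit near (but below) 1 and are cleanly separated from
# the bulk of the spectrum
DEFAULT_BLOCK_SHAPE = (30, 40)
DEFAULT_P_IN = 0.3
DEFAULT_NOISE = 0.01
# fraction of the column range a row connects into; 0.75 puts a single
# gradient block in the one-strong-axis regime (lambda_2 ~ 0.5, fast decay)
DEFAULT_BANDWIDTH = 0.75
MAX_RETRIES = 200


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters and planted ground truth of a generated table."""

    family: str
    n_r: int
    n_c: int
    seed: int
    params: dict = field(default_factory=dict)
    planted_row_blocks: tuple[int, ...] | None = None
    planted_col_blocks: tuple[int, ...] | None = None
    planted_row_order: tuple[int, ...] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family": self.family,
            "n_r": self.n_r,
            "n_c": self.n_c,
            "seed": self.seed,
            "params": self.params,
            "planted_row_blocks": list(self.planted_row_blocks)
            if self.planted_row_blocks is not None
            else None,
            "planted_col_blocks": list(self.planted_col_blocks)
            if self.planted_col_blocks is not None
            else None,
            "planted_row_order": list(self.planted_row_order)
            if self.planted_row_order is not None
            else None,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_json(source: str | Path) -> "GeneratorSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return GeneratorSpec(
            family=d["family"],
            n_r=d["n_r"],
            n_c=d["n_c"],
            seed=d["seed"],
            params=d.get("params", {}),
            planted_row_blocks=tuple(d["planted_row_blocks"])
            if d.get("planted_row_blocks") is not None
            else None,
            planted_col_blocks=tuple(d["planted_col_blocks"])
            if d.get("planted_col_blocks") is not None
            else None,
            planted_row_order=tuple(d["planted_row_order"])
            if d.get("planted_row_order") is not None
            else None,
        )


def _n_components(A: np.ndarray) -> int:
    """Connected components of the bipartite graph with bi-adjacency A."""
    n_r, n_c = A.shape
    biadj = sp.csr_matrix(A)
    adj = sp.bmat(
        [[None, biadj], [biadj.T, None]], format="csr"
    )
    n, _ = connected_components(adj, directed=False)
    return n


def _valid(A: np.ndarray, want_components: int) -> bool:
    if A.sum() == 0:
        return False
    if np.any(A.sum(axis=1) == 0) or np.any(A.sum(axis=0) == 0):
        return False
    return _n_components(A) == want_components


def _draw_until_valid(draw, want_components: int, what: str):
    for _ in range(MAX_RETRIES):
        A = draw()
        if _valid(A, want_components):
            return A
    raise RuntimeError(
        f"could not draw a {what} table with {want_components} component(s) "
        f"and positive margins in {MAX_RETRIES} attempts; parameters too sparse?"
    )


def _table(A: np.ndarray) -> IncidenceTable:
    return load_incidence(A, drop_empty=False)


def random_bipartite(
    n_r: int, n_c: int, p: float, seed: int
) -> tuple[IncidenceTable, GeneratorSpec]:
    """Erdos-Renyi-style bipartite table: i.i.d. Bernoulli(p) presences.

    Re-drawn until connected with all margins positive.
    """
    if not 0 < p < 1:
        raise ValueError("edge probability p must be in (0, 1)")
    if min(n_r, n_c) * p < 1:
        warnings.warn("expected degree below 1; connectivity retries likely", stacklevel=2)
    rng = np.random.default_rng(seed)
    A = _draw_until_valid(
        lambda: (rng.random((n_r, n_c)) < p).astype(float), 1, "random bipartite"
    )
    spec = GeneratorSpec("random", n_r, n_c, seed, params={"p": p})
    return _table(A), spec


def _band_mask(n_r: int, n_c: int, bandwidth: float) -> np.ndarray:
    i = (np.arange(n_r) / n_r)[:, None]
    j = (np.arange(n_c) / n_c)[None, :]
    return np.abs(i - j) <= bandwidth / 2


def gradient_band(
    n_r: int,
    n_c: int,
    bandwidth: float = DEFAULT_BANDWIDTH,
    p_in: float = 0.9,
    seed: int = 0,
) -> tuple[IncidenceTable, GeneratorSpec]:
    """Band-diagonal table: a single latent gradient drives the links.

    Cell (i, j) is present with probability ``p_in`` when the normalized
    positions of row i and column j differ by at most half the bandwidth,
    and absent otherwise.  The planted gradient is the row order itself.
    With ``bandwidth=1`` the band covers everything and the family reduces
    to ``random_bipartite(p_in)``.
    """
    if not 0 < bandwidth <= 1:
        raise ValueError("bandwidth must be in (0, 1]")
    if not 0 < p_in <= 1:
        raise ValueError("p_in must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = _band_mask(n_r, n_c, bandwidth)
    A = _draw_until_valid(
        lambda: (mask & (rng.random((n_r, n_c)) < p_in)).astype(float),
        1,
        "band-diagonal",
    )
    spec = GeneratorSpec(
        "gradient",
        n_r,
        n_c,
        seed,
        params={"bandwidth": bandwidth, "p_in": p_in},
        planted_row_order=tuple(range(n_r)),
    )
    return _table(A), spec


def _assemble_blocks(
    block_draws,
    n_blocks: int,
    block_shape: tuple[int, int],
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    br, bc = block_shape
    n_r, n_c = n_blocks * br, n_blocks * bc
    A = np.zeros((n_r, n_c))
    for b in range(n_blocks):
        A[b * br : (b + 1) * br, b * bc : (b + 1) * bc] = block_draws[b]
    if noise > 0:
        off = rng.random((n_r, n_c)) < noise
        for b in range(n_blocks):
            off[b * br : (b + 1) * br, b * bc : (b + 1) * bc] = False
        A[off] = 1.0
    return A


def blocks(
    n_blocks: int = 2,
    block_shape: tuple[int, int] = DEFAULT_BLOCK_SHAPE,
    p_in: float = DEFAULT_P_IN,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[IncidenceTable, GeneratorSpec]:
    """Block-diagonal table of weakly connected random bipartite blocks.

    Within-block cells are Bernoulli(``p_in``), between-block cells
    Bernoulli(``noise``).  ``noise=0`` yields exactly ``n_blocks``
    disconnected components (each block re-drawn until internally connected);
    small positive noise gives the weakly connected regime in which the
    leading eigenvalues sit just below 1.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if not 0 <= noise < p_in:
        raise ValueError("need 0 <= noise < p_in")
    rng = np.random.default_rng(seed)
    br, bc = block_shape
    want = n_blocks if noise == 0 else 1

    def draw():
        block_draws = [
            _draw_until_valid(
                lambda: (rng.random((br, bc)) < p_in).astype(float), 1, "block"
            )
            for _ in range(n_blocks)
        ]
        return _assemble_blocks(block_draws, n_blocks, block_shape, noise, rng)

    A = _draw_until_valid(draw, want, "block-structured")
    row_blocks = tuple(int(x) for x in np.repeat(np.arange(n_blocks), br))
    col_blocks = tuple(int(x) for x in np.repeat(np.arange(n_blocks), bc))
    spec = GeneratorSpec(
        "blocks",
        n_blocks * br,
        n_blocks * bc,
        seed,
        params={
            "n_blocks": n_blocks,
            "block_shape": list(block_shape),
            "p_in": p_in,
            "noise": noise,
        },
        planted_row_blocks=row_blocks,
        planted_col_blocks=col_blocks,
    )
    return _table(A), spec


def blocks_with_gradients(
    n_blocks: int = 2,
    block_shape: tuple[int, int] = DEFAULT_BLOCK_SHAPE,
    bandwidth: float = DEFAULT_BANDWIDTH,
    p_in: float = 0.9,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[IncidenceTable, GeneratorSpec]:
    """Weakly connected blocks, each internally band-diagonal.

    The spectrum shows ``n_blocks`` eigenvalues near 1 (the clusters)
    followed by one strong eigenvalue per within-block gradient, all
    separated from the noise bulk.  The planted truth records both the
    block labels and the within-block row orders.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if not 0 <= noise < p_in:
        raise ValueError("need 0 <= noise < p_in")
    rng = np.random.default_rng(seed)
    br, bc = block_shape
    mask = _band_mask(br, bc, bandwidth)
    want = n_blocks if noise == 0 else 1

    def draw():
        block_draws = [
            _draw_until_valid(
                lambda: (mask & (rng.random((br, bc)) < p_in)).astype(float),
                1,
                "gradient block",
            )
            for _ in range(n_blocks)
        ]
        return _assemble_blocks(block_draws, n_blocks, block_shape, noise, rng)

    A = _draw_until_valid(draw, want, "blocks-with-gradients")
    row_blocks = tuple(int(x) for x in np.repeat(np.arange(n_blocks), br))
    col_blocks = tuple(int(x) for x in np.repeat(np.arange(n_blocks), bc))
    # within each block the planted gradient is the local row index
    row_order = tuple(int(x) for x in np.tile(np.arange(br), n_blocks))
    spec = GeneratorSpec(
        "blocks_with_gradients",
        n_blocks * br,
        n_blocks * bc,
        seed,
        params={
            "n_blocks": n_blocks,
            "block_shape": list(block_shape),
            "bandwidth": bandwidth,
            "p_in": p_in,
            "noise": noise,
        },
        planted_row_blocks=row_blocks,
        planted_col_blocks=col_blocks,
        planted_row_order=row_order,
    )
    return _table(A), spec


def binarize_rca(weights, threshold: float = 1.0) -> IncidenceTable:
    """Binarize a weighted table by revealed comparative advantage.

    The Balassa index ``RCA_ij = (A_ij / r_i) / (c_j / n)`` compares cell
    ``(i, j)``'s share of its row to the column's share of the total; a
    presence marks cells with ``RCA >= threshold`` (default 1), i.e. rows
    that are "significant" holders of that column.  Rows or columns left
    empty after thresholding are dropped and logged on the result.
    """
    base = load_incidence(weights, drop_empty=True)
    A = base.dense()
    r = base.row_margins
    c = base.col_margins
    n = base.total
    rca = (A / r[:, None]) / (c[None, :] / n)
    binary = (rca >= threshold).astype(float)
    import pandas as pd

    frame = pd.DataFrame(binary, index=list(base.row_labels), columns=list(base.col_labels))
    return load_incidence(frame, drop_empty=True)
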