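"""End-to-end analysis pipeline and plot-data export.

``run_pipeline`` ties loading, the CA spectrum, the recursive
cluster-then-ordinate procedure and the exports into one reproducible run:
everything that influenced the result (config, dropped rows/columns, the
eigengap decision at every recursion node) is echoed into the output
directory as plain CSV/JSON, so a run can be audited and repeated
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import (
    DEFAULT_MAX_K,
    DEFAULT_MIN_SIZE,
    ClusterTree,
    recursive_scca,
)
from .incidence import IncidenceTable, load_incidence
from .spectrum import Embedding, ca_spectrum, embed

__all__ = ["RunConfig", "run_pipeline", "export_correspondence_plot"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one analysis run."""

    input_path: str
    fmt: str | None = None
    side: str = "row"
    max_k: int = DEFAULT_MAX_K
    min_size: int = DEFAULT_MIN_SIZE
    seed: int = 0
    normalization: str = "unit-variance"
    unit_tol: float = 1e-8
    out_dir: str = "caspectral_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _scores_frame(spectrum, side: str) -> pd.DataFrame:
    scores = spectrum.scores(side)
    labels = spectrum.side_labels(side)
    cols = {"label": list(labels)}
    for k in range(1, scores.shape[1]):
        cols[f"eigenvector_{k + 1}"] = scores[:, k]
    return pd.DataFrame(cols)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis described by ``config``.

    Writes into ``config.out_dir``:

    * ``config.json`` — the configuration as given;
    * ``spectrum.csv`` — eigenvalues, their square roots and inertia shares;
    * ``row_scores.csv`` / ``col_scores.csv`` — nontrivial score vectors;
    * ``cluster_tree.json`` — the recursive partition with per-node K,
      quality and spectrum prefix;
    * ``leaf_scores.csv`` — per row: leaf id and within-leaf axis-1 score;
    * ``log.json`` — dropped rows/columns, eigengap trace, tolerances.

    Returns a mapping of artefact names to written paths.  Identical config
    and input produce byte-identical outputs.
    """
    table = load_incidence(config.input_path, fmt=config.fmt, drop_empty=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spectrum = ca_spectrum(
        table,
        k_max=min(config.max_k + 1, min(table.shape)),
        normalization=config.normalization,
        unit_tol=config.unit_tol,
    )
    trace: list = []
    tree = recursive_scca(
        table,
        max_k=config.max_k,
        min_size=config.min_size,
        seed=config.seed,
        normalization=config.normalization,
        _trace=trace,
    )

    paths: dict[str, Path] = {}
    paths["config"] = out / "config.json"
    paths["config"].write_text(config.to_json() + "\n")
    paths["spectrum"] = out / "spectrum.csv"
    spectrum.to_frame().to_csv(paths["spectrum"], index=False, float_format="%.12g")
    paths["row_scores"] = out / "row_scores.csv"
    _scores_frame(spectrum, "row").to_csv(paths["row_scores"], index=False, float_format="%.12g")
    paths["col_scores"] = out / "col_scores.csv"
    _scores_frame(spectrum, "column").to_csv(paths["col_scores"], index=False, float_format="%.12g")
    paths["cluster_tree"] = out / "cluster_tree.json"
    tree.to_json(paths["cluster_tree"])
    paths["leaf_scores"] = out / "leaf_scores.csv"
    tree.leaf_scores_frame().to_csv(paths["leaf_scores"], index=False, float_format="%.12g")
    paths["log"] = out / "log.json"
    paths["log"].write_text(
        json.dumps(
            {
                "dropped_rows": list(table.dropped_rows),
                "dropped_cols": list(table.dropped_cols),
                "n_rows": table.n_rows,
                "n_cols": table.n_cols,
                "total": table.total,
                "unit_tol": config.unit_tol,
                "seed": config.seed,
                "eigengap_trace": trace,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths


def export_correspondence_plot(
    embedding: Embedding,
    axes: tuple[int, int] = (1, 2),
    cluster_labels=None,
    path: str | Path | None = None,
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Plot data for a correspondence plot: one axis against another.

    Returns (and optionally writes) a table of label, the two coordinates,
    an optional cluster assignment and each axis's variation share.  With
    ``figure_path`` a scatter is rendered too.
    """
    a, b = axes
    for ax in (a, b):
        if not 1 <= ax <= embedding.n_axes:
            raise ValueError(
                f"CA axis {ax} not available; axes 1..{embedding.n_axes} present"
            )
    if a == b:
        raise ValueError("correspondence plot needs two distinct axes")
    frame = pd.DataFrame(
        {
            "label": list(embedding.labels),
            f"axis{a}": embedding.axis(a),
            f"axis{b}": embedding.axis(b),
        }
    )
    if cluster_labels is not None:
        if len(cluster_labels) != len(frame):
            raise ValueError("cluster_labels length does not match embedding")
        frame["cluster"] = list(cluster_labels)
    frame[f"share_axis{a}"] = embedding.variation_shares[a - 1]
    frame[f"share_axis{b}"] = embedding.variation_shares[b - 1]
    if path is not None:
        frame.to_csv(path, index=False, float_format="%.12g")
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axp = plt.subplots(figsize=(6, 5))
        if cluster_labels is not None:
            codes = pd.Categorical(list(cluster_labels)).codes
            sc = axp.scatter(frame[f"axis{a}"], frame[f"axis{b}"], c=codes, cmap="tab10", s=18)
        else:
            axp.scatter(frame[f"axis{a}"], frame[f"axis{b}"], s=18)
        sa = 100 * embedding.variation_shares[a - 1]
        sb = 100 * embedding.variation_shares[b - 1]
        axp.set_xlabel(f"CA axis {a} ({sa:.1f}% of variation)")
        axp.set_ylabel(f"CA axis {b} ({sb:.1f}% of variation)")
        axp.set_title(f"Correspondence plot ({embedding.side} nodes)")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return frame
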