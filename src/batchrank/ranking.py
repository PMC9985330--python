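"""Rank aggregation of the six evaluation metrics into sumRank.

Batch-effect scores (e1 batch PVCA, e2 silhouette, e3 pcRegression) are
negated before dense ranking so that rank 1 = least residual batch effect;
biology-preservation scores (e4 bio PVCA, e5 entropy, e6 HVG union) are
dense-ranked directly so that rank 1 = best preservation.  sumRank is the
ascending dense rank of the per-method rank sum: rank 1 is the recommended
batch-correction method.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["e1", "e2", "e3", "e4", "e5", "e6"]
NEGATED = {"e1", "e2", "e3"}   # batch-effect metrics: smaller raw score is better

__all__ = ["dense_rank_desc", "transform_and_rank", "sum_rank", "diagnostic_report",
           "METRIC_COLUMNS", "NEGATED"]


def dense_rank_desc(values) -> np.ndarray:
    """Dense ranks, largest value first; ties share a rank, no gaps."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("dense rank requires finite values")
    uniq = np.unique(arr)[::-1]                 # descending distinct values
    lut = {v: i + 1 for i, v in enumerate(uniq)}
    return np.array([lut[v] for v in arr], dtype=int)


def transform_and_rank(evaluation: pd.DataFrame) -> pd.DataFrame:
    """Per-metric dense ranks of the evaluation matrix (methods x e1..e6)."""
    missing = [c for c in METRIC_COLUMNS if c not in evaluation.columns]
    if missing:
        raise ValueError(f"evaluation matrix lacks columns: {missing}")
    if evaluation.index.has_duplicates:
        raise ValueError("method labels must be unique")
    ranks = {}
    for col in METRIC_COLUMNS:
        vals = evaluation[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            culprit = evaluation.index[bad][0]
            raise ValueError(f"non-finite score: method {culprit!r}, metric {col}")
        ranks[col] = dense_rank_desc(-vals if col in NEGATED else vals)
    return pd.DataFrame(ranks, index=evaluation.index)


def sum_rank(per_metric_ranks: pd.DataFrame) -> pd.DataFrame:
    """Rank table with per-metric ranks, the rank sum, and sumRank."""
    table = per_metric_ranks.copy()
    table["rank_sum"] = table[METRIC_COLUMNS].sum(axis=1)
    # ascending dense rank of the sum: smallest sum -> sumRank 1
    table["sumRank"] = dense_rank_desc(-table["rank_sum"].to_numpy(dtype=float))
    return table


def diagnostic_report(evaluation: pd.DataFrame, rank_table: pd.DataFrame,
                      out_dir) -> list[Path]:
    """Write the evaluation matrix, the rank table and two diagnostic plots."""
    if evaluation.shape[0] == 0:
        raise ValueError("empty method list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    eval_path = out_dir / "evaluation_matrix.tsv"
    evaluation.rename_axis("method").to_csv(eval_path, sep="\t", float_format="%.10g")
    files.append(eval_path)

    # sort by sumRank; tied methods listed alphabetically
    ordered = rank_table.loc[
        rank_table.assign(_m=rank_table.index).sort_values(["sumRank", "_m"]).index
    ]
    rank_path = out_dir / "rank_table.tsv"
    ordered.rename_axis("method").to_csv(rank_path, sep="\t")
    files.append(rank_path)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(evaluation) + 2))
    ranks = rank_table[METRIC_COLUMNS]
    im = ax.imshow(ranks.to_numpy(), cmap="viridis_r", aspect="auto")
    ax.set_xticks(range(len(METRIC_COLUMNS)), METRIC_COLUMNS)
    ax.set_yticks(range(len(ranks.index)), ranks.index)
    for i in range(ranks.shape[0]):
        for j in range(ranks.shape[1]):
            ax.text(j, i, str(ranks.iat[i, j]), ha="center", va="center", fontsize=8)
    ax.set_title("Per-metric dense ranks (1 = best)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    heat_path = out_dir / "rank_heatmap.png"
    fig.tight_layout()
    fig.savefig(heat_path, dpi=120)
    plt.close(fig)
    files.append(heat_path)

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(ordered) + 2))
    ax.barh(range(len(ordered)), ordered["rank_sum"], color="steelblue")
    ax.set_yticks(range(len(ordered)), ordered.index)
    ax.invert_yaxis()
    ax.set_xlabel("rank sum over e1..e6 (smaller = better)")
    ax.set_title("sumRank ordering")
    bar_path = out_dir / "sumrank_barplot.png"
    fig.tight_layout()
    fig.savefig(bar_path, dpi=120)
    plt.close(fig)
    files.append(bar_path)
    return files
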