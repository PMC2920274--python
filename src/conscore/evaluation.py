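"""Catalytic-site prediction performance: per-alignment ROC/AUC.

Each alignment with at least one catalytic and one non-catalytic
analyzable column yields one AUC per method (the probability that a
random catalytic column outranks a random non-catalytic one, with the
midrank tie convention).  Mean AUC is reported over alignments, optionally
restricted to alignments of at most ``max_N`` sequences to expose the
size dependence of the methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .comparison import method_names


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC of conservation scores against catalytic labels."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both a positive and a negative class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def per_alignment_auc(score_table: pd.DataFrame) -> pd.DataFrame:
    """One row per (alignment, method) AUC; single-class alignments skipped."""
    names = method_names(score_table)
    rows = []
    for aln_id, group in score_table.groupby("alignment_id", sort=False):
        labels = group["is_catalytic"].to_numpy(dtype=bool)
        if labels.all() or not labels.any():
            continue
        for name in names:
            rows.append(
                {
                    "alignment_id": aln_id,
                    "method": name,
                    "auc": roc_auc(group[name].to_numpy(), labels),
                }
            )
    return pd.DataFrame(rows, columns=["alignment_id", "method", "auc"])


@dataclass(frozen=True)
class AucReport:
    method: str
    max_N: int | None
    mean_auc: float
    n_alignments_used: int


def mean_auc_by_size_cap(
    score_table: pd.DataFrame,
    alignment_sizes: dict[str, int],
    caps: list[int] | None = None,
) -> pd.DataFrame:
    """Mean AUC per method for alignments with ``N <= cap``.

    ``caps=None`` gives a single uncapped report.  Caps must be ascending;
    a cap excluding every eligible alignment produces no rows.  Averaging
    over alignments is unweighted.
    """
    if caps is not None and list(caps) != sorted(caps):
        raise ValueError("caps must be ascending")
    per_aln = per_alignment_auc(score_table)
    if per_aln.empty:
        return pd.DataFrame(columns=["method", "max_N", "mean_auc", "n_alignments"])
    per_aln = per_aln.assign(
        N=per_aln["alignment_id"].map(alignment_sizes).astype(int)
    )
    rows = []
    for cap in [None] if caps is None else caps:
        sub = per_aln if cap is None else per_aln[per_aln["N"] <= cap]
        if sub.empty:
            continue
        agg = sub.groupby("method", sort=False)["auc"].agg(["mean", "count"])
        for name, row in agg.iterrows():
            rows.append(
                {
                    "method": name,
                    "max_N": cap,
                    "mean_auc": row["mean"],
                    "n_alignments": int(row["count"]),
                }
            )
    return pd.DataFrame(rows, columns=["method", "max_N", "mean_auc", "n_alignments"])
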