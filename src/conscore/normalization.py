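"""Within-alignment rank normalization and ranking-contrast reports.

Because the pipeline compares rankings throughout, scores are normalized
per alignment by fractional rank: the most conserved site(s) get exactly
1.0 and an all-tied alignment normalizes to all 1.0.  The contrast report
reproduces the worked-example layout: for one chosen column, every
method's normalized value side by side, optionally labeled by cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .comparison import method_names


def normalize_within_alignment(values: np.ndarray) -> np.ndarray:
    """Fractional-rank normalization onto (0, 1] with top ties pinned at 1.0.

    Ranks ascend with conservation and ties share the maximal rank of
    their group, so every member of the most-conserved tie group maps to
    exactly 1.0.  Idempotent and invariant under strictly monotone
    transforms of the input.
    """
    values = np.asarray(values, dtype=float)
    return rankdata(values, method="max") / len(values)


def normalize_score_table(score_table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_within_alignment` per alignment and method."""
    names = method_names(score_table)
    out = score_table.copy()
    for _, idx in out.groupby("alignment_id", sort=False).groups.items():
        for name in names:
            out.loc[idx, name] = normalize_within_alignment(
                out.loc[idx, name].to_numpy()
            )
    return out


def ranking_contrast_report(
    score_table: pd.DataFrame,
    alignment_id: str,
    column: int,
    cluster_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalized value of one column under every method, sorted descending.

    ``column`` is the 1-based source index of an analyzable column.
    Returns a DataFrame with columns ``method``, ``cluster``, ``value``.
    """
    sub = score_table[score_table["alignment_id"] == alignment_id]
    if sub.empty:
        raise KeyError(f"alignment {alignment_id!r} not in score table")
    if column not in set(sub["column"]):
        raise KeyError(
            f"column {column} is not an analyzable column of {alignment_id!r}"
        )
    normalized = normalize_score_table(sub)
    row = normalized[normalized["column"] == column].iloc[0]
    labels = cluster_labels or {}
    report = pd.DataFrame(
        {
            "method": method_names(score_table),
            "cluster": [labels.get(m, "") for m in method_names(score_table)],
            "value": [row[m] for m in method_names(score_table)],
        }
    )
    return report.sort_values("value", ascending=False, ignore_index=True)
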