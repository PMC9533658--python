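"""Unweighted condition summaries.

The study design analyses condition by unweighted counts: number and
percent of wetlands in each condition category, overall or by grouping
labels (grassland type, hydrologic class), plus mean ± SD of the index
totals.  Because results are category counts there are no associated
confidence intervals; none are computed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .ipci import IPCIResult, METRIC_IDS, default_category_table, round_half_up

__all__ = ["results_frame", "summarize", "format_summary", "write_results"]

_GROUP_LABELS = ("hydro_class", "grassland_type")


def results_frame(results: Sequence[IPCIResult]) -> pd.DataFrame:
    """One row per assessed wetland: metrics, scores, total, category."""
    rows = []
    for r in results:
        row: dict = {
            "site_id": r.site_id,
            "hydro_class": r.hydro_class,
            "grassland_type": r.grassland_type,
        }
        row.update(r.metrics.as_dict())
        row.update({f"score_{mid}": s for mid, s in zip(METRIC_IDS, r.scores)})
        row["total"] = r.total
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_frame(df: pd.DataFrame, group_by: Sequence[str] = ()) -> pd.DataFrame:
    """Summarize a per-wetland assessment table (see :func:`results_frame`)."""
    if df.empty:
        raise ValueError("no results to summarize")
    for g in group_by:
        if g not in df.columns:
            raise ValueError(f"grouping label {g!r} missing from results")
    categories = default_category_table().all_categories()

    def one_group(sub: pd.DataFrame) -> dict:
        n = len(sub)
        out = {"n": n}
        for cat in categories:
            out[f"pct_{cat.lower().replace(' ', '_')}"] = round_half_up(
                100.0 * (sub["category"] == cat).sum() / n, 1
            )
        out["mean_total"] = round_half_up(float(sub["total"].mean()), 1)
        out["sd_total"] = (
            round_half_up(float(sub["total"].std(ddof=1)), 1) if n > 1 else 0.0
        )
        return out

    if not group_by:
        return pd.DataFrame([{"group": "all", **one_group(df)}])
    rows = []
    for keys, sub in df.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_by, keys))
        row.update(one_group(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    results: Sequence[IPCIResult], group_by: Sequence[str] = ()
) -> pd.DataFrame:
    """Unweighted category percentages and mean ± SD of totals per group.

    ``group_by`` may name any of ``hydro_class`` / ``grassland_type``;
    empty means one overall row.  Percentages are reported to one decimal
    (half-away-from-zero) and SD uses the n-1 denominator.
    """
    if not results:
        raise ValueError("no results to summarize")
    for g in group_by:
        if g not in _GROUP_LABELS:
            raise ValueError(f"unknown grouping label {g!r}; use {_GROUP_LABELS}")
    return summarize_frame(results_frame(results), group_by)


def format_summary(summary: pd.DataFrame) -> str:
    """Plain-text table of a summary frame."""
    return summary.to_string(index=False)


def write_results(
    results: Sequence[IPCIResult], path: Union[str, Path]
) -> None:
    """Write per-wetland assessment rows as delimited text."""
    results_frame(results).to_csv(path, index=False)


def category_barchart(summary: pd.DataFrame, path: Union[str, Path],
                      group_col: Optional[str] = None) -> None:
    """Optional bar-chart export of category percentages (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct_cols = [c for c in summary.columns if c.startswith("pct_")]
    labels = [c[4:].replace("_", " ") for c in pct_cols]
    fig, ax = plt.subplots(figsize=(7, 4))
    idx = summary[group_col] if group_col else summary.get("group", ["all"])
    width = 0.8 / len(summary)
    for i, (_, row) in enumerate(summary.iterrows()):
        ax.bar(
            [j + i * width for j in range(len(pct_cols))],
            [row[c] for c in pct_cols],
            width=width,
            label=str(idx.iloc[i]) if hasattr(idx, "iloc") else "all",
        )
    ax.set_xticks(range(len(pct_cols)))
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("Percent of wetlands")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
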