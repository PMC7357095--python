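"""Indicated-vs-control statistics: t-test, LS-means slice F tests, BH-FDR.

The subgroup analysis fits, per classification category, a cell-means linear
model of the unique-pair SJI on the cells (subgroup × indication).  Because
group sizes are heavily unbalanced, the comparison inside each subgroup uses
least-squares means with the model-wide pooled residual mean square: the
slice (partition) F statistic for subgroup *s* is

    F_s = (m_I - m_C)^2 / ( MSE * (1/n_I + 1/n_C) ),   df = (1, N - #cells)

where m_I, m_C are the indicated and control cell means within *s*, and MSE
is the pooled within-cell residual mean square over all cells of the
category's model.  Pooling the residual variance is what lets a subgroup
with a single indicated pair still be tested (its own SD is undefined).

All tested subgroups — across the five categories jointly, by default —
form one Benjamini–Hochberg family; q < 0.05 flags a subgroup whose
indicated pairs score significantly differently from its controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .subgroups import CATEGORIES

log = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "DegenerateDataError",
    "overall_t_test",
    "slice_f_tests",
    "bh_fdr",
    "subgroup_analysis",
    "format_results_table",
]

RESULT_COLUMNS = [
    "category",
    "subgroup",
    "n_indicated",
    "n_control",
    "mean_indicated",
    "sd_indicated",
    "mean_control",
    "sd_control",
    "f_statistic",
    "p_value",
    "q_value",
    "tested",
]


class DegenerateDataError(ValueError):
    """Input data too degenerate for the requested test."""


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variant: str


def overall_t_test(
    indicated_sjis: Sequence[float],
    control_sjis: Sequence[float],
    variant: str = "pooled",
) -> TTestResult:
    """Two-sided two-sample t-test on unique-pair SJIs.

    ``variant="pooled"`` assumes equal variances (consistent with the
    pooled-MSE subgroup model); ``"welch"`` drops that assumption.  Groups
    with identical constant values give p = 1 by convention; constant groups
    with unequal means are rejected as degenerate.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(indicated_sjis, dtype=float)
    b = np.asarray(control_sjis, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TTestResult(statistic=0.0, df=df, p_value=1.0, variant=variant)
        raise DegenerateDataError(
            "zero variance in both groups with unequal means: t undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
    )


def slice_f_tests(
    pairs_with_sji: pd.DataFrame,
    subgroup_table: pd.DataFrame,
    category: str,
) -> pd.DataFrame:
    """Per-subgroup LS-means slice F tests within one classification category.

    ``pairs_with_sji`` is a unique-pair table (``drug_name``,
    ``disease_name``, ``mean_sji``, ``indicated``); ``subgroup_table`` maps
    pairs to subgroup labels.  Subgroups with only one indication level are
    returned untested (``tested=False``, NaN statistics).  ``q_value`` is
    left NaN — attach it across categories with :func:`bh_fdr` or use
    :func:`subgroup_analysis`.
    """
    table = subgroup_table[subgroup_table["category"] == category]
    merged = table.merge(
        pairs_with_sji[["drug_name", "disease_name", "mean_sji", "indicated"]],
        on=["drug_name", "disease_name"],
        how="inner",
    )
    if merged.empty:
        raise DegenerateDataError(f"category {category!r}: no annotated pairs")

    cells = merged.groupby(["subgroup", "indicated"])["mean_sji"].agg(
        ["count", "mean", "var"]
    )
    n_obs = len(merged)
    n_cells = len(cells)
    df_resid = n_obs - n_cells
    if df_resid <= 0:
        raise DegenerateDataError(
            f"category {category!r}: residual df {df_resid} <= 0; "
            "merge subgroups or add data"
        )
    # pooled within-cell SSE; single-observation cells contribute 0
    sse = float(((cells["count"] - 1) * cells["var"].fillna(0.0)).sum())
    mse = sse / df_resid

    rows = []
    for subgroup in sorted(merged["subgroup"].unique()):
        def _cell(flag):
            try:
                return cells.loc[(subgroup, flag)]
            except KeyError:
                return None

        ind, ctl = _cell(True), _cell(False)
        row = {
            "category": category,
            "subgroup": subgroup,
            "n_indicated": int(ind["count"]) if ind is not None else 0,
            "n_control": int(ctl["count"]) if ctl is not None else 0,
            "mean_indicated": float(ind["mean"]) if ind is not None else np.nan,
            "sd_indicated": (
                float(np.sqrt(ind["var"])) if ind is not None and ind["count"] > 1
                else np.nan
            ),
            "mean_control": float(ctl["mean"]) if ctl is not None else np.nan,
            "sd_control": (
                float(np.sqrt(ctl["var"])) if ctl is not None and ctl["count"] > 1
                else np.nan
            ),
            "f_statistic": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "tested": False,
        }
        if ind is not None and ctl is not None and mse > 0:
            n_i, n_c = int(ind["count"]), int(ctl["count"])
            diff = float(ind["mean"]) - float(ctl["mean"])
            f = diff**2 / (mse * (1.0 / n_i + 1.0 / n_c))
            row["f_statistic"] = f
            row["p_value"] = float(sps.f.sf(f, 1, df_resid))
            row["tested"] = True
        elif ind is not None and ctl is not None:
            # zero pooled residual variance: identical means -> no evidence
            row["f_statistic"] = 0.0 if ind["mean"] == ctl["mean"] else np.inf
            row["p_value"] = 1.0 if ind["mean"] == ctl["mean"] else 0.0
            row["tested"] = True
        rows.append(row)
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    result.attrs["df_resid"] = df_resid
    result.attrs["mse"] = mse
    return result


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def subgroup_analysis(
    pairs_with_sji: pd.DataFrame,
    subgroup_table: pd.DataFrame,
    categories: Sequence[str] = CATEGORIES,
    fdr_family: str = "pooled",
) -> pd.DataFrame:
    """Slice F tests for every category, with BH q-values attached.

    ``fdr_family="pooled"`` (default) corrects all tested subgroups from all
    categories as one family; ``"per_category"`` corrects each category
    separately.
    """
    if fdr_family not in ("pooled", "per_category"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    frames = []
    for category in categories:
        if (subgroup_table["category"] == category).any():
            frames.append(slice_f_tests(pairs_with_sji, subgroup_table, category))
    if not frames:
        raise DegenerateDataError("no category has annotated pairs")
    results = pd.concat(frames, ignore_index=True)
    if fdr_family == "pooled":
        tested = results["tested"]
        if tested.any():
            results.loc[tested, "q_value"] = bh_fdr(results.loc[tested, "p_value"])
    else:
        for category in categories:
            mask = (results["category"] == category) & results["tested"]
            if mask.any():
                results.loc[mask, "q_value"] = bh_fdr(results.loc[mask, "p_value"])
    return results


def format_results_table(results: pd.DataFrame) -> pd.DataFrame:
    """Render subgroup results with '----------' for undefined SDs."""
    out = results.copy()
    for col in ("sd_indicated", "sd_control"):
        out[col] = out[col].map(
            lambda v: "----------" if pd.isna(v) else f"{v:.5f}"
        )
    return out
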