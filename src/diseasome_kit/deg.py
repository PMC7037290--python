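"""Differential-expression calling on case/control log2 matrices.

Per gene: an unpaired two-sided Welch t-test between case and control
samples, a log2 fold change (case mean minus control mean; the matrix is
already on the log2 scale so the difference of means IS the log2 fold
change), Benjamini-Hochberg adjustment across genes, and a signed call:

* ``up``      if logFC >  fc_threshold and the p criterion is met,
* ``down``    if logFC < -fc_threshold and the p criterion is met,
* ``neutral`` otherwise,
* ``degenerate`` when no finite t statistic exists (both groups constant
  at different values).

Thresholds default to the strict fold-change cut |logFC| > 1 with p < 0.01.
The p criterion uses the raw p-value by default; ``p_mode="adjusted"``
switches the same cut to BH-adjusted values (an FDR threshold).  A pooled
equal-variance t-test is available via ``equal_var=True``; Welch is the
default because it stays calibrated under unequal group variances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DiseaseGeneSet, ExpressionStudy

DEG_COLUMNS = ["symbol", "logFC", "t", "p", "p_adj", "call"]


def two_group_ttest(
    values_case, values_control, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided unpaired t-test (Welch by default) for one gene.

    Degenerate edge cases: if both groups are constant with equal means the
    test is vacuous and returns (0.0, 1.0); if both are constant with
    different means no finite t exists and (nan, nan) is returned — callers
    flag the gene degenerate.
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("both groups need at least 2 values for the t-test")
    if case.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        if case.mean() == control.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(case, control, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    study: ExpressionStudy,
    fc_threshold: float = 1.0,
    alpha: float = 0.01,
    p_mode: str = "raw",
    equal_var: bool = False,
) -> tuple[pd.DataFrame, DiseaseGeneSet]:
    """Call DEGs for one study.

    Returns the per-gene table (symbol, logFC, t, p, p_adj, call) and the
    signed :class:`DiseaseGeneSet`.  Strict inequalities are applied at both
    thresholds; a gene with logFC exactly at the cut is neutral.
    """
    if p_mode not in ("raw", "adjusted"):
        raise ValueError(f"unknown p_mode '{p_mode}'")
    study.validate()
    case = study.values[:, study.group_columns("case")]
    control = study.values[:, study.group_columns("control")]

    logfc = case.mean(axis=1) - control.mean(axis=1)
    var_case = case.var(axis=1, ddof=1)
    var_control = control.var(axis=1, ddof=1)
    both_const = (var_case == 0.0) & (var_control == 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # both groups constant: vacuous test if means agree, degenerate otherwise
    vacuous = both_const & (logfc == 0.0)
    degenerate = both_const & (logfc != 0.0)
    t[vacuous], p[vacuous] = 0.0, 1.0
    t[degenerate], p[degenerate] = np.nan, np.nan

    p_adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        p_adj[ok] = bh_adjust(p[ok])

    p_crit = p if p_mode == "raw" else p_adj
    significant = ok & (p_crit < alpha)
    calls = np.where(
        degenerate,
        "degenerate",
        np.where(
            significant & (logfc > fc_threshold),
            "up",
            np.where(significant & (logfc < -fc_threshold), "down", "neutral"),
        ),
    )

    table = pd.DataFrame(
        {
            "symbol": study.gene_ids,
            "logFC": logfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "call": calls,
        }
    )
    gene_set = DiseaseGeneSet(
        disease_id=study.disease_id,
        up=set(table.loc[table["call"] == "up", "symbol"]),
        down=set(table.loc[table["call"] == "down", "symbol"]),
    )
    return table, gene_set


def top_by_magnitude(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k called DEGs of greatest |logFC|, for shortlist reports.

    No default filtering is applied anywhere in the pipeline; this is an
    optional report.
    """
    called = table[table["call"].isin(["up", "down"])]
    return called.reindex(
        called["logFC"].abs().sort_values(ascending=False).index
    ).head(k)
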