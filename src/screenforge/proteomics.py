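"""Spectral-count differential proteomics.

Replicate-averaged spectral counts give a per-protein log2 fold change; a
two-sided Welch t-test across the replicate values gives a p-value.  Two
nested result sets follow: the study set (log2FC >= 1 and p < 0.05) and the
GSEA list (p < 0.05, ranked by log2FC) which feeds the preranked enrichment
module against hallmark-style GMT gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import permutation_p
from .stats import bh_adjust

__all__ = [
    "log2_fold_change",
    "welch_t",
    "differential_proteins",
    "build_study_sets",
    "preranked_gsea",
]


def log2_fold_change(case_counts, control_counts, pseudocount: float = 0.5) -> float:
    """log2((mean case + c) / (mean control + c)).

    Spectral-count tables contain zeros, so a small pseudocount keeps the
    ratio defined; with both means zero the fold change is exactly 0.
    """
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("need at least one count per condition")
    return float(np.log2((case.mean() + pseudocount)
                         / (control.mean() + pseudocount)))


def welch_t(case_values, control_values) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t-test: (t, Satterthwaite df, p).

    Degenerate zero-variance inputs: equal means give (0, df, 1); unequal
    means give p = 0 (an infinitely confident, flagged-degenerate call).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def differential_proteins(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 0.5,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-protein differential table for a case vs control comparison.

    ``design`` maps sample_id to condition in {case, control}; biological and
    technical replicates all enter the Welch test as observations.  Returns
    per-protein means, log2fc, Welch statistics, BH-adjusted p, and the two
    membership flags (``in_study_set``: log2fc >= lfc_threshold and
    p < p_threshold; ``in_gsea_list``: p < p_threshold).
    """
    case_cols = design.loc[design["condition"] == "case", "sample_id"]
    ctrl_cols = design.loc[design["condition"] == "control", "sample_id"]
    if case_cols.empty or ctrl_cols.empty:
        raise ValueError("design needs both case and control samples")
    case = counts[list(case_cols)].to_numpy(dtype=float)
    ctrl = counts[list(ctrl_cols)].to_numpy(dtype=float)
    rows = []
    for i, pid in enumerate(counts.index):
        lfc = log2_fold_change(case[i], ctrl[i], pseudocount)
        t, df, p = welch_t(case[i], ctrl[i])
        rows.append((pid, case[i].mean(), ctrl[i].mean(), lfc, t, df, p))
    out = pd.DataFrame(rows, columns=[
        "protein_id", "mean_case", "mean_control", "log2fc", "t", "df",
        "p_welch",
    ])
    out["padj"] = bh_adjust(np.clip(out["p_welch"], np.finfo(float).tiny, 1.0))
    out["in_study_set"] = (out["log2fc"] >= lfc_threshold) & \
        (out["p_welch"] < p_threshold)
    out["in_gsea_list"] = out["p_welch"] < p_threshold
    return out


def build_study_sets(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(study set, GSEA ranked list) from a differential table.

    The study set is the stringent filter (upregulated at log2FC >= 1 with
    p < 0.05); the GSEA list is every protein with p < 0.05 ranked by
    descending log2 fold change.  The study set is always a subset of the
    GSEA list.
    """
    study = results[results["in_study_set"]].reset_index(drop=True)
    ranked = results[results["in_gsea_list"]].sort_values(
        "log2fc", ascending=False, kind="mergesort", ignore_index=True
    )
    return study, ranked


def preranked_gsea(
    ranked: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Preranked enrichment of GMT gene sets in the p < 0.05 protein list.

    Sets are restricted to their overlap with the ranked proteins; sets with
    fewer than ``min_overlap`` ranked members are skipped.  BH adjustment is
    applied across tested sets.
    """
    items = list(ranked["protein_id"])
    scores = ranked["log2fc"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sorted(gene_sets.items()):
        overlap = members & set(items)
        if len(overlap) < min_overlap or len(overlap) == len(items):
            continue
        es, p = permutation_p(
            scores, members=overlap, items=items, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append((name, len(overlap), es, p))
    out = pd.DataFrame(rows, columns=["gene_set", "n_hits", "es", "p_perm"])
    if not out.empty:
        out["padj"] = bh_adjust(out["p_perm"].to_numpy())
        out = out.sort_values(["padj", "p_perm", "gene_set"],
                              ignore_index=True)
    else:
        out["padj"] = pd.Series(dtype=float)
    return out
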