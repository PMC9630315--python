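"""Triplex-Seq lncRNA prioritization: Poisson enrichment and filter cascade.

A peak's enrichment is judged against a Poisson model of its expected read
count: fold enrichment is observed/expected and the p-value is the upper
tail P(X >= observed | lambda = expected). Candidate lncRNAs are then run
through a fixed cascade of filters — fold enrichment > 10 and
-log10(p) > 20 on the best peak, presence in both cell lines, a positive
nuclear expression value, positive signal in each endothelial tissue, a
coding probability below the non-coding cutoff, and absence of an
overlapping-gene conflict (the manual-inspection step encoded as an input
flag). Filter outcomes are pure functions of the row and the thresholds,
so the screen is invariant to row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import TISSUE_COLUMNS

#: -log10(p) values are capped here to keep scores finite.
NEG_LOG10_CAP = 300.0


def poisson_enrichment(observed, expected):
    """Fold enrichment and upper-tail Poisson p-value of a peak.

    ``p = P(X >= observed)`` with X ~ Poisson(expected); the tail is closed
    at the observed count, so observed = 0 gives p = 1. Accepts scalars or
    arrays; expected must be positive.
    """
    obs = np.asarray(observed)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected read rate must be positive")
    if np.any(obs < 0):
        raise ValueError("observed read counts must be non-negative")
    fold = obs / exp
    p = stats.poisson.sf(obs - 1, exp)  # sf(k) = P(X > k), so sf(obs-1) = P(X >= obs)
    if np.ndim(observed) == 0 and np.ndim(expected) == 0:
        return float(fold), float(p)
    return fold, p


def neg_log10(p, cap: float = NEG_LOG10_CAP):
    """-log10(p), capped to avoid non-finite scores at underflowing p."""
    with np.errstate(divide="ignore"):
        score = -np.log10(p)
    score = np.minimum(score, cap)
    return float(score) if np.ndim(p) == 0 else score


def annotate_peaks(peaks: pd.DataFrame, cap: float = NEG_LOG10_CAP) -> pd.DataFrame:
    """Add fold_enrichment, p_enrich and neg_log10_p columns to a peak table."""
    for col in ("observed_reads", "expected_reads"):
        if col not in peaks.columns:
            raise ValueError(f"peak table is missing required column {col!r}")
    out = peaks.copy()
    fold, p = poisson_enrichment(
        out["observed_reads"].to_numpy(), out["expected_reads"].to_numpy()
    )
    out["fold_enrichment"] = fold
    out["p_enrich"] = p
    out["neg_log10_p"] = neg_log10(p, cap)
    return out


def best_peaks(annotated: pd.DataFrame) -> pd.DataFrame:
    """Reduce an annotated peak table to one row per lncRNA.

    ``best_fold_enrichment`` and ``best_neg_log10_p`` are the per-lncRNA
    maxima over its peaks (the stringency cuts apply to the best peak).
    """
    grouped = annotated.groupby("lncrna_id", sort=True)
    out = grouped.agg(
        best_fold_enrichment=("fold_enrichment", "max"),
        best_neg_log10_p=("neg_log10_p", "max"),
    ).reset_index()
    return out


def intersect_cell_lines(set_a, set_b) -> list[str]:
    """lncRNA identifiers present in both cell lines, sorted."""
    return sorted(set(set_a) & set(set_b))


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs of the prioritization cascade; fold/p cuts are strict (>)."""

    fold_cut: float = 10.0
    logp_cut: float = 20.0
    nuclear_min: float = 0.0
    tissue_min: float = 0.0
    coding_cut: float = 0.364  # published CPAT human coding-probability cutoff
    tissue_columns: tuple = TISSUE_COLUMNS


#: Cascade order used for attrition attribution (first failing filter counts).
FILTER_ORDER = (
    "fold_enrichment", "neg_log10_p", "cell_line_overlap",
    "nuclear_expression", "tissue_expression", "non_coding", "gene_conflict",
)

_REQUIRED_COLUMNS = (
    "lncrna_id", "best_fold_enrichment", "best_neg_log10_p",
    "present_in_both_cell_lines", "nuclear_signal",
    "coding_probability", "overlapping_gene_conflict",
)


def apply_screen(rows: pd.DataFrame,
                 thresholds: ScreenThresholds = ScreenThresholds()):
    """Run the full filter cascade over candidate rows.

    Returns (retained rows with per-filter pass flags, attrition report).
    The retained set is the conjunction of all filters and is independent
    of row order and of the order filters are evaluated in; the attrition
    report attributes each removed row to the first filter (in the fixed
    cascade order) that rejects it.
    """
    for col in _REQUIRED_COLUMNS + tuple(thresholds.tissue_columns):
        if col not in rows.columns:
            raise ValueError(f"candidate table is missing required column {col!r}")
    df = rows.copy()
    tissue_ok = np.ones(len(df), dtype=bool)
    for col in thresholds.tissue_columns:
        tissue_ok &= df[col].to_numpy() > thresholds.tissue_min
    passes = {
        "fold_enrichment": df["best_fold_enrichment"].to_numpy() > thresholds.fold_cut,
        "neg_log10_p": df["best_neg_log10_p"].to_numpy() > thresholds.logp_cut,
        "cell_line_overlap": df["present_in_both_cell_lines"].to_numpy().astype(bool),
        "nuclear_expression": df["nuclear_signal"].to_numpy() > thresholds.nuclear_min,
        "tissue_expression": tissue_ok,
        "non_coding": df["coding_probability"].to_numpy() < thresholds.coding_cut,
        "gene_conflict": ~df["overlapping_gene_conflict"].to_numpy().astype(bool),
    }
    for name in FILTER_ORDER:
        df[f"pass_{name}"] = passes[name]
    all_pass = np.logical_and.reduce([passes[name] for name in FILTER_ORDER])

    removed_by = {}
    still_in = np.ones(len(df), dtype=bool)
    for name in FILTER_ORDER:
        fails_here = still_in & ~passes[name]
        removed_by[name] = int(fails_here.sum())
        still_in &= passes[name]
    removed_counts = np.array([removed_by[name] for name in FILTER_ORDER])
    attrition = pd.DataFrame({
        "filter": list(FILTER_ORDER),
        "removed": removed_counts,
        "remaining": len(df) - removed_counts.cumsum(),
    })
    retained = df[all_pass].reset_index(drop=True)
    return retained, attrition
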