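"""qPCR validation statistics: delta-delta Ct, percent input, RNase-H ratio.

These are the quantitative read-outs used to verify triplex association in
the wet lab: relative expression by the delta-delta Ct method, RIP/ChIP
recovery expressed as percent of a measured input aliquot (dilution
adjusted), and the ratio of percent-input recovery with vs without RNase H
treatment. RNase H digests the RNA of DNA:RNA heteroduplexes but leaves
triplex-bound RNA intact, so a ratio near 1 marks RNase-H-resistant
(triplex-like) association and a ratio well below 1 marks
heteroduplex-like sensitivity.

Amplification efficiency is assumed perfect (one doubling per cycle) by
default and is configurable. Replicate folds are aggregated by geometric
mean, i.e. arithmetic mean in the delta-delta Ct (log) domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_EFFICIENCY = 2.0


def ddct_fold(target_ct: float, ref_ct: float,
              target_ct_ctrl: float, ref_ct_ctrl: float,
              efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """Fold change by the delta-delta Ct method.

    ddCt = (target_ct - ref_ct) - (target_ct_ctrl - ref_ct_ctrl) and the
    fold change is efficiency**(-ddCt). Adding a constant to all four Ct
    values leaves the result unchanged.
    """
    for v in (target_ct, ref_ct, target_ct_ctrl, ref_ct_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_ct - ref_ct) - (target_ct_ctrl - ref_ct_ctrl)
    return float(efficiency ** (-ddct))


def percent_input(ct_ip: float, ct_input: float, input_fraction: float,
                  efficiency: float = DEFAULT_EFFICIENCY,
                  dilution_adjust: bool = True) -> float:
    """Recovery of an immunoprecipitation as percent of input material.

    The input aliquot is only ``input_fraction`` of the sample (e.g. 0.10
    or 0.05), so its Ct is first shifted by log_E(1/fraction) cycles to
    represent 100% input; recovery is then 100 * E**(adjusted_input_ct -
    ct_ip). Set ``dilution_adjust=False`` to skip the aliquot correction.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    adjusted = ct_input
    if dilution_adjust:
        adjusted = ct_input - math.log(1.0 / input_fraction, efficiency)
    return float(100.0 * efficiency ** (adjusted - ct_ip))


@dataclass(frozen=True)
class RecoveryRatio:
    """Percent-input recovery with/without RNase H and their ratio."""

    analyte_id: str
    pct_input_plus_rnaseh: float
    pct_input_minus_rnaseh: float
    ratio: float


def rnaseh_ratio(pct_plus: float, pct_minus: float,
                 analyte_id: str = "") -> RecoveryRatio:
    """Ratio of percent-input recovery with vs without RNase H treatment."""
    if pct_plus < 0 or pct_minus < 0:
        raise ValueError("percent-input recoveries must be non-negative")
    if pct_minus == 0:
        raise ValueError("recovery without RNase H is zero; ratio undefined")
    return RecoveryRatio(analyte_id, float(pct_plus), float(pct_minus),
                         float(pct_plus / pct_minus))


def aggregate_folds(folds) -> float:
    """Geometric mean of replicate fold changes (mean of ddCt values)."""
    f = np.asarray(list(folds), dtype=float)
    if len(f) == 0:
        raise ValueError("no folds to aggregate")
    if np.any(f <= 0):
        raise ValueError("fold changes must be positive")
    return float(np.exp(np.mean(np.log(f))))


def analyze_ct_table(table: pd.DataFrame,
                     efficiency: float = DEFAULT_EFFICIENCY) -> pd.DataFrame:
    """Treated-vs-control fold change per sample from a long-format Ct table.

    Expects columns sample_id, condition ('treated'/'control'), replicate,
    target_ct, reference_ct. The control delta-Ct baseline is the mean over
    control replicates; per-replicate treated folds are aggregated by
    geometric mean. Returns one row per sample with the recovered fold.
    """
    required = {"sample_id", "condition", "replicate", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    rows = []
    for sample, grp in table.groupby("sample_id", sort=True):
        ctrl = grp[grp["condition"] == "control"]
        trt = grp[grp["condition"] == "treated"]
        if ctrl.empty or trt.empty:
            raise ValueError(f"sample {sample!r} lacks a treated or control arm")
        baseline = float((ctrl["target_ct"] - ctrl["reference_ct"]).mean())
        dct = trt["target_ct"].to_numpy() - trt["reference_ct"].to_numpy()
        folds = efficiency ** (-(dct - baseline))
        rows.append({
            "sample_id": sample,
            "n_replicates": len(trt),
            "fold_change": aggregate_folds(folds),
        })
    return pd.DataFrame(rows)
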