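"""Relative qPCR quantification (delta-CT) and microarray concordance.

Duplicate CT measurements are averaged on the cycle scale, then
``dCT = CT(gene) - CT(housekeeping)`` and relative expression ``2**-dCT``.
A gene is called regulated between two conditions when the expression ratio
reaches twofold (inclusive, in either direction).  The concordance table
compares, per donor and gene, the twofold call from the microarray fold
change against the twofold call from qPCR, and summarizes the fraction of
concordant cells — the cross-method consistency check applied to the
candidate genes from the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .paired_selection import SelectionResult

HOUSEKEEPING_GENE = "RPS29"


@dataclass
class QpcrRecord:
    sample_id: str
    gene: str
    ct_mean: float  # NaN when the target never amplified
    housekeeping_ct_mean: float
    delta_ct: float
    relative_expression: float  # 2**-delta_ct; NaN when not detected

    @property
    def detected(self) -> bool:
        return not np.isnan(self.delta_ct)


def delta_ct(gene_cts: Sequence[float], housekeeping_cts: Sequence[float],
             sample_id: str = "", gene: str = "") -> QpcrRecord:
    """Average duplicate CTs on the cycle scale and form dCT and 2**-dCT.

    Undetermined CTs (NaN, i.e. no amplification) propagate: the record is
    marked non-detected and its expression is absent, not zero.
    """
    hk = [c for c in housekeeping_cts if not np.isnan(c)]
    if not hk:
        raise ContractError("housekeeping CT missing for sample "
                            f"{sample_id!r}")
    gene_arr = np.asarray(list(gene_cts), dtype=float)
    detected = gene_arr[~np.isnan(gene_arr)]
    hk_mean = float(np.mean(hk))
    if detected.size == 0:
        return QpcrRecord(sample_id, gene, float("nan"), hk_mean,
                          float("nan"), float("nan"))
    ct_mean = float(np.mean(detected))
    dct = ct_mean - hk_mean
    return QpcrRecord(sample_id, gene, ct_mean, hk_mean, dct,
                      float(2.0 ** -dct))


def qpcr_fold_change(record_a: QpcrRecord, record_b: QpcrRecord) -> float:
    """Expression ratio condition A over condition B, NaN when either
    condition was not detected."""
    if not (record_a.detected and record_b.detected):
        return float("nan")
    return record_a.relative_expression / record_b.relative_expression


def call_regulated(ratio: float, threshold: float = 2.0) -> str:
    """Direction call at a twofold (inclusive) boundary: ``up`` when the
    ratio is at least the threshold, ``down`` at or below its reciprocal,
    ``none`` in between, ``not_assessable`` for NaN."""
    if np.isnan(ratio):
        return "not_assessable"
    if ratio >= threshold:
        return "up"
    if ratio <= 1.0 / threshold:
        return "down"
    return "none"


def quantify_table(ct_table: pd.DataFrame,
                   housekeeping: str = HOUSEKEEPING_GENE) -> pd.DataFrame:
    """Quantify a long-format CT table.

    Input columns: ``sample, donor, condition, gene, ct_rep1, ct_rep2``
    (the housekeeping gene appears as ordinary rows).  Returns one row per
    sample x non-housekeeping gene with ``delta_ct`` and
    ``relative_expression`` columns added.
    """
    required = {"sample", "donor", "condition", "gene", "ct_rep1", "ct_rep2"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ContractError(f"CT table lacks columns {sorted(missing)}")
    hk = ct_table[ct_table["gene"] == housekeeping].set_index("sample")
    rows = []
    for _, row in ct_table[ct_table["gene"] != housekeeping].iterrows():
        if row["sample"] not in hk.index:
            raise ContractError(
                f"housekeeping CT missing for sample {row['sample']!r}"
            )
        h = hk.loc[row["sample"]]
        rec = delta_ct(
            [row["ct_rep1"], row["ct_rep2"]],
            [h["ct_rep1"], h["ct_rep2"]],
            sample_id=row["sample"], gene=row["gene"],
        )
        rows.append(
            {
                "sample": row["sample"], "donor": row["donor"],
                "condition": row["condition"], "gene": row["gene"],
                "delta_ct": rec.delta_ct,
                "relative_expression": rec.relative_expression,
            }
        )
    return pd.DataFrame(rows)


def qpcr_calls(quantified: pd.DataFrame, condition_a: str, condition_b: str,
               threshold: float = 2.0) -> pd.DataFrame:
    """Per donor x gene regulation calls between two conditions
    (A over B, heparin over none in the study design)."""
    pivot = quantified.pivot_table(
        index=["donor", "gene"], columns="condition",
        values="relative_expression", aggfunc="mean",
    )
    for cond in (condition_a, condition_b):
        if cond not in pivot.columns:
            raise ContractError(f"condition {cond!r} absent from CT table")
    ratio = pivot[condition_a] / pivot[condition_b]
    out = ratio.rename("qpcr_ratio").reset_index()
    out["qpcr_direction"] = [call_regulated(r, threshold) for r in out["qpcr_ratio"]]
    return out


def concordance_table(selection: SelectionResult, calls: pd.DataFrame,
                      threshold: float = 2.0) -> tuple[pd.DataFrame, float]:
    """Compare microarray and qPCR twofold calls per donor x gene.

    The microarray direction of each donor cell is the twofold call on that
    donor's fold change for the gene (from the screen's per-pair ratios).
    Genes present in only one source are listed with direction
    ``not_available`` and excluded from the summary fraction.

    Returns the per-cell table and the fraction of assessable cells whose
    directions agree.
    """
    donors = [c[len("ratio_"):] for c in selection.table.columns
              if c.startswith("ratio_")]
    array_long = []
    for _, row in selection.table.iterrows():
        for d in donors:
            array_long.append(
                {
                    "donor": d, "gene": row["gene"],
                    "array_ratio": row[f"ratio_{d}"],
                    "array_direction": call_regulated(
                        float(row[f"ratio_{d}"]), threshold),
                }
            )
    array_df = pd.DataFrame(array_long)
    merged = array_df.merge(calls, on=["donor", "gene"], how="outer")
    merged["array_direction"] = merged["array_direction"].fillna("not_available")
    merged["qpcr_direction"] = merged["qpcr_direction"].fillna("not_available")
    assessable = ~merged["array_direction"].isin(["not_available", "not_assessable"]) \
        & ~merged["qpcr_direction"].isin(["not_available", "not_assessable"])
    merged["concordant"] = np.where(
        assessable, merged["array_direction"] == merged["qpcr_direction"], False
    )
    n_assessable = int(assessable.sum())
    fraction = float(merged.loc[assessable, "concordant"].mean()) \
        if n_assessable else float("nan")
    return merged, fraction
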