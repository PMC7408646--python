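"""Collapse on-chip replicate populations to one value per probe.

Each non-control probe is printed several times on the array (quintuplicates
by default).  The replicate population is reduced to its geometric mean after
removing features that

  i.   were manually flagged,
  ii.  were flagged as outliers by the extraction software,
  iii. lie outside ``median +/- iqr_multiplier x IQR`` of the probe's
       replicate signal population (boundary values are kept), or
  iv.  have a pixel-intensity coefficient of variation above ``pixel_cv_max``.

The rules are applied as an independent union: a feature may trip several
rules and is counted in the tally of each one.  The interval for rule iii is
centred on the replicate-population median and computed on the raw signals of
that population, with linear-interpolation quantiles.  A replicate with a
signal of exactly zero cannot enter a geometric mean and is dropped with a
warning; if nothing survives, the probe's value is reported missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import NON_CONTROL
from .errors import ContractError

RULES = ("manual", "software_outlier", "iqr", "pixel_cv")


@dataclass(frozen=True)
class AggregationParams:
    """Tunables of the replicate-exclusion rules.

    iqr_multiplier : half-width of the rule-iii interval in IQR units.
    pixel_cv_max : rule-iv cap on the per-feature pixel CV.
    min_surviving_replicates : minimum survivors for a non-missing value.
    """

    iqr_multiplier: float = 1.42
    pixel_cv_max: float = 0.5
    min_surviving_replicates: int = 1

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if self.pixel_cv_max <= 0:
            raise ValueError("pixel_cv_max must be > 0")
        if self.min_surviving_replicates < 1:
            raise ValueError("min_surviving_replicates must be >= 1")


@dataclass
class AggregatedProbe:
    probe_id: str
    value: float  # geometric mean of surviving replicates, NaN if missing
    n_used: int
    exclusions: dict  # rule name -> count of replicates tripping it

    @property
    def missing(self) -> bool:
        return bool(np.isnan(self.value))


def _exclusion_masks(df: pd.DataFrame, params: AggregationParams,
                     grouped: bool) -> pd.DataFrame:
    """Per-feature boolean mask for each of the four rules."""
    gps = df["gps"]
    if grouped:
        stats = (
            df.groupby("probe_id", sort=False)["gps"]
            .quantile([0.25, 0.5, 0.75])
            .unstack()
        )
        med = df["probe_id"].map(stats[0.5])
        q1 = df["probe_id"].map(stats[0.25])
        q3 = df["probe_id"].map(stats[0.75])
    else:
        med = gps.median()
        q1 = gps.quantile(0.25)
        q3 = gps.quantile(0.75)
    iqr = q3 - q1
    lo = med - params.iqr_multiplier * iqr
    hi = med + params.iqr_multiplier * iqr
    return pd.DataFrame(
        {
            "manual": df["manual_flag"].to_numpy(dtype=bool),
            "software_outlier": df["outlier_flag"].to_numpy(dtype=bool),
            "iqr": ((gps < lo) | (gps > hi)).to_numpy(),
            "pixel_cv": (df["pixel_cv"] > params.pixel_cv_max).to_numpy(),
        },
        index=df.index,
    )


def aggregate_probe(features: pd.DataFrame,
                    params: AggregationParams | None = None) -> AggregatedProbe:
    """Aggregate the replicate population of a single probe.

    ``features`` holds one row per replicate of one probe (columns as read by
    :func:`mscarray.array_io.read_feature_table`).
    """
    params = params or AggregationParams()
    if len(features) == 0:
        raise ContractError("empty replicate population")
    ids = features["probe_id"].unique()
    if len(ids) != 1:
        raise ContractError(f"mixed probe ids in replicate population: {list(ids)}")

    masks = _exclusion_masks(features, params, grouped=False)
    excluded = masks.any(axis=1).to_numpy()
    gps = features["gps"].to_numpy(dtype=float)
    survivors = gps[~excluded]
    n_zero = int((survivors == 0).sum())
    if n_zero:
        warnings.warn(
            f"probe {ids[0]}: {n_zero} surviving replicate(s) with zero signal "
            "dropped from the geometric mean",
            stacklevel=2,
        )
        survivors = survivors[survivors > 0]
    if len(survivors) >= params.min_surviving_replicates:
        value = float(np.exp(np.mean(np.log(survivors))))
        n_used = len(survivors)
    else:
        value, n_used = float("nan"), 0
    return AggregatedProbe(
        probe_id=str(ids[0]),
        value=value,
        n_used=n_used,
        exclusions={r: int(masks[r].sum()) for r in RULES},
    )


def aggregate_array(features: pd.DataFrame,
                    params: AggregationParams | None = None) -> pd.DataFrame:
    """Aggregate a full sample: one row per unique non-control probe.

    Control features never appear in the output.  Returns a DataFrame with
    columns ``probe_id, gene_symbol, value, n_used`` plus one ``excl_<rule>``
    tally per exclusion rule, in first-appearance probe order.
    """
    params = params or AggregationParams()
    nc = features[features["control_type"] == NON_CONTROL]
    if len(nc) == 0:
        return pd.DataFrame(
            columns=["probe_id", "gene_symbol", "value", "n_used"]
            + [f"excl_{r}" for r in RULES]
        )
    masks = _exclusion_masks(nc, params, grouped=True)
    excluded = masks.any(axis=1).to_numpy()
    gps = nc["gps"].to_numpy(dtype=float)
    survives = ~excluded & (gps > 0)
    n_zero_surv = int((~excluded & (gps == 0)).sum())
    if n_zero_surv:
        warnings.warn(
            f"{n_zero_surv} surviving replicate(s) with zero signal dropped "
            "from geometric means",
            stacklevel=2,
        )

    work = pd.DataFrame(
        {
            "probe_id": nc["probe_id"].to_numpy(),
            "gene_symbol": nc["gene_symbol"].to_numpy(),
            "log_gps": np.where(survives, np.log(gps, where=gps > 0,
                                                 out=np.zeros_like(gps)), 0.0),
            "used": survives,
        }
    )
    for r in RULES:
        work[f"excl_{r}"] = masks[r].to_numpy()

    g = work.groupby("probe_id", sort=False)
    out = g.agg(
        gene_symbol=("gene_symbol", "first"),
        log_sum=("log_gps", "sum"),
        n_used=("used", "sum"),
        **{f"excl_{r}": (f"excl_{r}", "sum") for r in RULES},
    ).reset_index()
    enough = out["n_used"] >= params.min_surviving_replicates
    with np.errstate(invalid="ignore", divide="ignore"):
        out["value"] = np.where(
            enough, np.exp(out["log_sum"] / out["n_used"].to_numpy(dtype=float)),
            np.nan,
        )
    out.loc[~enough, "n_used"] = 0
    out["n_used"] = out["n_used"].astype(int)
    cols = ["probe_id", "gene_symbol", "value", "n_used"] + [f"excl_{r}" for r in RULES]
    return out[cols]


def write_aggregation_report(aggregated: pd.DataFrame, path) -> None:
    aggregated.to_csv(path, sep="\t", index=False, na_rep="NA")
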