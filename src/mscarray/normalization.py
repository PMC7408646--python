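"""Global linear scaling to a series-wide 75th-percentile reference.

Every array is multiplied by a single scaling factor chosen so that the 75th
percentile of its aggregated non-control signals lands on a reference value
shared by the whole series (1500 signal units by default).  After scaling, a
surrogate floor replaces measurements below the reliable detection limit of
the platform (15 normalized units by default, chosen from the intensity
distribution of the negative-control features).

The percentile is computed over non-missing aggregated values only, with
linear interpolation between order statistics.  The floor is applied strictly
after scaling, never before.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateArrayError


@dataclass(frozen=True)
class NormalizationParams:
    """reference_percentile_value : target signal level for the percentile.
    percentile : which quantile of each array is pinned to the reference.
    surrogate_floor : substitute for sub-threshold normalized values."""

    reference_percentile_value: float = 1500.0
    percentile: float = 0.75
    surrogate_floor: float = 15.0

    def __post_init__(self) -> None:
        if self.reference_percentile_value <= 0:
            raise ValueError("reference_percentile_value must be > 0")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.surrogate_floor < 0:
            raise ValueError("surrogate_floor must be >= 0")


@dataclass
class NormalizedArray:
    """One sample's normalized expression vector (indexed by probe id)."""

    sample_id: str
    values: pd.Series
    scaling_factor: float
    floored: bool = False
    floor_value: float | None = None


def scaling_factor(values, params: NormalizationParams | None = None) -> float:
    """Array-specific scaling factor: reference / p75(non-missing values)."""
    params = params or NormalizationParams()
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise DegenerateArrayError("no non-missing aggregated values")
    p = float(np.quantile(arr, params.percentile))  # linear interpolation
    if p <= 0:
        raise DegenerateArrayError(
            f"percentile of aggregated signals is {p}; cannot scale"
        )
    return params.reference_percentile_value / p


def normalize_array(aggregated: pd.DataFrame,
                    params: NormalizationParams | None = None,
                    sample_id: str = "") -> NormalizedArray:
    """Scale an aggregated sample so its p75 equals the series reference.

    ``aggregated`` is the output of
    :func:`mscarray.probe_aggregation.aggregate_array` (columns ``probe_id``
    and ``value``; missing values stay missing).
    """
    params = params or NormalizationParams()
    values = pd.Series(
        aggregated["value"].to_numpy(dtype=float),
        index=pd.Index(aggregated["probe_id"], name="probe_id"),
    )
    factor = scaling_factor(values, params)
    return NormalizedArray(
        sample_id=sample_id, values=values * factor, scaling_factor=factor
    )


def apply_floor(normalized: NormalizedArray,
                params: NormalizationParams | None = None) -> NormalizedArray:
    """Substitute the surrogate floor for sub-threshold values (idempotent);
    missing entries stay missing."""
    params = params or NormalizationParams()
    floored = normalized.values.where(
        normalized.values >= params.surrogate_floor, other=params.surrogate_floor
    )
    floored[normalized.values.isna()] = np.nan
    return NormalizedArray(
        sample_id=normalized.sample_id,
        values=floored,
        scaling_factor=normalized.scaling_factor,
        floored=True,
        floor_value=params.surrogate_floor,
    )


def floor_from_negative_controls(features: pd.DataFrame, factor: float,
                                 quantile: float = 0.95) -> float:
    """Non-default recalibration of the surrogate floor: a high quantile of
    the scaled negative-control signal distribution.  The published fixed
    floor remains the default."""
    from .array_io import NEGATIVE_CONTROL

    neg = features.loc[features["control_type"] == NEGATIVE_CONTROL, "gps"]
    if neg.empty:
        raise DegenerateArrayError("no negative-control features present")
    return float(np.quantile(neg.to_numpy(dtype=float) * factor, quantile))
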