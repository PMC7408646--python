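"""Closed-form culture and assay metrics.

Population doubling time assumes exponential growth between two passages:
``PDT = hours * ln 2 / ln(n2 / n1)``.  Cultures that did not gain cells have
no defined doubling time and raise :class:`~mscarray.errors.NoNetGrowthError`
(some donor cultures simply stop proliferating).

GAG/DNA is the chondrogenesis readout: secreted glycosaminoglycan mass per
DNA mass, each optionally passed through a linear calibration mapping raw
assay signal to mass.  Mineralization of a cell layer is called when both
calcium and phosphate ion concentrations strictly exceed 1 mM.  Marker
summaries aggregate percent-positive flow-cytometry values per antigen and
condition as arithmetic mean with sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, NoNetGrowthError


@dataclass(frozen=True)
class LinearCalibration:
    """signal -> quantity mapping: quantity = slope * signal + intercept."""

    slope: float = 1.0
    intercept: float = 0.0

    def __call__(self, signal: float) -> float:
        return self.slope * signal + self.intercept

    @classmethod
    def from_two_points(cls, signal_lo, mass_lo, signal_hi, mass_hi):
        slope = (mass_hi - mass_lo) / (signal_hi - signal_lo)
        return cls(slope=slope, intercept=mass_lo - slope * signal_lo)


IDENTITY = LinearCalibration()


def population_doubling_time(n1: float, n2: float, hours: float) -> float:
    """Hours per population doubling between two passages."""
    if n1 <= 0 or n2 <= 0 or hours <= 0:
        raise ContractError("cell counts and elapsed time must be positive")
    if n2 <= n1:
        raise NoNetGrowthError(
            f"no net growth: {n1:g} -> {n2:g} cells over {hours:g} h"
        )
    return hours * math.log(2.0) / math.log(n2 / n1)


def gag_dna_ratio(gag_signal: float, dna_signal: float,
                  gag_calibration: LinearCalibration = IDENTITY,
                  dna_calibration: LinearCalibration = IDENTITY) -> float:
    """Glycosaminoglycan mass per DNA mass after linear calibration."""
    if gag_signal < 0 or dna_signal < 0:
        raise ContractError("assay signals must be non-negative")
    gag = gag_calibration(gag_signal)
    dna = dna_calibration(dna_signal)
    if dna <= 0:
        raise ZeroDivisionError("DNA quantity is zero after calibration")
    return gag / dna


def classify_mineralization(calcium_mm: float, phosphate_mm: float,
                            threshold: float = 1.0) -> bool:
    """Notable mineral accumulation: both ion concentrations strictly
    above the threshold (1 mM)."""
    if calcium_mm < 0 or phosphate_mm < 0:
        raise ContractError("ion concentrations must be non-negative")
    return calcium_mm > threshold and phosphate_mm > threshold


def marker_summary(markers: pd.DataFrame) -> pd.DataFrame:
    """Summarize surface-marker panels across donors.

    Input columns: ``donor, condition, antigen, percent_positive`` with
    percentages in [0, 100].  Returns mean and sample SD per
    antigen x condition; the SD of a single-donor group is missing.
    """
    required = {"donor", "condition", "antigen", "percent_positive"}
    missing = required - set(markers.columns)
    if missing:
        raise ContractError(f"marker table lacks columns {sorted(missing)}")
    pct = markers["percent_positive"].astype(float)
    if ((pct < 0) | (pct > 100)).any():
        raise ContractError("percent_positive values must lie in [0, 100]")
    g = markers.groupby(["antigen", "condition"])["percent_positive"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].astype(float)
    return out


def growth_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized PDT over a table with ``donor, condition, n1, n2, hours``;
    non-growing cultures get a missing PDT and ``grew = False``."""
    out = records.copy()
    grew = out["n2"] > out["n1"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pdt = out["hours"] * math.log(2.0) / np.log(out["n2"] / out["n1"])
    out["pdt_hours"] = np.where(grew, pdt, np.nan)
    out["grew"] = grew
    return out
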