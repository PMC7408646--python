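"""Paired fold-change screen for heparin-regulated genes.

Fold changes are formed per donor as heparin sample over no-heparin sample on
the normalized, floored expression values.  A gene is called up-regulated
when every one of its probes satisfies:

  1. at least ``min_strong_pairs`` cell pairs show a fold change at or above
     the threshold (``>= 2`` by default, inclusive);
  2. any remaining pair changes in the same direction (ratio above 1), and in
     that case the geometric mean of all pairs' ratios must exceed the
     threshold strictly (more than twofold);
  3. the normalized signal of the heparin sample clears an intensity floor
     (``> 100`` normalized units) in every pair, guarding against calls made
     near the detection limit.

Down-regulation is the mirror image (ratios at or below 1/threshold, strict
geometric mean below 1/threshold, intensity floor applied to the no-heparin
samples).  Genes with a missing probe value in any pair are rejected as
incomplete rather than judged on a subset.

``brute_force_select`` re-evaluates the criteria gene by gene in plain loops
and exists as an independent oracle for tests; production code uses
:func:`select_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import ContractError
from .normalization import NormalizedArray


@dataclass(frozen=True)
class SelectionCriteria:
    """fc_threshold : twofold by default; strong pairs compared inclusively,
    the geometric mean strictly.
    intensity_floor_for_call : minimum normalized signal in the samples on
    the high side of the comparison.
    min_strong_pairs : pairs that must individually clear the threshold."""

    fc_threshold: float = 2.0
    intensity_floor_for_call: float = 100.0
    min_strong_pairs: int = 2

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.min_strong_pairs < 1:
            raise ValueError("min_strong_pairs must be >= 1")


@dataclass
class CellPair:
    """Matched samples of one donor: heparin (numerator) vs none
    (denominator), both normalized and floored."""

    donor: str
    numerator: NormalizedArray
    denominator: NormalizedArray


@dataclass
class SelectionResult:
    up: list
    down: list
    table: pd.DataFrame  # gene, direction, per-pair ratios, geo_mean_fc, reason

    def gene_fold_changes(self, gene: str) -> pd.Series:
        row = self.table.loc[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(gene)
        return row.iloc[0].filter(like="ratio_")


def probe_fold_changes(pair: CellPair) -> pd.Series:
    """Per-probe ratio numerator/denominator on the shared probe universe;
    probes missing in either sample yield NaN."""
    num, den = pair.numerator.values, pair.denominator.values
    shared = num.index.intersection(den.index)
    if len(shared) == 0:
        raise ContractError(
            f"pair {pair.donor}: disjoint probe sets between samples"
        )
    idx = num.index.union(den.index)
    return (num.reindex(idx) / den.reindex(idx)).rename(pair.donor)


def _direction_pass(ratios: np.ndarray, num_int: np.ndarray, den_int: np.ndarray,
                    crit: SelectionCriteria, up: bool) -> tuple[bool, str]:
    """Evaluate one probe in one direction; returns (passed, failure reason)."""
    thr = crit.fc_threshold if up else 1.0 / crit.fc_threshold
    strong = ratios >= thr if up else ratios <= thr
    if strong.sum() < crit.min_strong_pairs:
        return False, "too_few_strong_pairs"
    weak = ~strong
    if weak.any():
        same_dir = (ratios[weak] > 1.0) if up else (ratios[weak] < 1.0)
        if not same_dir.all():
            return False, "opposite_direction_pair"
        gm = float(gmean(ratios))
        if up and not gm > crit.fc_threshold:
            return False, "geometric_mean_below_threshold"
        if not up and not gm < 1.0 / crit.fc_threshold:
            return False, "geometric_mean_above_threshold"
    intens = num_int if up else den_int
    if not (intens > crit.intensity_floor_for_call).all():
        return False, "intensity_below_floor"
    return True, ""


def select_genes(pairs: Sequence[CellPair],
                 criteria: SelectionCriteria | None = None,
                 probe_to_gene: Mapping[str, str] | pd.Series = None
                 ) -> SelectionResult:
    """Apply the four selection criteria and return up/down gene lists.

    ``probe_to_gene`` maps every probe id to its gene symbol; genes with
    several probes are called only when every probe passes.  The reported
    per-gene fold changes are those of the probe with the highest mean
    normalized signal across all samples of all pairs.
    """
    criteria = criteria or SelectionCriteria()
    if len(pairs) < 2:
        raise ContractError("gene selection requires at least two cell pairs")
    if probe_to_gene is None:
        raise ContractError("a probe-to-gene map is required")
    p2g = pd.Series(probe_to_gene)

    ratios = pd.concat([probe_fold_changes(p) for p in pairs], axis=1)
    num_int = pd.concat(
        [p.numerator.values.reindex(ratios.index).rename(p.donor) for p in pairs],
        axis=1,
    )
    den_int = pd.concat(
        [p.denominator.values.reindex(ratios.index).rename(p.donor) for p in pairs],
        axis=1,
    )
    unmapped = ratios.index.difference(p2g.index)
    if len(unmapped) > 0:
        raise ContractError(f"probes without gene mapping: {list(unmapped[:5])}")

    donors = [p.donor for p in pairs]
    mean_intensity = pd.concat([num_int, den_int], axis=1).mean(axis=1)
    genes = p2g.reindex(ratios.index)

    rows = []
    up_genes: list = []
    down_genes: list = []
    for gene, probe_idx in genes.groupby(genes).groups.items():
        probes = list(probe_idx)
        sub_r = ratios.loc[probes]
        # representative probe: highest mean normalized signal over conditions
        rep = mean_intensity.loc[probes].idxmax()
        rep_ratios = ratios.loc[rep]
        record = {
            "gene": gene,
            **{f"ratio_{d}": rep_ratios[d] for d in donors},
        }
        if sub_r.isna().any().any():
            record.update(direction="none",
                          geo_mean_fc=np.nan, reason="incomplete")
            rows.append(record)
            continue
        record["geo_mean_fc"] = float(gmean(rep_ratios.to_numpy()))

        verdicts = {}
        for up in (True, False):
            reason = ""
            ok = True
            for probe in probes:
                ok, reason = _direction_pass(
                    ratios.loc[probe].to_numpy(dtype=float),
                    num_int.loc[probe].to_numpy(dtype=float),
                    den_int.loc[probe].to_numpy(dtype=float),
                    criteria, up,
                )
                if not ok:
                    break
            verdicts["up" if up else "down"] = (ok, reason)

        if verdicts["up"][0]:
            up_genes.append(gene)
            record.update(direction="up", reason="")
        elif verdicts["down"][0]:
            down_genes.append(gene)
            record.update(direction="down", reason="")
        else:
            record.update(
                direction="none",
                reason=(f"up:{verdicts['up'][1]};down:{verdicts['down'][1]}"),
            )
        rows.append(record)

    table = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
    return SelectionResult(up=sorted(up_genes), down=sorted(down_genes),
                           table=table)


def brute_force_select(pairs: Sequence[CellPair],
                       criteria: SelectionCriteria | None = None,
                       probe_to_gene: Mapping[str, str] | pd.Series = None
                       ) -> SelectionResult:
    """Literal re-evaluation of every criterion per gene, written as plain
    loops without shared helpers.  Test oracle only; quadratic and slow."""
    criteria = criteria or SelectionCriteria()
    if len(pairs) < 2:
        raise ContractError("gene selection requires at least two cell pairs")
    p2g = dict(pd.Series(probe_to_gene).items())

    all_probes: list = []
    for p in pairs:
        for probe in p.numerator.values.index.union(p.denominator.values.index):
            if probe not in all_probes:
                all_probes.append(probe)
    for probe in all_probes:
        if probe not in p2g:
            raise ContractError(f"probes without gene mapping: [{probe!r}]")

    gene_probes: dict = {}
    for probe in all_probes:
        gene_probes.setdefault(p2g[probe], []).append(probe)

    up_genes, down_genes, rows = [], [], []
    for gene in gene_probes:
        probes = gene_probes[gene]
        complete = True
        for probe in probes:
            for p in pairs:
                n = p.numerator.values.get(probe, np.nan)
                d = p.denominator.values.get(probe, np.nan)
                if np.isnan(n) or np.isnan(d):
                    complete = False

        def probe_ok(probe, up):
            rs, ni, di = [], [], []
            for p in pairs:
                n = float(p.numerator.values[probe])
                d = float(p.denominator.values[probe])
                rs.append(n / d)
                ni.append(n)
                di.append(d)
            thr = criteria.fc_threshold
            strong = [(r >= thr) if up else (r <= 1.0 / thr) for r in rs]
            if sum(strong) < criteria.min_strong_pairs:
                return False
            if not all(strong):
                for r, s in zip(rs, strong):
                    if not s and not ((r > 1.0) if up else (r < 1.0)):
                        return False
                logmean = sum(np.log(r) for r in rs) / len(rs)
                gm = float(np.exp(logmean))
                if up and gm <= thr:
                    return False
                if not up and gm >= 1.0 / thr:
                    return False
            side = ni if up else di
            for v in side:
                if not v > criteria.intensity_floor_for_call:
                    return False
            return True

        rep, rep_mean = None, -np.inf
        for probe in probes:
            vals = []
            for p in pairs:
                vals.append(float(p.numerator.values.get(probe, np.nan)))
                vals.append(float(p.denominator.values.get(probe, np.nan)))
            m = np.nanmean(vals)
            if m > rep_mean:
                rep, rep_mean = probe, m
        record = {"gene": gene}
        for p in pairs:
            n = p.numerator.values.get(rep, np.nan)
            d = p.denominator.values.get(rep, np.nan)
            record[f"ratio_{p.donor}"] = n / d

        if not complete:
            record.update(direction="none", geo_mean_fc=np.nan,
                          reason="incomplete")
            rows.append(record)
            continue
        rep_rs = [record[f"ratio_{p.donor}"] for p in pairs]
        record["geo_mean_fc"] = float(np.exp(np.mean(np.log(rep_rs))))
        if all(probe_ok(pr, True) for pr in probes):
            up_genes.append(gene)
            record.update(direction="up", reason="")
        elif all(probe_ok(pr, False) for pr in probes):
            down_genes.append(gene)
            record.update(direction="down", reason="")
        else:
            record.update(direction="none", reason="rejected")
        rows.append(record)

    table = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
    return SelectionResult(up=sorted(up_genes), down=sorted(down_genes),
                           table=table)


def write_selection_table(result: SelectionResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def pairs_from_matrix(matrix: pd.DataFrame,
                      pair_columns: Mapping[str, tuple[str, str]]
                      ) -> list[CellPair]:
    """Build cell pairs from an expression matrix (e.g. a deposited series
    matrix whose values are already normalized and floored).

    ``pair_columns`` maps donor -> (heparin column, no-heparin column).
    """
    pairs = []
    for donor, (hep_col, none_col) in pair_columns.items():
        pairs.append(
            CellPair(
                donor=donor,
                numerator=NormalizedArray(
                    sample_id=str(hep_col), values=matrix[hep_col].astype(float),
                    scaling_factor=1.0, floored=True,
                ),
                denominator=NormalizedArray(
                    sample_id=str(none_col), values=matrix[none_col].astype(float),
                    scaling_factor=1.0, floored=True,
                ),
            )
        )
    return pairs
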