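"""End-to-end orchestration: aggregate -> normalize -> floor -> select
-> (optionally) qPCR concordance, with a provenance-complete run report.

The stage order is fixed: replicate aggregation happens on raw signals,
global scaling on aggregated values, the surrogate floor strictly after
scaling, and the fold-change screen consumes floored values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import array_io
from .errors import ConfigError
from .normalization import NormalizationParams, NormalizedArray, \
    apply_floor, normalize_array
from .paired_selection import CellPair, SelectionCriteria, SelectionResult, \
    select_genes, write_selection_table
from .probe_aggregation import AggregationParams, RULES, aggregate_array
from .qpcr_concordance import concordance_table, qpcr_calls, quantify_table
from .synthetic_data import StudyConfig, generate_assays, generate_growth, \
    generate_qpcr, generate_study
from .culture_metrics import growth_table, classify_mineralization


@dataclass
class PipelineConfig:
    """Everything a run needs; every tunable lands in the run report."""

    study: StudyConfig = field(default_factory=StudyConfig)
    aggregation: AggregationParams = field(default_factory=AggregationParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    heparin_condition: str | None = None  # default: last configured condition
    out_dir: str | Path | None = None
    log_level: str = "INFO"


def process_sample(features: pd.DataFrame, sample_id: str,
                   agg_params: AggregationParams,
                   norm_params: NormalizationParams):
    """Raw feature table -> floored NormalizedArray (+ aggregation table)."""
    agg = aggregate_array(features, agg_params)
    norm = apply_floor(normalize_array(agg, norm_params, sample_id=sample_id),
                       norm_params)
    return norm, agg


def build_pairs(arrays: Mapping[tuple, NormalizedArray],
                baseline_condition: str, heparin_condition: str) -> list:
    pairs = []
    donors = sorted({d for d, _ in arrays})
    for donor in donors:
        num = arrays.get((donor, heparin_condition))
        den = arrays.get((donor, baseline_condition))
        if num is None or den is None:
            raise ConfigError(
                f"donor {donor}: missing sample for pairing "
                f"({heparin_condition} vs {baseline_condition})"
            )
        pairs.append(CellPair(donor=donor, numerator=num, denominator=den))
    return pairs


def expression_matrix(arrays: Mapping[tuple, NormalizedArray],
                      sample_ids: Mapping[tuple, str] | None = None
                      ) -> pd.DataFrame:
    cols = {a.sample_id: a.values for a in arrays.values()}
    return pd.DataFrame(cols)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a study from ``config.study`` and run every stage.

    Returns the run report (plain dict, YAML-serializable); when
    ``config.out_dir`` is set, all stage outputs and the report are written
    there.  Identical config implies an identical report.
    """
    report: dict = {
        "parameters": {
            "study": _study_dict(config.study),
            "aggregation": asdict(config.aggregation),
            "normalization": asdict(config.normalization),
            "selection": asdict(config.selection),
        },
        "seed": config.study.seed,
        "stages": {},
    }
    study = config.study
    heparin = config.heparin_condition or study.conditions[-1]
    baseline = study.conditions[0]
    if heparin not in study.conditions or heparin == baseline:
        raise ConfigError(f"heparin_condition {heparin!r} not usable")

    tables, truth = generate_study(study)
    report["stages"]["simulate"] = {
        "n_samples": len(tables),
        "features_per_sample": int(len(next(iter(tables.values())))),
        "regulated_genes": int(len(truth.regulated)),
    }

    arrays, agg_tables = {}, {}
    agg_stage = {}
    for (donor, cond), feats in tables.items():
        sid = study.sample_id(donor, cond)
        norm, agg = process_sample(feats, sid, config.aggregation,
                                   config.normalization)
        arrays[(donor, cond)] = norm
        agg_tables[(donor, cond)] = agg
        agg_stage[sid] = {
            "features_read": int(len(feats)),
            "probes": int(len(agg)),
            "exclusions": {r: int(agg[f"excl_{r}"].sum()) for r in RULES},
            "scaling_factor": float(norm.scaling_factor),
            "n_floored": int(
                (normalize_array(agg, config.normalization, sid).values
                 < config.normalization.surrogate_floor).sum()
            ),
        }
    report["stages"]["arrays"] = agg_stage

    pairs = build_pairs(arrays, baseline, heparin)
    selection = select_genes(pairs, config.selection,
                             truth.probe_to_gene)
    report["stages"]["selection"] = {
        "n_pairs": len(pairs),
        "up": list(selection.up),
        "down": list(selection.down),
        "n_up": len(selection.up),
        "n_down": len(selection.down),
    }

    qpcr_genes = sorted(set(selection.up) | set(selection.down)
                        | set(truth.regulated["gene"]))
    concordance_fraction = None
    if qpcr_genes:
        ct = generate_qpcr(truth, study, genes=qpcr_genes)
        quantified = quantify_table(ct)
        calls = qpcr_calls(quantified, heparin, baseline)
        conc, concordance_fraction = concordance_table(selection, calls)
        assessable = (
            ~conc["array_direction"].isin(["not_available", "not_assessable"])
            & ~conc["qpcr_direction"].isin(["not_available", "not_assessable"])
        )
        report["stages"]["qpcr"] = {
            "genes_tested": qpcr_genes,
            "concordance_fraction": float(concordance_fraction),
            "n_cells": int(assessable.sum()),
        }
    growth = growth_table(generate_growth(study))
    assays = generate_assays(study)
    assays["mineralized"] = [
        classify_mineralization(c, p)
        for c, p in zip(assays["calcium_mm"], assays["phosphate_mm"])
    ]
    assays["gag_dna_ratio"] = assays["gag_ug"] / assays["dna_ug"]
    report["stages"]["metrics"] = {
        "mean_pdt_hours": float(growth["pdt_hours"].mean()),
        "n_mineralized": int(assays["mineralized"].sum()),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (donor, cond), feats in tables.items():
            array_io.write_feature_table(
                feats, out / f"features_{study.sample_id(donor, cond)}.tsv"
            )
        truth.to_tsv(out / "ground_truth.tsv")
        matrix = expression_matrix(arrays)
        array_io.write_expression_matrix(matrix, out / "expression_matrix.tsv")
        pd.DataFrame(
            {
                "sample": [a.sample_id for a in arrays.values()],
                "scaling_factor": [a.scaling_factor for a in arrays.values()],
            }
        ).to_csv(out / "scaling_factors.tsv", sep="\t", index=False)
        write_selection_table(selection, out / "selection.tsv")
        growth.to_csv(out / "growth_metrics.tsv", sep="\t", index=False)
        assays.to_csv(out / "assay_metrics.tsv", sep="\t", index=False)
        if qpcr_genes:
            conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        write_report(report, out / "report.yaml")
    return report


def write_report(report: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)


def _study_dict(study: StudyConfig) -> dict:
    d = asdict(study)
    d["conditions"] = list(study.conditions)
    d["regulated_genes"] = [
        {k: v for k, v in asdict(rg).items() if v is not None}
        for rg in study.regulated_genes
    ]
    return d


def read_selection_table(path) -> SelectionResult:
    """Rebuild a SelectionResult from its serialized table."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    up = sorted(table.loc[table["direction"] == "up", "gene"])
    down = sorted(table.loc[table["direction"] == "down", "gene"])
    return SelectionResult(up=up, down=down, table=table)
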