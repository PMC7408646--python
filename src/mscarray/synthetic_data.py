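"""Synthetic heparin-exposure studies with known ground truth.

The generator emulates the structure of a paired one-color microarray study
of bone-marrow MSCs: each donor contributes one sample per anticoagulation
condition, each array prints every probe in replicate (quintuplicates by
default), and a chosen subset of genes responds multiplicatively to heparin
while everything else is null.  Matched qPCR CT tables, exponential-growth
count pairs and differentiation-assay readouts are derived from the same
ground truth, so every downstream stage of the pipeline can be checked
against known answers without any external data.

Generative model
----------------
* Per-gene baseline expression is log-normal (``baseline_log_mean``,
  ``baseline_log_sd``), shared across donors; each donor applies a gene-wise
  multiplicative jitter (log-SD ``donor_jitter_log_sd``) that is identical in
  both of that donor's conditions and therefore cancels in fold changes.
* A ``background_fraction`` of genes sits near the detection limit,
  emulating the large share of transcripts a whole-genome array measures at
  background; these exercise the surrogate floor.
* Replicate noise is multiplicative log-normal with coefficient of variation
  ``replicate_noise_cv`` (log-scale sigma ``sqrt(ln(1 + cv^2))``, median
  unbiased so geometric means recover the true value).
* Contamination: single replicates receive 50-200x multiplicative spikes at
  ``outlier_rate`` (deliberately left unflagged so the IQR rule has real
  work); manual and software outlier flags are each drawn at
  ``manual_flag_rate`` and the affected values are distorted, so failing to
  honour the flags would corrupt results; pixel CVs above the 0.5 cap appear
  at ``high_pixel_cv_rate``, again with distorted values.
* Negative-control features are drawn far below the signal range so they
  land under the surrogate floor after normalization.

One RNG stream per donor x condition is derived from the master seed, so
adding donors or conditions never perturbs existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
import yaml

from .array_io import NEGATIVE_CONTROL, NON_CONTROL
from .errors import ConfigError

#: probability that the extraction software flags an injected spike itself
_SPIKE_FLAGGED_P = 0.9

_BASELINE_STREAM = 1
_SAMPLE_STREAM = 2
_DONOR_STREAM = 3
_QPCR_STREAM = 4
_GROWTH_STREAM = 5
_ASSAY_STREAM = 6


@dataclass(frozen=True)
class RegulatedGene:
    """A gene that responds to heparin.

    ``fold`` is the magnitude of the effect (>= 1 up, or any positive value;
    the applied multiplier is ``fold`` for direction ``up`` and ``1/fold``
    for ``down``).  It may be a single number applied in every non-baseline
    condition or a mapping condition -> fold.  ``baseline`` optionally pins
    the gene's baseline expression (raw signal units) instead of drawing it.
    """

    gene: str
    direction: str  # "up" or "down"
    fold: float | Mapping[str, float] = 2.0
    baseline: float | None = None

    def fold_for(self, condition: str) -> float:
        if isinstance(self.fold, Mapping):
            f = float(self.fold.get(condition, 1.0))
        else:
            f = float(self.fold)
        return f

    def multiplier(self, condition: str) -> float:
        f = self.fold_for(condition)
        return f if self.direction == "up" else 1.0 / f


@dataclass
class StudyConfig:
    """Parameters of a synthetic study; defaults mirror the paired-design
    transcriptome arm (three donors, no-heparin vs high-heparin) on a
    1000-gene array with quintuplicate on-chip replicates."""

    n_donors: int = 3
    conditions: tuple = ("none", "high")  # first entry is the baseline
    n_genes: int = 1000
    probes_per_gene: int = 1
    replicates_per_probe: int = 5
    n_negative_controls: int = 100
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    donor_jitter_log_sd: float = 0.1
    background_fraction: float = 0.1
    replicate_noise_cv: float = 0.05
    outlier_rate: float = 0.01
    manual_flag_rate: float = 0.005
    high_pixel_cv_rate: float = 0.01
    regulated_genes: tuple = ()
    qpcr_ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_donors": self.n_donors, "n_genes": self.n_genes,
            "probes_per_gene": self.probes_per_gene,
            "n_negative_controls": self.n_negative_controls,
        }
        for name, v in counts.items():
            if v < 0 or (v == 0 and name in ("n_donors", "n_genes",
                                             "probes_per_gene")):
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.replicates_per_probe < 1:
            raise ConfigError("replicates_per_probe must be >= 1")
        if len(self.conditions) < 2:
            raise ConfigError("need a baseline plus at least one condition")
        for name in ("background_fraction", "outlier_rate",
                     "manual_flag_rate", "high_pixel_cv_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.replicate_noise_cv < 0 or self.qpcr_ct_noise_sd < 0 \
                or self.donor_jitter_log_sd < 0:
            raise ConfigError("noise magnitudes must be non-negative")
        self.regulated_genes = tuple(
            RegulatedGene(**g) if isinstance(g, Mapping) else g
            for g in self.regulated_genes
        )
        universe = set(self.gene_ids())
        for rg in self.regulated_genes:
            if rg.direction not in ("up", "down"):
                raise ConfigError(f"direction must be up/down: {rg}")
            folds = [rg.fold_for(c) for c in self.conditions[1:]]
            if any(f <= 0 for f in folds):
                raise ConfigError(f"effect multipliers must be > 0: {rg}")
            if rg.gene not in universe:
                raise ConfigError(f"regulated gene outside universe: {rg.gene}")
            if rg.baseline is not None and rg.baseline <= 0:
                raise ConfigError(f"pinned baseline must be > 0: {rg}")

    # -- identifier helpers -------------------------------------------------
    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def donor_ids(self) -> list:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    def probe_ids(self) -> list:
        return [
            f"{g}_P{p + 1}"
            for g in self.gene_ids()
            for p in range(self.probes_per_gene)
        ]

    def probe_to_gene(self) -> pd.Series:
        return pd.Series(
            {p: p.rsplit("_P", 1)[0] for p in self.probe_ids()},
            name="gene_symbol",
        )

    @staticmethod
    def sample_id(donor: str, condition: str) -> str:
        return f"{donor}_{condition}"


@dataclass
class GroundTruth:
    """True state of a synthetic study: regulated-gene table (gene,
    direction, one ``true_fc_<condition>`` per non-baseline condition) and
    the noise-free probe x sample expression matrix (raw signal units)."""

    regulated: pd.DataFrame
    expression: pd.DataFrame
    probe_to_gene: pd.Series
    baseline_condition: str

    def true_fold_change(self, gene: str, condition: str) -> float:
        row = self.regulated.loc[self.regulated["gene"] == gene]
        if row.empty:
            return 1.0
        return float(row.iloc[0][f"true_fc_{condition}"])

    def gene_expression(self, gene: str, sample: str) -> float:
        probes = self.probe_to_gene[self.probe_to_gene == gene].index
        if len(probes) == 0:
            raise KeyError(f"gene not in study universe: {gene}")
        return float(self.expression.loc[probes[0], sample])

    def to_tsv(self, path) -> None:
        self.regulated.to_csv(path, sep="\t", index=False)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _true_expression(config: StudyConfig) -> pd.DataFrame:
    """Noise-free probe x sample matrix implied by the config."""
    rng = _stream(config.seed, _BASELINE_STREAM)
    genes = config.gene_ids()
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                             size=config.n_genes))
    n_bg = int(round(config.background_fraction * config.n_genes))
    if n_bg:
        bg_idx = rng.choice(config.n_genes, size=n_bg, replace=False)
        bg_mean = math.exp(config.baseline_log_mean) / 300.0
        base[bg_idx] = np.exp(rng.normal(math.log(bg_mean), 0.5, size=n_bg))
    baseline = pd.Series(base, index=genes)
    for rg in config.regulated_genes:
        if rg.baseline is not None:
            baseline[rg.gene] = rg.baseline

    multipliers = pd.DataFrame(1.0, index=genes, columns=list(config.conditions))
    for rg in config.regulated_genes:
        for cond in config.conditions[1:]:
            multipliers.loc[rg.gene, cond] = rg.multiplier(cond)

    cols = {}
    for d_idx, donor in enumerate(config.donor_ids()):
        jitter_rng = _stream(config.seed, _DONOR_STREAM, d_idx)
        jitter = np.exp(
            jitter_rng.normal(0.0, config.donor_jitter_log_sd, config.n_genes)
        )
        for cond in config.conditions:
            gene_expr = baseline.to_numpy() * jitter * multipliers[cond].to_numpy()
            cols[config.sample_id(donor, cond)] = np.repeat(
                gene_expr, config.probes_per_gene
            )
    return pd.DataFrame(cols, index=pd.Index(config.probe_ids(), name="probe_id"))


def generate_study(config: StudyConfig):
    """Generate one feature table per donor x condition plus ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps
    ``(donor, condition) -> feature DataFrame`` in the dialect of
    :mod:`mscarray.array_io`.
    """
    expr = _true_expression(config)
    p2g = config.probe_to_gene()
    sigma = math.sqrt(math.log(1.0 + config.replicate_noise_cv ** 2))
    neg_mean = math.exp(config.baseline_log_mean) / 500.0

    reg_rows = []
    for rg in config.regulated_genes:
        row = {"gene": rg.gene, "direction": rg.direction}
        for cond in config.conditions[1:]:
            row[f"true_fc_{cond}"] = rg.multiplier(cond)
        reg_rows.append(row)
    truth = GroundTruth(
        regulated=pd.DataFrame(
            reg_rows, columns=["gene", "direction"]
            + [f"true_fc_{c}" for c in config.conditions[1:]],
        ),
        expression=expr,
        probe_to_gene=p2g,
        baseline_condition=config.conditions[0],
    )

    rep = config.replicates_per_probe
    tables = {}
    for d_idx, donor in enumerate(config.donor_ids()):
        for c_idx, cond in enumerate(config.conditions):
            rng = _stream(config.seed, _SAMPLE_STREAM, d_idx, c_idx)
            sample = config.sample_id(donor, cond)
            true_vals = np.repeat(expr[sample].to_numpy(), rep)
            n = true_vals.size

            noise = np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else 1.0
            gps = true_vals * noise

            spike = rng.random(n) < config.outlier_rate
            gps = np.where(spike, gps * rng.uniform(50.0, 200.0, n), gps)
            # the extraction software catches most gross artifacts; the
            # unflagged residue is what the IQR rule exists for
            spike_flagged = spike & (rng.random(n) < _SPIKE_FLAGGED_P)

            manual = rng.random(n) < config.manual_flag_rate
            soft = rng.random(n) < config.manual_flag_rate
            distort = np.exp(rng.uniform(math.log(0.1), math.log(10.0), n))
            gps = np.where(manual | soft, gps * distort, gps)
            soft = soft | spike_flagged

            high_cv = rng.random(n) < config.high_pixel_cv_rate
            pixel_cv = np.where(
                high_cv,
                rng.uniform(0.55, 1.5, n),
                rng.uniform(0.02, 0.2, n),
            )
            cv_distort = np.exp(rng.uniform(math.log(0.2), math.log(5.0), n))
            gps = np.where(high_cv, gps * cv_distort, gps)

            probe_col = np.repeat(expr.index.to_numpy(), rep)
            gene_col = np.repeat(p2g.reindex(expr.index).to_numpy(), rep)
            frame = pd.DataFrame(
                {
                    "probe_id": probe_col,
                    "gene_symbol": gene_col,
                    "control_type": NON_CONTROL,
                    "gps": gps,
                    "manual_flag": manual,
                    "outlier_flag": soft,
                    "pixel_cv": pixel_cv,
                }
            )

            if config.n_negative_controls:
                n_neg = config.n_negative_controls * rep
                neg_vals = np.exp(
                    rng.normal(math.log(neg_mean), 0.5, n_neg)
                )
                neg = pd.DataFrame(
                    {
                        "probe_id": np.repeat(
                            [f"NEG{i:04d}" for i in
                             range(config.n_negative_controls)], rep),
                        "gene_symbol": "",
                        "control_type": NEGATIVE_CONTROL,
                        "gps": neg_vals,
                        "manual_flag": False,
                        "outlier_flag": False,
                        "pixel_cv": rng.uniform(0.02, 0.2, n_neg),
                    }
                )
                frame = pd.concat([frame, neg], ignore_index=True)
            tables[(donor, cond)] = frame
    return tables, truth


_QPCR_REFERENCE_EXPR = 1000.0  # raw-signal units mapping to delta-CT 0
_HOUSEKEEPING_CT = 20.0


def generate_qpcr(truth: GroundTruth, config: StudyConfig,
                  genes: Sequence[str] | None = None,
                  housekeeping: str = "RPS29") -> pd.DataFrame:
    """Duplicate CT values per sample x gene consistent with the true
    expression (2**-dCT reproduces relative expression up to CT noise).

    Raises ``KeyError`` for genes outside the study universe.
    """
    if genes is None:
        genes = list(truth.regulated["gene"])
    rng = _stream(config.seed, _QPCR_STREAM)
    sd = config.qpcr_ct_noise_sd
    rows = []
    for donor in config.donor_ids():
        for cond in config.conditions:
            sample = config.sample_id(donor, cond)
            hk_cts = _HOUSEKEEPING_CT + rng.normal(0.0, sd, 2)
            rows.append(
                {
                    "sample": sample, "donor": donor, "condition": cond,
                    "gene": housekeeping,
                    "ct_rep1": hk_cts[0], "ct_rep2": hk_cts[1],
                }
            )
            for gene in genes:
                e = truth.gene_expression(gene, sample)
                ct_true = _HOUSEKEEPING_CT - math.log2(e / _QPCR_REFERENCE_EXPR)
                cts = ct_true + rng.normal(0.0, sd, 2)
                rows.append(
                    {
                        "sample": sample, "donor": donor, "condition": cond,
                        "gene": gene,
                        "ct_rep1": cts[0], "ct_rep2": cts[1],
                    }
                )
    return pd.DataFrame(rows)


def generate_growth(config: StudyConfig) -> pd.DataFrame:
    """Exponential-growth count pairs with known doubling times: columns
    ``donor, condition, n1, n2, hours, true_pdt_hours``."""
    rng = _stream(config.seed, _GROWTH_STREAM)
    rows = []
    for donor in config.donor_ids():
        for cond in config.conditions:
            pdt = rng.uniform(40.0, 80.0)
            hours = rng.uniform(72.0, 144.0)
            n1 = 2.0e5
            rows.append(
                {
                    "donor": donor, "condition": cond,
                    "n1": n1, "n2": n1 * 2.0 ** (hours / pdt),
                    "hours": hours, "true_pdt_hours": pdt,
                }
            )
    return pd.DataFrame(rows)


def generate_assays(config: StudyConfig) -> pd.DataFrame:
    """Differentiation-assay readouts with known truth: GAG and DNA masses
    (ug) with their ratio, calcium/phosphate concentrations (mM) with the
    mineralization class (both ions > 1 mM)."""
    rng = _stream(config.seed, _ASSAY_STREAM)
    rows = []
    for donor in config.donor_ids():
        for cond in config.conditions:
            gag = rng.uniform(2.0, 20.0)
            dna = rng.uniform(0.5, 5.0)
            ca = rng.uniform(0.0, 3.0)
            ph = rng.uniform(0.0, 3.0)
            rows.append(
                {
                    "donor": donor, "condition": cond,
                    "gag_ug": gag, "dna_ug": dna,
                    "true_gag_dna_ratio": gag / dna,
                    "calcium_mm": ca, "phosphate_mm": ph,
                    "true_mineralized": bool(ca > 1.0 and ph > 1.0),
                }
            )
    return pd.DataFrame(rows)


# -- config (de)serialization ----------------------------------------------

def config_to_yaml(config: StudyConfig, path) -> None:
    data = asdict(config)
    data["conditions"] = list(config.conditions)
    data["regulated_genes"] = [
        {k: (dict(v) if isinstance(v, Mapping) else v)
         for k, v in asdict(rg).items() if v is not None}
        for rg in config.regulated_genes
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> StudyConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigError(f"empty config file: {path!s}")
    data["conditions"] = tuple(data.get("conditions", ("none", "high")))
    data["regulated_genes"] = tuple(
        RegulatedGene(**g) for g in data.get("regulated_genes", [])
    )
    try:
        return StudyConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
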