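import numpy as np
import pandas as pd
import pytest

from mscarray.errors import ConfigError
from mscarray.normalization import NormalizationParams, apply_floor, \
    normalize_array
from mscarray.probe_aggregation import AggregationParams, aggregate_array
from mscarray.qpcr_concordance import qpcr_calls, quantify_table
from mscarray.synthetic_data import (
    RegulatedGene,
    StudyConfig,
    config_from_yaml,
    config_to_yaml,
    generate_assays,
    generate_growth,
    generate_qpcr,
    generate_study,
)


def spiked_config(**kw):
    defaults = dict(
        n_genes=150, n_negative_controls=20, seed=21,
        regulated_genes=(RegulatedGene("G00003", "up", 4.0, baseline=20000.0),),
    )
    defaults.update(kw)
    return StudyConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_donors=0),
            dict(replicates_per_probe=0),
            dict(outlier_rate=1.5),
            dict(manual_flag_rate=-0.1),
            dict(conditions=("none",)),
            dict(regulated_genes=(RegulatedGene("G99999", "up", 2.0),)),
            dict(regulated_genes=(RegulatedGene("G00001", "sideways", 2.0),)),
            dict(regulated_genes=(RegulatedGene("G00001", "up", -1.0),)),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            StudyConfig(n_genes=100, **kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = spiked_config()
        path = tmp_path / "study.yaml"
        config_to_yaml(cfg, path)
        back = config_from_yaml(path)
        assert back == cfg


class TestGenerateStudy:
    def test_zero_noise_null_replicates_identical_and_fc_one(self):
        cfg = StudyConfig(
            n_genes=40, n_negative_controls=5, seed=1,
            replicate_noise_cv=0.0, outlier_rate=0.0, manual_flag_rate=0.0,
            high_pixel_cv_rate=0.0,
        )
        tables, truth = generate_study(cfg)
        for (donor, cond), table in tables.items():
            nc = table[table["control_type"] == 0]
            assert (nc.groupby("probe_id")["gps"].nunique() == 1).all()
        fc = truth.expression["D1_high"] / truth.expression["D1_none"]
        np.testing.assert_array_equal(fc.to_numpy(), 1.0)

    def test_fixed_seed_reproduces_byte_identical_tables(self, tmp_path):
        from mscarray.array_io import write_feature_table

        cfg = spiked_config()
        paths = []
        for run in (0, 1):
            tables, _ = generate_study(cfg)
            p = tmp_path / f"run{run}.tsv"
            write_feature_table(tables[("D2", "high")], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_adding_donors_preserves_existing_samples(self):
        small, _ = generate_study(spiked_config(n_donors=2))
        large, _ = generate_study(spiked_config(n_donors=4))
        for key, table in small.items():
            pd.testing.assert_frame_equal(table, large[key])

    def test_regulated_gene_effect_recovered_through_aggregation(self):
        """Aggregated, normalized per-pair fold change of a 4x spiked gene
        lands within 15% of truth at 5% replicate noise."""
        cfg = spiked_config(replicate_noise_cv=0.05)
        tables, truth = generate_study(cfg)
        norm_params = NormalizationParams()
        ratios = []
        for donor in cfg.donor_ids():
            arrays = {}
            for cond in cfg.conditions:
                agg = aggregate_array(tables[(donor, cond)], AggregationParams())
                arrays[cond] = apply_floor(
                    normalize_array(agg, norm_params,
                                    sample_id=cfg.sample_id(donor, cond)),
                    norm_params,
                )
            fc = arrays["high"].values / arrays["none"].values
            ratios.append(fc["G00003_P1"])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.15)

    def test_contamination_rates_within_binomial_bounds(self):
        cfg = StudyConfig(
            n_genes=2000, n_negative_controls=0, seed=8,
            outlier_rate=0.02, manual_flag_rate=0.01, high_pixel_cv_rate=0.015,
        )
        tables, _ = generate_study(cfg)
        table = tables[("D1", "none")]
        n = len(table)

        def check(observed, rate):
            sd = np.sqrt(rate * (1 - rate) / n)
            assert abs(observed / n - rate) < 3 * sd

        check(table["manual_flag"].sum(), cfg.manual_flag_rate)
        check((table["pixel_cv"] > 0.5).sum(), cfg.high_pixel_cv_rate)
        # software flags: independent draws at manual_flag_rate plus the
        # 90%-flagged fraction of injected spikes
        soft_rate = 1 - (1 - cfg.manual_flag_rate) * (1 - 0.9 * cfg.outlier_rate)
        check(table["outlier_flag"].sum(), soft_rate)

    def test_negative_controls_land_below_floor_after_scaling(self):
        cfg = spiked_config()
        tables, _ = generate_study(cfg)
        table = tables[("D1", "none")]
        agg = aggregate_array(table, AggregationParams())
        norm = normalize_array(agg, NormalizationParams())
        neg = table.loc[table["control_type"] == -1, "gps"]
        assert (neg * norm.scaling_factor).median() < 15.0


class TestGenerateQpcr:
    def test_twofold_truth_gives_exact_one_cycle_shift(self):
        cfg = StudyConfig(
            n_genes=30, seed=4, qpcr_ct_noise_sd=0.0,
            replicate_noise_cv=0.0, outlier_rate=0.0, manual_flag_rate=0.0,
            high_pixel_cv_rate=0.0,
            regulated_genes=(RegulatedGene("G00002", "up", 2.0,
                                           baseline=5000.0),),
        )
        _, truth = generate_study(cfg)
        ct = generate_qpcr(truth, cfg, genes=["G00002"])
        q = quantify_table(ct).set_index(["donor", "condition"])
        for donor in cfg.donor_ids():
            diff = q.loc[(donor, "high"), "delta_ct"] \
                - q.loc[(donor, "none"), "delta_ct"]
            assert diff == pytest.approx(-1.0, abs=1e-12)

    def test_unregulated_gene_has_constant_delta_ct(self):
        cfg = StudyConfig(n_genes=30, seed=4, qpcr_ct_noise_sd=0.0,
                          replicate_noise_cv=0.0, donor_jitter_log_sd=0.0)
        _, truth = generate_study(cfg)
        ct = generate_qpcr(truth, cfg, genes=["G00005"])
        q = quantify_table(ct)
        per_donor = q.groupby("donor")["delta_ct"].nunique()
        assert (per_donor == 1).all()

    def test_unknown_gene_rejected(self):
        cfg = StudyConfig(n_genes=10, seed=4)
        _, truth = generate_study(cfg)
        with pytest.raises(KeyError):
            generate_qpcr(truth, cfg, genes=["NOT_A_GENE"])

    def test_monte_carlo_fold_change_recovery(self):
        """At 0.2 cycles of CT noise, mean recovered fold change over 100
        regulated genes is within 10% of the true twofold effect."""
        reg = tuple(
            RegulatedGene(f"G{i:05d}", "up", 2.0, baseline=2000.0)
            for i in range(100)
        )
        cfg = StudyConfig(n_genes=100, seed=13, qpcr_ct_noise_sd=0.2,
                          regulated_genes=reg)
        _, truth = generate_study(cfg)
        ct = generate_qpcr(truth, cfg)
        calls = qpcr_calls(quantify_table(ct), "high", "none")
        assert calls["qpcr_ratio"].mean() == pytest.approx(2.0, rel=0.10)


class TestGrowthAndAssays:
    def test_growth_counts_follow_exponential_closed_form(self):
        growth = generate_growth(StudyConfig(seed=5))
        expected = growth["n1"] * 2.0 ** (growth["hours"]
                                          / growth["true_pdt_hours"])
        np.testing.assert_allclose(growth["n2"], expected, rtol=1e-12)

    def test_assay_truth_fields_consistent(self):
        assays = generate_assays(StudyConfig(seed=6))
        np.testing.assert_allclose(
            assays["true_gag_dna_ratio"], assays["gag_ug"] / assays["dna_ug"]
        )
        expected_class = (assays["calcium_mm"] > 1.0) \
            & (assays["phosphate_mm"] > 1.0)
        assert (assays["true_mineralized"] == expected_class).all()

    def test_deterministic_given_seed(self):
        a = generate_growth(StudyConfig(seed=7))
        b = generate_growth(StudyConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)
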