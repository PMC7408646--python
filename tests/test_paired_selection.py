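import numpy as np
import pandas as pd
import pytest

from mscarray.errors import ContractError
from mscarray.normalization import NormalizedArray
from mscarray.paired_selection import (
    CellPair,
    SelectionCriteria,
    brute_force_select,
    probe_fold_changes,
    select_genes,
)

from conftest import make_pair, pairs_from_ratio_table


def identity_map(pairs):
    probes = pairs[0].numerator.values.index
    return pd.Series(probes, index=probes)


class TestProbeFoldChanges:
    def test_simple_ratio(self):
        pair = make_pair("D1", {"A": 300.0}, {"A": 100.0})
        assert probe_fold_changes(pair)["A"] == pytest.approx(3.0)

    def test_both_at_floor_give_unity(self):
        pair = make_pair("D1", {"A": 15.0}, {"A": 15.0})
        assert probe_fold_changes(pair)["A"] == pytest.approx(1.0)

    def test_missing_probe_marked_missing(self):
        pair = make_pair("D1", {"A": 100.0, "B": np.nan}, {"A": 50.0, "B": 200.0})
        fc = probe_fold_changes(pair)
        assert np.isnan(fc["B"]) and fc["A"] == 2.0

    def test_disjoint_probe_sets_rejected(self):
        pair = make_pair("D1", {"A": 1.0}, {"B": 1.0})
        with pytest.raises(ContractError, match="disjoint"):
            probe_fold_changes(pair)


class TestSelectGenes:
    """Worked criterion examples; every case is also cross-checked against
    the brute-force oracle."""

    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ((2.5, 2.2, 1.5), "up"),      # geomean 2.02 > 2, third same dir
            ((2.5, 2.1, 0.9), "none"),    # third pair opposite direction
            ((2.5, 2.1, 1.2), "none"),    # geomean 1.85 < 2
            ((0.3, 0.4, 0.45), "down"),   # all pairs strong down
            ((2.0, 2.0, 2.0), "up"),      # inclusive at-least-twofold bound
            ((2.0, 2.0, 1.5), "none"),    # geomean 1.817 < 2 (strict)
            ((1.0, 1.0, 1.0), "none"),
            ((3.0, 1.5, 1.5), "none"),    # only one strong pair
            ((0.5, 0.5, 0.9), "none"),    # geomean 0.607 > 0.5
        ],
    )
    def test_criterion_examples(self, ratios, expected):
        pairs = pairs_from_ratio_table({"G": ratios}, den_intensity=1000.0)
        res = select_genes(pairs, SelectionCriteria(), identity_map(pairs))
        direction = res.table.loc[res.table["gene"] == "G", "direction"].iloc[0]
        assert direction == expected
        oracle = brute_force_select(pairs, SelectionCriteria(),
                                    identity_map(pairs))
        assert (oracle.up, oracle.down) == (res.up, res.down)

    def test_intensity_floor_blocks_up_call(self):
        # ratios of 3 but heparin-side signals of only 60 normalized units
        pairs = pairs_from_ratio_table({"G": (3.0, 3.0, 3.0)},
                                       den_intensity=20.0)
        res = select_genes(pairs, SelectionCriteria(), identity_map(pairs))
        assert res.up == []
        reason = res.table["reason"].iloc[0]
        assert "intensity" in reason

    def test_down_call_requires_bright_no_heparin_side(self):
        pairs = pairs_from_ratio_table({"G": (0.3, 0.3, 0.3)},
                                       den_intensity=90.0)
        res = select_genes(pairs, SelectionCriteria(), identity_map(pairs))
        assert res.down == []

    def test_single_pair_rejected(self):
        pairs = pairs_from_ratio_table({"G": (3.0, 3.0, 3.0)})[:1]
        with pytest.raises(ContractError, match="two cell pairs"):
            select_genes(pairs, SelectionCriteria(), identity_map(pairs))

    def test_unmapped_probe_rejected(self):
        pairs = pairs_from_ratio_table({"G": (3.0, 3.0, 3.0)})
        with pytest.raises(ContractError, match="mapping"):
            select_genes(pairs, SelectionCriteria(), pd.Series(dtype=object))

    def test_missing_value_marks_gene_incomplete(self):
        pairs = pairs_from_ratio_table({"G": (3.0, 3.0, 3.0)})
        pairs[1].numerator.values["G"] = np.nan
        res = select_genes(pairs, SelectionCriteria(), identity_map(pairs))
        assert res.up == []
        assert res.table["reason"].iloc[0] == "incomplete"

    def test_multi_probe_gene_needs_every_probe(self):
        p2g = pd.Series({"P1": "G", "P2": "G"})
        pairs = []
        for donor, (r1, r2) in zip(
            ["D1", "D2", "D3"], [(4.0, 4.0), (4.0, 0.9), (4.0, 4.0)]
        ):
            pairs.append(
                make_pair(donor, {"P1": r1 * 1000, "P2": r2 * 1000},
                          {"P1": 1000.0, "P2": 1000.0})
            )
        res = select_genes(pairs, SelectionCriteria(), p2g)
        # P2 flips direction in donor D2 -> whole gene rejected
        assert res.up == []
        oracle = brute_force_select(pairs, SelectionCriteria(), p2g)
        assert oracle.up == []

    def test_reported_fold_change_uses_brightest_probe(self):
        p2g = pd.Series({"P1": "G", "P2": "G"})
        pairs = [
            make_pair(d, {"P1": 4000.0, "P2": 40000.0},
                      {"P1": 1000.0, "P2": 10000.0})
            for d in ["D1", "D2", "D3"]
        ]
        res = select_genes(pairs, SelectionCriteria(), p2g)
        assert res.up == ["G"]
        # both probes show 4x; reported ratios must come from P2 (brightest)
        assert res.table["ratio_D1"].iloc[0] == pytest.approx(4.0)


def random_instance(rng, n_genes):
    """Random small instance with ratios and intensities concentrated around
    the decision boundaries."""
    genes = [f"g{i}" for i in range(n_genes)]
    pairs = []
    for donor in ["D1", "D2", "D3"]:
        den = np.maximum(15.0, np.exp(rng.normal(np.log(120), 1.0, n_genes)))
        ratios = np.exp(rng.normal(0.0, np.log(2.2), n_genes))
        pairs.append(
            make_pair(donor, dict(zip(genes, den * ratios)),
                      dict(zip(genes, den)))
        )
    return pairs, pd.Series(genes, index=genes)


class TestOracleAndProperties:
    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            pairs, p2g = random_instance(rng, int(rng.integers(2, 40)))
            a = select_genes(pairs, SelectionCriteria(), p2g)
            b = brute_force_select(pairs, SelectionCriteria(), p2g)
            assert (a.up, a.down) == (b.up, b.down)

    def test_antisymmetry_under_pair_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs, p2g = random_instance(rng, 30)
            fwd = select_genes(pairs, SelectionCriteria(), p2g)
            swapped = [
                CellPair(p.donor, numerator=p.denominator,
                         denominator=p.numerator)
                for p in pairs
            ]
            rev = select_genes(swapped, SelectionCriteria(), p2g)
            assert fwd.up == rev.down
            assert fwd.down == rev.up

    def test_raising_threshold_never_grows_selection(self):
        rng = np.random.default_rng(42)
        pairs, p2g = random_instance(rng, 120)
        loose = select_genes(pairs, SelectionCriteria(fc_threshold=1.8), p2g)
        tight = select_genes(pairs, SelectionCriteria(fc_threshold=2.6), p2g)
        assert set(tight.up) <= set(loose.up)
        assert set(tight.down) <= set(loose.down)

    def test_up_down_lists_disjoint(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            pairs, p2g = random_instance(rng, 50)
            res = select_genes(pairs, SelectionCriteria(), p2g)
            assert not set(res.up) & set(res.down)

    def test_empty_and_null_instances(self):
        pairs = pairs_from_ratio_table({"G": (1.0, 1.0, 1.0)})
        res = brute_force_select(pairs, SelectionCriteria(),
                                 identity_map(pairs))
        assert res.up == [] and res.down == []
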