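import numpy as np
import pandas as pd
import pytest

from mscarray.normalization import NormalizedArray
from mscarray.paired_selection import CellPair
from mscarray.synthetic_data import RegulatedGene, StudyConfig


def make_features(gps, probe_id="P1", gene="G1", manual=None, outlier=None,
                  pixel_cv=None, control_type=0):
    """Build a replicate population DataFrame for one probe."""
    n = len(gps)
    return pd.DataFrame(
        {
            "probe_id": probe_id,
            "gene_symbol": gene,
            "control_type": control_type,
            "gps": np.asarray(gps, dtype=float),
            "manual_flag": manual if manual is not None else [False] * n,
            "outlier_flag": outlier if outlier is not None else [False] * n,
            "pixel_cv": pixel_cv if pixel_cv is not None else [0.1] * n,
        }
    )


def make_pair(donor, num_values, den_values):
    """CellPair from probe->value dicts (already normalized/floored)."""
    return CellPair(
        donor=donor,
        numerator=NormalizedArray(
            sample_id=f"{donor}_high", values=pd.Series(num_values, dtype=float),
            scaling_factor=1.0, floored=True, floor_value=15.0,
        ),
        denominator=NormalizedArray(
            sample_id=f"{donor}_none", values=pd.Series(den_values, dtype=float),
            scaling_factor=1.0, floored=True, floor_value=15.0,
        ),
    )


def pairs_from_ratio_table(ratios, den_intensity=1000.0):
    """Three cell pairs realizing per-gene ratio triples.

    ``ratios``: dict gene -> (r1, r2, r3).  Every denominator value is
    ``den_intensity`` and the numerator is ratio * denominator, so both
    sides can be placed relative to the selection intensity floor.
    """
    pairs = []
    for i, donor in enumerate(["D1", "D2", "D3"]):
        num = {g: rs[i] * den_intensity for g, rs in ratios.items()}
        den = {g: den_intensity for g in ratios}
        pairs.append(make_pair(donor, num, den))
    return pairs


@pytest.fixture
def zero_noise_config():
    """Small noiseless study with one up- and one down-regulated gene pinned
    far above both the surrogate floor and the scaling percentile."""
    return StudyConfig(
        n_genes=120,
        n_negative_controls=20,
        seed=11,
        replicate_noise_cv=0.0,
        outlier_rate=0.0,
        manual_flag_rate=0.0,
        high_pixel_cv_rate=0.0,
        qpcr_ct_noise_sd=0.0,
        regulated_genes=(
            RegulatedGene("G00007", "up", 4.0, baseline=20000.0),
            RegulatedGene("G00042", "down", 4.0, baseline=20000.0),
        ),
    )


@pytest.fixture
def probe_gene_identity():
    def _map(genes):
        return pd.Series({g: g for g in genes})

    return _map
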