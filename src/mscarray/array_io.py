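"""Readers and writers for probe-level feature tables and expression matrices.

The probe-level dialect mirrors the feature-extraction style output of a
one-color scanner: one row per physical on-chip feature, tab-separated,
with the processed green-channel signal (gPS) plus the QC annotations the
downstream exclusion rules consume.  Control probes are kept and labelled:
``ControlType`` 0 = regular probe, -1 = negative control, 1 = other control.

A minimal GEO series-matrix reader is included so a deposited series can be
fed straight into the paired fold-change screen.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import FormatError

FEATURE_COLUMNS = [
    "ProbeName",
    "GeneSymbol",
    "ControlType",
    "gProcessedSignal",
    "IsManualFlag",
    "IsFeatureOutlier",
    "PixelCV",
]

#: internal (snake_case) column names used throughout the pipeline
_INTERNAL = {
    "ProbeName": "probe_id",
    "GeneSymbol": "gene_symbol",
    "ControlType": "control_type",
    "gProcessedSignal": "gps",
    "IsManualFlag": "manual_flag",
    "IsFeatureOutlier": "outlier_flag",
    "PixelCV": "pixel_cv",
}

NON_CONTROL = 0
NEGATIVE_CONTROL = -1
OTHER_CONTROL = 1


def read_feature_table(path) -> pd.DataFrame:
    """Read a probe-level feature table (TSV).

    Returns a DataFrame with one row per on-chip feature and columns
    ``probe_id, gene_symbol, control_type, gps, manual_flag, outlier_flag,
    pixel_cv``.  Control rows are retained.

    Raises
    ------
    FormatError
        If a required column is missing (the message names it) or a row
        carries a non-numeric signal (the message carries the line number).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"feature table {path!s} lacks required column {col!r}")
    df = df[FEATURE_COLUMNS].rename(columns=_INTERNAL)

    gps = pd.to_numeric(df["gps"], errors="coerce")
    bad = gps.isna() | (gps < 0)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"feature table {path!s}, line {line}: "
            f"non-numeric or negative gProcessedSignal {df['gps'].iloc[line - 2]!r}"
        )
    df["gps"] = gps.astype(float)
    df["control_type"] = pd.to_numeric(df["control_type"]).astype(int)
    df["manual_flag"] = pd.to_numeric(df["manual_flag"]).astype(int).astype(bool)
    df["outlier_flag"] = pd.to_numeric(df["outlier_flag"]).astype(int).astype(bool)
    df["pixel_cv"] = pd.to_numeric(df["pixel_cv"]).astype(float)
    if (df["pixel_cv"] < 0).any():
        raise FormatError(f"feature table {path!s}: negative PixelCV")
    if (df["probe_id"] == "").any():
        raise FormatError(f"feature table {path!s}: empty ProbeName")
    return df


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write a feature DataFrame in the TSV dialect read by
    :func:`read_feature_table` (bit-exact round trip for valid tables)."""
    out = pd.DataFrame(
        {
            "ProbeName": features["probe_id"],
            "GeneSymbol": features["gene_symbol"],
            "ControlType": features["control_type"].astype(int),
            "gProcessedSignal": features["gps"],
            "IsManualFlag": features["manual_flag"].astype(int),
            "IsFeatureOutlier": features["outlier_flag"].astype(int),
            "PixelCV": features["pixel_cv"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a probe/gene x sample expression matrix (TSV, first column id,
    ``NA`` for missing entries)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Parse a GEO series-matrix file into a sample-annotated matrix.

    Only the standard ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    framing plus the ``!Sample_title`` line is interpreted; columns are named
    by sample title when present (verbatim, quotes stripped), otherwise by
    accession.  Values of ``null`` / empty are treated as missing.

    Raises
    ------
    FormatError
        If the table markers are absent.
    """
    titles: list[str] | None = None
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(stripped)
            elif stripped.startswith("!Sample_title"):
                fields = stripped.split("\t")[1:]
                titles = [f.strip().strip('"') for f in fields]
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path!s}: missing series_matrix_table begin/end markers"
        )
    buf = _io.StringIO("\n".join(table_lines))
    df = pd.read_csv(buf, sep="\t", index_col=0, na_values=["null", ""])
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    if titles is not None and len(titles) == df.shape[1]:
        df.columns = titles
    return df.astype(float)


def write_geo_series_matrix(matrix: pd.DataFrame, path,
                            titles: Iterable[str] | None = None) -> None:
    """Write an expression matrix with minimal series-matrix framing
    (used for synthetic reproduction fixtures)."""
    cols = list(matrix.columns)
    with open(path, "wt", encoding="utf-8") as fh:
        if titles is None:
            titles = cols
        fh.write("!Sample_title\t" + "\t".join(f'"{t}"' for t in titles) + "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("ID_REF\t" + "\t".join(f'"{c}"' for c in cols) + "\n")
        for idx, row in matrix.iterrows():
            vals = "\t".join("null" if pd.isna(v) else repr(float(v)) for v in row)
            fh.write(f'"{idx}"\t{vals}\n')
        fh.write("!series_matrix_table_end\n")
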