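"""Tabular readers and writers (TSV/CSV) for the pipeline's inputs and outputs.

Canonical orientation is samples in rows; files with features in rows are
handled by ``orientation="features_in_rows"``.  Accepted missing-value tokens
are "NA", "NaN" and the empty cell; "NA" is emitted on write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, PhenotypeTable, ValidationError

MISSING_TOKENS = ("NA", "NaN", "")


def _read_table(path, numeric: bool) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = sorted({c for i, c in enumerate(header) if c in header[:i]})
    if dup_cols:
        raise ValidationError(f"{path.name}: duplicate column id(s): {', '.join(dup_cols[:5])}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, na_values=list(MISSING_TOKENS))
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path.name}: duplicate row id(s): {', '.join(map(str, dups[:5]))}")
    df.index.name = None
    df.columns.name = None
    if numeric:
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name}: non-numeric cell: {exc}") from exc
    return df


def read_feature_matrix(path, orientation: str = "samples_in_rows") -> FeatureMatrix:
    """Read a feature matrix from tab- or comma-separated text.

    Parameters
    ----------
    path
        File with one header row and one id column.
    orientation
        "samples_in_rows" (canonical) or "features_in_rows" (transposed on
        read, so the two readings of the same data are identical).
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path, numeric=True)
    if orientation == "features_in_rows":
        df = df.T
    return FeatureMatrix(df)


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    fm.values.to_csv(path, sep=sep, na_rep="NA", float_format="%g",
                     index_label="id")


def read_phenotype_table(path, ambiguous_labels=("Maybe",)) -> PhenotypeTable:
    """Read a samples x experiments table of categorical labels.

    Labels are preserved verbatim; ambiguous labels are marked, never dropped
    here (removal is a per-experiment downstream choice).
    """
    df = _read_table(path, numeric=False)
    return PhenotypeTable(df, ambiguous_labels=ambiguous_labels)


def write_phenotype_table(pt: PhenotypeTable, path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    pt.labels.to_csv(path, sep=sep, na_rep="NA", index_label="id")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a report table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")
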