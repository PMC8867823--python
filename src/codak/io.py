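"""Delimited-text readers/writers and dataset assembly.

Abundance tables are CSV/TSV with the sample ID in the first column and one
column per cell type; all-integer tables are treated as counts, anything
else as proportions.  Metadata tables carry the predictor and optional
covariates, aligned to the abundance table by sample ID regardless of row
order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .adjust import CovariateMatrix
from .compositions import CompositionMatrix, CountMatrix

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "write_matrix",
    "load_dataset",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    return df


def read_abundance_table(path: str | Path) -> CountMatrix | CompositionMatrix:
    """Read an abundance table, auto-detecting counts versus proportions."""
    df = _read_delimited(path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
        raise ValueError(f"non-numeric abundance columns: {bad.tolist()}")
    ids = [str(s) for s in df.index]
    cols = [str(c) for c in df.columns]
    if np.allclose(values, np.rint(values)) and values.max() > 1:
        return CountMatrix(values, ids, cols)
    return CompositionMatrix(values, ids, cols)


def write_abundance_table(
    data: CountMatrix | CompositionMatrix, path: str | Path
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    data.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


def write_matrix(values: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    """Export a square matrix (distance or kernel) with sample-ID headers."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(values, index=sample_ids, columns=sample_ids).to_csv(
        path, sep=sep, index_label="sample_id"
    )


def load_dataset(
    table_path: str | Path,
    metadata_path: str | Path,
    predictor_column: str,
    covariate_columns: list[str] | None = None,
    strata_column: str | None = None,
):
    """Load and align an abundance table with its metadata by sample ID.

    Returns ``(data, predictor, covariates, strata)``; covariates/strata are
    None unless requested.  Metadata row order is irrelevant; every sample in
    the abundance table must appear in the metadata.
    """
    data = read_abundance_table(table_path)
    meta = _read_delimited(metadata_path)
    meta.index = meta.index.astype(str)
    missing = [s for s in data.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata is missing samples: {missing}")
    meta = meta.loc[data.sample_ids]
    if predictor_column not in meta.columns:
        raise ValueError(f"predictor column {predictor_column!r} not in metadata")
    x = meta[predictor_column].to_numpy()
    covariates = None
    if covariate_columns:
        absent = [c for c in covariate_columns if c not in meta.columns]
        if absent:
            raise ValueError(f"covariate columns not in metadata: {absent}")
        covariates = CovariateMatrix.from_dataframe(meta[list(covariate_columns)])
    strata = None
    if strata_column is not None:
        if strata_column not in meta.columns:
            raise ValueError(f"strata column {strata_column!r} not in metadata")
        strata = meta[strata_column].to_numpy()
    return data, x, covariates, strata
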