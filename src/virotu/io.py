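"""CSV readers and writers for the pipeline's tabular contracts.

All tables are plain CSV with headers and stable column order, so that
re-reading any output reproduces the in-memory object and repeated runs
are byte-identical.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .occurrence import COVERAGE_COLUMNS, validate_coverage

PAIRS_COLUMNS = ["seq_a", "seq_b", "identity", "coverage"]


def write_coverage(path, cov: pd.DataFrame) -> None:
    validate_coverage(cov)
    cov[COVERAGE_COLUMNS].to_csv(path, index=False)


def read_coverage(path) -> pd.DataFrame:
    cov = pd.read_csv(path)
    validate_coverage(cov)
    return cov


def write_design(path, design: pd.DataFrame) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_occurrence(path, occ: pd.DataFrame) -> None:
    """Occurrence matrix as 0/1 CSV, vOTUs in rows."""
    occ.astype(int).to_csv(path, index=True, index_label="votu_id")


def read_occurrence(path) -> pd.DataFrame:
    occ = pd.read_csv(path, index_col="votu_id")
    occ.columns.name = "sample_id"
    return occ.astype(bool)


def write_abundance(path, abund: pd.DataFrame) -> None:
    """TPM matrix CSV at 6 decimal places."""
    abund.to_csv(path, index=True, index_label="votu_id", float_format="%.6f")


def read_abundance(path) -> pd.DataFrame:
    ab = pd.read_csv(path, index_col="votu_id")
    ab.columns.name = "sample_id"
    return ab


def write_matrix(path, mat: pd.DataFrame, float_format: str = "%.6f") -> None:
    """Square labeled matrix (e.g. dissimilarities) as CSV."""
    mat.to_csv(path, index=True, float_format=float_format)


def read_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    missing = set(PAIRS_COLUMNS) - set(pairs.columns)
    if missing:
        raise ValueError(f"pairwise similarity table missing columns: {sorted(missing)}")
    return pairs


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_hosts(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_functions(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
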