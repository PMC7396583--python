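"""Delimited-text input/output for every pipeline table.

All tables are TSV with a one-line column header; lines starting with ``#``
are comments (generator provenance is written there) and are skipped on
read. Matrices carry the feature id in the first column; sample metadata is
a separate TSV keyed by ``sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from coldomics.degsets import ExpressionMatrix
from coldomics.lipidomics import LipidProfile

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "read_expression",
    "read_lipid_profile",
    "read_ffa",
    "reference_dbi_table",
    "reference_ffa_table",
]

_DATA_DIR = Path(__file__).parent / "data"


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV; first column is the feature id."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_matrix(df: pd.DataFrame, path, *, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return meta


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    return ExpressionMatrix(values=read_matrix(expr_path), meta=read_metadata(meta_path))


def read_lipid_profile(profile_path, meta_path) -> LipidProfile:
    return LipidProfile(values=read_matrix(profile_path), meta=read_metadata(meta_path))


def read_ffa(table_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    return read_matrix(table_path), read_metadata(meta_path)


def reference_dbi_table() -> pd.DataFrame:
    """Published per-class membrane-lipid DBI reference values for the NH5/FH18
    cultivar pair (control and 24-h cold columns with their relative changes)."""
    return pd.read_csv(_DATA_DIR / "reference_dbi.tsv", sep="\t", comment="#", index_col=0)


def reference_ffa_table() -> pd.DataFrame:
    """Published 22-component free-fatty-acid panel means (ng mg^-1) for the
    NH5/FH18 cultivar pair under control and 24-h cold conditions."""
    return pd.read_csv(_DATA_DIR / "reference_ffa.tsv", sep="\t", comment="#", index_col=0)
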