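"""Readers and writers for the tab-delimited interchange formats.

All tables are plain TSV with a header row: mutation tables carry
``chrom, pos, ref, alt, context`` plus per-sample ``depth_<s>`` /
``alt_<s>`` column pairs; count matrices have gene (or barcode) rows and
sample columns; ligand-receptor pair tables have two columns.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_mutation_table",
    "write_mutation_table",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_pairs_tsv",
]

_MUTATION_FIXED = ["chrom", "pos", "ref", "alt", "context"]


def read_mutation_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MUTATION_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df


def write_mutation_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Gene/barcode x sample integer count matrix (first column = row id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(df: pd.DataFrame, path: str, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        # accept headerless two-column DLRP-style tables
        df = pd.read_csv(path, sep="\t", header=None, names=["ligand", "receptor"])
    return df[["ligand", "receptor"]]
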