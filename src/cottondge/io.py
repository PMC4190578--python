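"""Readers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import ReferenceTranscript

__all__ = [
    "read_reference_fasta",
    "read_tag_library",
    "read_gene_counts",
    "read_design",
]


def read_reference_fasta(path: str | Path) -> list[ReferenceTranscript]:
    from Bio import SeqIO

    return [
        ReferenceTranscript(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_tag_library(path: str | Path) -> dict[str, int]:
    """2-column headerless TSV ``tag<TAB>count``."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["tag", "count"],
        dtype={"tag": str, "count": int},
    )
    return dict(zip(df["tag"], df["count"]))


def read_gene_counts(path: str | Path) -> dict[str, int]:
    """TSV with header ``gene_id<TAB>count``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "count": int})
    return dict(zip(df["gene_id"], df["count"]))


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
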