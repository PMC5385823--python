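"""Plain-text readers and writers for the pipeline's on-disk formats.

Matrix TSV: header row of sample ids, first column gene ids. Class TSV: two
columns ``sample`` and ``class``. FASTA via Biopython, wrapped at 60 columns.
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CASE, CONTROL, NORMAL, TUMOR, CountDataset, ExpressionDataset
from .errors import FormatError


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    return df


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "gene") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_classes(path: str | os.PathLike, allowed: set[str] | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "class"]:
        raise FormatError(f"{path}: expected columns 'sample' and 'class'")
    ser = df.set_index("sample")["class"]
    if allowed is not None:
        bad = set(ser) - allowed
        if bad:
            raise FormatError(f"{path}: unknown class labels {sorted(bad)}")
    return ser


def write_classes(samples: list[str], classes, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample": samples, "class": list(classes)}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_expression_dataset(
    matrix_path: str | os.PathLike,
    classes_path: str | os.PathLike,
    name: str | None = None,
    log2: bool = True,
) -> ExpressionDataset:
    df = read_matrix(matrix_path)
    classes = read_classes(classes_path, allowed={TUMOR, NORMAL})
    missing = [s for s in df.columns if s not in classes.index]
    if missing:
        raise FormatError(f"{classes_path}: samples without class label: {missing}")
    return ExpressionDataset(
        name=name or Path(matrix_path).stem,
        genes=list(df.index),
        samples=list(df.columns),
        values=df.to_numpy(float),
        classes=classes.loc[list(df.columns)].to_numpy(),
        log2=log2,
    )


def read_count_dataset(
    counts_path: str | os.PathLike, classes_path: str | os.PathLike
) -> CountDataset:
    df = read_matrix(counts_path)
    classes = read_classes(classes_path, allowed={CASE, CONTROL})
    missing = [s for s in df.columns if s not in classes.index]
    if missing:
        raise FormatError(f"{classes_path}: samples without class label: {missing}")
    return CountDataset(
        genes=list(df.index),
        samples=list(df.columns),
        counts=df.to_numpy(),
        classes=classes.loc[list(df.columns)].to_numpy(),
    )


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs, wrapped at 60 columns."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqrecords = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_table(df: pd.DataFrame, path: str | os.PathLike, **kwargs) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", **kwargs)
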