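"""Readers and writers for the pipeline's standard text formats.

Every writer here round-trips through its matching reader (the
``format_round_trip`` contract): FASTA, Newick, Rtab-style presence/absence
TSV, square distance-matrix TSV, CSV tables, and JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hostflux.errors import InputError
from hostflux.tree import Tree

PathLike = Union[str, Path]

__all__ = [
    "read_fasta", "write_fasta",
    "read_presence_tsv", "write_presence_tsv",
    "read_distance_tsv", "write_distance_tsv",
    "read_newick", "write_newick",
    "read_json", "write_json",
    "format_round_trip",
]


# ---------------------------------------------------------------------- #
# FASTA
# ---------------------------------------------------------------------- #

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise InputError(f"duplicate FASTA id {record.id!r} in {path}")
        out[record.id] = str(record.seq).upper()
    if not out:
        raise InputError(f"no FASTA records in {path}")
    return out


def write_fasta(path: PathLike, sequences: dict[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------- #
# presence/absence TSV (Rtab-style: rows = families, columns = genomes)
# ---------------------------------------------------------------------- #

def write_presence_tsv(path: PathLike, genomes: list[str], families: list[str],
                       values: np.ndarray) -> None:
    frame = pd.DataFrame(values.T.astype(int), index=pd.Index(families, name="Gene"),
                         columns=genomes)
    frame.to_csv(path, sep="\t")


def read_presence_tsv(path: PathLike) -> tuple[list[str], list[str], np.ndarray]:
    """Return (genome ids, family ids, boolean genomes × families matrix)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise InputError(f"empty presence/absence table in {path}")
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise InputError(f"presence/absence table {path} contains non-binary cells")
    return list(frame.columns), list(frame.index), values.T.astype(bool)


# ---------------------------------------------------------------------- #
# square distance matrix TSV
# ---------------------------------------------------------------------- #

def write_distance_tsv(path: PathLike, labels: list[str], matrix: np.ndarray) -> None:
    frame = pd.DataFrame(matrix, index=pd.Index(labels, name="id"), columns=labels)
    frame.to_csv(path, sep="\t")


def read_distance_tsv(path: PathLike) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise InputError(f"distance matrix {path} rows and columns disagree")
    return list(frame.index), frame.to_numpy(dtype=float)


# ---------------------------------------------------------------------- #
# Newick / JSON
# ---------------------------------------------------------------------- #

def read_newick(path: PathLike) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def write_newick(path: PathLike, tree: Tree, **kwargs) -> None:
    Path(path).write_text(tree.to_newick(**kwargs) + "\n")


def read_json(path: PathLike):
    with open(path) as handle:
        return json.load(handle)


def write_json(path: PathLike, obj) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


# ---------------------------------------------------------------------- #
# round-trip checker
# ---------------------------------------------------------------------- #

def format_round_trip(path: PathLike, fmt: str, out_path: PathLike):
    """Parse ``path`` as ``fmt``, rewrite to ``out_path``, and return the
    parsed object.  Raises :class:`InputError` on malformed input."""
    if fmt == "fasta":
        obj = read_fasta(path)
        write_fasta(out_path, obj)
    elif fmt == "newick":
        obj = read_newick(path)
        write_newick(out_path, obj)
    elif fmt == "tsv-matrix":
        genomes, families, values = obj = read_presence_tsv(path)
        write_presence_tsv(out_path, genomes, families, values)
    elif fmt == "csv":
        obj = pd.read_csv(path)
        obj.to_csv(out_path, index=False)
    elif fmt == "json":
        obj = read_json(path)
        write_json(out_path, obj)
    else:
        raise InputError(f"unknown format {fmt!r}")
    return obj
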