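"""Partitioned character matrices and their on-disk formats.

A :class:`CharacterMatrix` is taxa x characters over an arbitrary symbol
alphabet with ``?`` as the missing symbol (``-`` is treated as missing for
scoring by default).  Partitions map partition names to column-index arrays;
every column belongs to exactly one partition.

Formats: NEXUS (DATA block + SETS block with one charset per partition,
1-based inclusive ranges) and relaxed PHYLIP plus a partition TSV
(partition_name, start, end; 1-based inclusive).  NEXUS reading is delegated
to dendropy; writing is done directly so charset boundaries are controlled.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import dendropy

MISSING = "?"
GAP = "-"


class MatrixError(ValueError):
    """Invalid character matrix or partition map."""


class CharacterMatrix:
    """Taxa x characters with named, disjoint column partitions."""

    def __init__(self, taxa: Sequence[str], data,
                 partitions: Optional[Mapping[str, Sequence[int]]] = None):
        self.taxa = list(taxa)
        arr = np.asarray(data)
        if arr.dtype.kind != "U":
            arr = arr.astype("<U1")
        if arr.ndim != 2:
            raise MatrixError("data must be 2-D (taxa x characters)")
        if arr.shape[0] != len(self.taxa):
            raise MatrixError(
                f"{len(self.taxa)} taxa but {arr.shape[0]} rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon names")
        self.data = arr.astype("<U1")
        if partitions is None:
            partitions = {"all": range(arr.shape[1])}
        self.partitions = {name: np.asarray(list(idx), dtype=int)
                           for name, idx in partitions.items()}
        self._validate_partitions()
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def _validate_partitions(self) -> None:
        ncols = self.data.shape[1]
        seen = np.zeros(ncols, dtype=bool)
        for name, idx in self.partitions.items():
            if len(idx) == 0:
                raise MatrixError(f"partition {name!r} is empty")
            if idx.min() < 0 or idx.max() >= ncols:
                raise MatrixError(f"partition {name!r} indexes out of range")
            if seen[idx].any():
                raise MatrixError(f"partition {name!r} overlaps another partition")
            seen[idx] = True
        if not seen.all():
            raise MatrixError("some columns belong to no partition")

    # -- accessors ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.data[self._index[taxon]]
        except KeyError:
            raise MatrixError(f"no row for taxon {taxon!r}") from None

    @classmethod
    def from_dict(cls, rows: Mapping[str, str],
                  partitions: Optional[Mapping[str, Sequence[int]]] = None
                  ) -> "CharacterMatrix":
        taxa = list(rows)
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise MatrixError("sequences have unequal lengths")
        data = np.array([list(rows[t]) for t in taxa], dtype="<U1")
        return cls(taxa, data, partitions)

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def is_missing_row(self, taxon: str,
                       columns: Optional[Sequence[int]] = None) -> bool:
        row = self.row(taxon)
        if columns is not None:
            row = row[np.asarray(columns, dtype=int)]
        return bool(np.isin(row, [MISSING, GAP]).all())

    def present_taxa(self, columns: Optional[Sequence[int]] = None) -> list[str]:
        return [t for t in self.taxa if not self.is_missing_row(t, columns)]

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self._index[t] for t in taxa]
        return CharacterMatrix(list(taxa), self.data[idx],
                               {k: v for k, v in self.partitions.items()})


def concat_matrices(blocks: Sequence[tuple[str, CharacterMatrix]],
                    taxa: Sequence[str]) -> CharacterMatrix:
    """Concatenate per-partition matrices over a common taxon list.

    ``blocks`` are (partition_name, matrix) pairs; taxa absent from a block
    are filled with ``?``.  Each block's own partitioning is ignored.
    """
    ncols = sum(m.n_columns for _, m in blocks)
    data = np.full((len(taxa), ncols), MISSING, dtype="<U1")
    pos = {t: i for i, t in enumerate(taxa)}
    partitions = {}
    at = 0
    for name, m in blocks:
        w = m.n_columns
        for t in m.taxa:
            if t in pos:
                data[pos[t], at:at + w] = m.row(t)
        partitions[name] = range(at, at + w)
        at += w
    return CharacterMatrix(taxa, data, partitions)


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def _partition_ranges(idx: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous 1-based inclusive ranges covering a sorted index array."""
    idx = np.sort(idx)
    ranges = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            ranges.append((start + 1, prev + 1))
            start = prev = i
    ranges.append((start + 1, prev + 1))
    return ranges


def write_nexus(matrix: CharacterMatrix, path, datatype: str = "protein") -> None:
    """Write a DATA block plus a SETS block with one charset per partition."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_columns};\n")
        fh.write(f"    FORMAT DATATYPE={datatype.upper()} MISSING={MISSING} GAP={GAP};\n")
        fh.write("    MATRIX\n")
        width = max(len(t) for t in matrix.taxa) + 4
        for t in matrix.taxa:
            name = f"'{t}'" if " " in t else t
            fh.write(f"    {name:<{width}} {matrix.sequence(t)}\n")
        fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
        for name, idx in matrix.partitions.items():
            spans = " ".join(
                f"{a}-{b}" if a != b else str(a)
                for a, b in _partition_ranges(idx))
            fh.write(f"    CHARSET {name} = {spans};\n")
        fh.write("END;\n")


def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS character matrix with charsets (via dendropy)."""
    ds = dendropy.DataSet.get(path=str(path), schema="nexus",
                              preserve_underscores=True)
    if not ds.char_matrices:
        raise MatrixError(f"no character matrix in {path}")
    cm = ds.char_matrices[0]
    taxa = [t.label for t in cm.taxon_namespace]
    rows = {t.label: str(cm[t]).replace(" ", "") for t in cm.taxon_namespace}
    partitions = {}
    for name, subset in cm.character_subsets.items():
        partitions[name] = sorted(subset.character_indices)
    return CharacterMatrix.from_dict(rows, partitions or None)


# ---------------------------------------------------------------------------
# Relaxed PHYLIP + partition TSV
# ---------------------------------------------------------------------------

def write_phylip(matrix: CharacterMatrix, path, partitions_path=None) -> None:
    bad = [t for t in matrix.taxa if any(c.isspace() for c in t)]
    if bad:
        raise MatrixError(
            f"relaxed PHYLIP cannot hold whitespace in taxon names: {bad}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{matrix.n_taxa} {matrix.n_columns}\n")
        for t in matrix.taxa:
            fh.write(f"{t}  {matrix.sequence(t)}\n")
    if partitions_path is not None:
        rows = []
        for name, idx in matrix.partitions.items():
            for a, b in _partition_ranges(idx):
                rows.append({"partition_name": name, "start": a, "end": b})
        pd.DataFrame(rows).to_csv(partitions_path, sep="\t", index=False)


def read_phylip(path, partitions_path=None) -> CharacterMatrix:
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    try:
        ntax, nchar = map(int, lines[0].split())
    except Exception as exc:
        raise MatrixError(f"bad PHYLIP header in {path}: {lines[0]!r}") from exc
    rows = {}
    for ln in lines[1:1 + ntax]:
        name, seq = ln.split(None, 1)
        rows[name] = seq.replace(" ", "")
        if len(rows[name]) != nchar:
            raise MatrixError(
                f"row {name!r} has {len(rows[name])} characters, expected {nchar}")
    partitions = None
    if partitions_path is not None:
        df = pd.read_csv(partitions_path, sep="\t")
        partitions = {}
        for name, grp in df.groupby("partition_name", sort=False):
            idx: list[int] = []
            for _, r in grp.iterrows():
                idx.extend(range(int(r["start"]) - 1, int(r["end"])))
            partitions[name] = idx
    return CharacterMatrix.from_dict(rows, partitions)


# ---------------------------------------------------------------------------
# FASTA (aligned gene-family members, headers "geneid|speciesid")
# ---------------------------------------------------------------------------

def write_fasta(rows: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in rows.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_matrix(path) -> CharacterMatrix:
    """Read an aligned FASTA into a single-partition CharacterMatrix."""
    from Bio import SeqIO
    rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise MatrixError(f"no sequences in {path}")
    return CharacterMatrix.from_dict(rows)


def split_gene_header(header: str) -> tuple[str, str]:
    """Split a ``geneid|speciesid`` FASTA header; gene ids contain the species."""
    if "|" not in header:
        raise MatrixError(f"header {header!r} lacks the 'geneid|speciesid' form")
    gene, species = header.rsplit("|", 1)
    return header, species
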