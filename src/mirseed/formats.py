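"""Readers and writers for the external formats the pipeline touches.

All tabular formats are tab-separated UTF-8 with a mandatory header row and
"." as the decimal separator.  Sequence input is normalized so that RNA and
DNA files are interchangeable: for UTR sets U is mapped to T and everything
is uppercased; mature miRNAs are normalized the other way (T to U).

Missing expression values are rejected rather than imputed: a matrix cell
that does not parse as a finite number is an error carrying the row/column
address.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for any malformed or inconsistent input file."""


_DNA_ALPHABET = frozenset("ACGTN")
_RNA_ALPHABET = frozenset("ACGUN")


def normalize_dna(sequence: str) -> str:
    """Uppercase and map U->T; reject characters outside {A,C,G,T,N}."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def normalize_rna(sequence: str) -> str:
    """Uppercase and map T->U; reject characters outside {A,C,G,U,N}."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SeqEntry:
    sequence: str
    description: str = ""


class SequenceSet:
    """Ordered collection of uppercase DNA sequences keyed by unique ids."""

    def __init__(self) -> None:
        self._records: "OrderedDict[str, SeqEntry]" = OrderedDict()

    def add(self, seq_id: str, sequence: str, description: str = "") -> None:
        if not seq_id:
            raise FormatError("empty sequence id")
        if seq_id in self._records:
            raise FormatError(f"duplicate id {seq_id}")
        seq = normalize_dna(sequence)
        if len(seq) < 1:
            raise FormatError(f"empty sequence for id {seq_id}")
        self._records[seq_id] = SeqEntry(seq, description)

    def ids(self) -> list[str]:
        return list(self._records)

    def items(self) -> Iterator[tuple[str, SeqEntry]]:
        return iter(self._records.items())

    def __getitem__(self, seq_id: str) -> str:
        return self._records[seq_id].sequence

    def description(self, seq_id: str) -> str:
        return self._records[seq_id].description

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._records == other._records


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA sequence, 5'->3', RNA alphabet."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise FormatError("empty miRNA id")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if "N" in self.sequence:
            raise FormatError(f"ambiguous base in miRNA {self.mirna_id}")
        if len(self.sequence) < 16:
            raise FormatError(
                f"miRNA {self.mirna_id} shorter than 16 nt ({len(self.sequence)})"
            )


class SampleSheet:
    """Maps sample ids to (condition, replicate)."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"condition", "replicate"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns {sorted(missing)}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids {dups}")
        reps = pd.to_numeric(table["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
            raise FormatError("replicate must be a positive integer")
        self.table = table.assign(replicate=reps.astype(int))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "SampleSheet":
        rows = list(records)
        df = pd.DataFrame(
            rows, columns=["sample_id", "condition", "replicate"]
        ).set_index("sample_id")
        return cls(df)

    def conditions(self) -> list[str]:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for c in self.table["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return self.table.index[mask].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSheet):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]

    def member_set(self) -> frozenset:
        return frozenset(self.members)


class GeneSets:
    """Named gene sets (GMT semantics): unique members, non-empty sets."""

    def __init__(self) -> None:
        self._sets: "OrderedDict[str, GeneSet]" = OrderedDict()

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        if not set_id:
            raise FormatError("empty gene-set id")
        if set_id in self._sets:
            raise FormatError(f"duplicate gene-set id {set_id}")
        uniq: "OrderedDict[str, None]" = OrderedDict()
        for m in members:
            if m:
                uniq.setdefault(m, None)
        if not uniq:
            raise FormatError(f"gene set {set_id} has no members")
        self._sets[set_id] = GeneSet(set_id, description, tuple(uniq))

    def ids(self) -> list[str]:
        return list(self._sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def items(self) -> Iterator[tuple[str, GeneSet]]:
        return iter(self._sets.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSets):
            return NotImplemented
        return self._sets == other._sets


class OrthologMap:
    """Symbol pairing across species; many-to-one permitted in both directions."""

    def __init__(self) -> None:
        self.pairs: "OrderedDict[tuple[str, str], None]" = OrderedDict()
        self._fwd: dict[str, set[str]] = {}
        self._rev: dict[str, set[str]] = {}

    def add_pair(self, symbol_a: str, symbol_b: str) -> None:
        if not symbol_a or not symbol_b:
            raise FormatError("empty symbol in ortholog pair")
        key = (symbol_a, symbol_b)
        if key in self.pairs:  # duplicate rows are idempotent
            return
        self.pairs[key] = None
        self._fwd.setdefault(symbol_a, set()).add(symbol_b)
        self._rev.setdefault(symbol_b, set()).add(symbol_a)

    def forward(self, symbol_a: str) -> frozenset:
        return frozenset(self._fwd.get(symbol_a, ()))

    def reverse(self, symbol_b: str) -> frozenset:
        return frozenset(self._rev.get(symbol_b, ()))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologMap):
            return NotImplemented
        return list(self.pairs) == list(other.pairs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    """Read a nucleotide FASTA into a normalized :class:`SequenceSet`.

    Insertion order is preserved; U and lowercase are normalized away so
    RNA- and DNA-alphabet files scan identically downstream.
    """
    path = Path(path)
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.add(rec.id, str(rec.seq), desc)
    if len(out) == 0:
        raise FormatError(f"no FASTA records in {path}")
    return out


def read_mirna_fasta(path: str | Path) -> "OrderedDict[str, MatureMirna]":
    """Read mature miRNA sequences (RNA alphabet enforced after T->U)."""
    path = Path(path)
    out: "OrderedDict[str, MatureMirna]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate id {rec.id}")
        out[rec.id] = MatureMirna(rec.id, str(rec.seq))
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(seqset: SequenceSet, path: str | Path, width: int = 60) -> None:
    records = []
    for seq_id, entry in seqset.items():
        records.append(
            SeqRecord(Seq(entry.sequence), id=seq_id, description=entry.description)
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, samplesheet_path: str | Path
) -> tuple[pd.DataFrame, SampleSheet]:
    """Read a features x samples log2 matrix plus its sample sheet.

    Every matrix column must be annotated in the sheet; every cell must be a
    finite number (missing values are an error, not imputed).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature id {dups[0]}")
    if raw.columns.has_duplicates:
        raise FormatError("duplicate sample columns in matrix")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-numeric or missing value at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    matrix = values.astype(float)
    matrix.index.name = None

    sheet_df = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    if "sample_id" not in sheet_df.columns:
        raise FormatError("sample sheet missing column 'sample_id'")
    sheet = SampleSheet(sheet_df.set_index("sample_id"))
    for col in matrix.columns:
        if col not in sheet.table.index:
            raise FormatError(f"unannotated sample {col}")
    return matrix, sheet


def write_expression(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    matrix_path: str | Path,
    samplesheet_path: str | Path,
) -> None:
    out = matrix.copy()
    out.index.name = "feature_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g")
    st = sheet.table.copy()
    st.index.name = "sample_id"
    st.to_csv(samplesheet_path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSets:
    path = Path(path)
    sets = GeneSets()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set_id, description and "
                    f"at least one member"
                )
            try:
                sets.add(fields[0], fields[1], fields[2:])
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if n_lines == 0:
        raise FormatError(f"empty GMT file {path}")
    return sets


def write_gmt(sets: GeneSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, gs in sets.items():
            fh.write("\t".join([set_id, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Flat annotation tables
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path, columns: list[str]) -> list[tuple]:
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"empty file {path}")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in columns if c not in header]
        if missing:
            raise FormatError(f"{path}:1: missing columns {missing}")
        idx = [header.index(c) for c in columns]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            row = tuple(fields[i] for i in idx)
            if any(not v for v in row):
                raise FormatError(f"{path}:{lineno}: empty field")
            rows.append(row)
    if not rows:
        raise FormatError(f"no data rows in {path}")
    return rows


def read_target_table(path: str | Path) -> list:
    """Read a flat (source, mirna_id, gene) table into per-source predictions.

    Duplicate membership rows collapse idempotently.
    """
    from .seedtargets import TargetPredictions

    rows = _read_tsv_rows(path, ["source", "mirna_id", "gene"])
    by_source: "OrderedDict[str, OrderedDict[str, OrderedDict[str, None]]]" = OrderedDict()
    for source, mirna_id, gene in rows:
        by_source.setdefault(source, OrderedDict()).setdefault(
            mirna_id, OrderedDict()
        ).setdefault(gene, None)
    return [
        TargetPredictions(
            source=source,
            targets={m: frozenset(genes) for m, genes in per_mirna.items()},
        )
        for source, per_mirna in by_source.items()
    ]


def write_target_table(predictions: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tmirna_id\tgene\n")
        for pred in predictions:
            for mirna_id in sorted(pred.targets):
                for gene in sorted(pred.targets[mirna_id]):
                    fh.write(f"{pred.source}\t{mirna_id}\t{gene}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    rows = _read_tsv_rows(path, ["symbol_a", "symbol_b"])
    out = OrthologMap()
    for a, b in rows:
        out.add_pair(a, b)
    return out


def write_ortholog_map(orthologs: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol_a\tsymbol_b\n")
        for a, b in orthologs.pairs:
            fh.write(f"{a}\t{b}\n")


def read_annotation_tables(path: str | Path, kind: str):
    """Dispatch reader for GMT / target-prediction / ortholog tables."""
    readers = {
        "gmt": read_gmt,
        "targets": read_target_table,
        "orthologs": read_ortholog_map,
    }
    if kind not in readers:
        raise ValueError(f"unknown annotation kind {kind!r}")
    return readers[kind](path)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["AveExpr", "logFC", "t_mod", "p", "adjP"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE table missing columns {missing}")
    if df.index.has_duplicates:
        raise FormatError("duplicate feature ids in DE table")
    df.index.name = None
    return df


def write_de_table(detable: pd.DataFrame, path: str | Path) -> None:
    out = detable.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
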