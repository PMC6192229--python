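"""Readers and writers for the external formats the pipeline touches.

Sequence sets come in as plain FASTA (protein or CDS), pairwise similarity
hits as 12/14-column tabular files (BLAST ``outfmt 6`` dialect), and
expression data as a gene x tissue TSV of RPKM values.  Every report the
pipeline writes is a TSV with a JSON sidecar recording the run parameters,
so results stay reproducible without a database.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("wrkyevol")

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_LETTERS = frozenset("ACGTN")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``id`` is unique within a dataset."""

    id: str
    seq: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        _validate_seq(self.id, self.seq, PROTEIN_LETTERS)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsRecord:
    """A coding nucleotide sequence paired (by id) with a protein."""

    id: str
    seq: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        _validate_seq(self.id, self.seq, NUCLEOTIDE_LETTERS)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (tabular outfmt-6 dialect)."""

    query: str
    subject: str
    identity: float
    aln_len: int
    evalue: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


def _validate_seq(rec_id: str, seq: str, alphabet: frozenset[str]) -> None:
    if not rec_id:
        raise ValueError("record id must be non-empty")
    if not seq:
        raise ValueError(f"{rec_id}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"{rec_id}: illegal character {ch!r} at position {pos}"
            )


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    species: str = "",
) -> list[ProteinRecord] | list[CdsRecord]:
    """Parse a FASTA file into validated records.

    The id is the header token before the first whitespace; the full header
    is kept as ``description``.  Sequences are uppercased; a trailing ``*``
    (stop) on protein sequences is trimmed.  Duplicate ids and characters
    outside the declared alphabet are hard errors.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = ProteinRecord if alphabet == "protein" else CdsRecord
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq.rstrip("*")
        records.append(
            cls(id=rec.id, seq=seq, species=species, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_hit_table(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Parse a tabular hit file (outfmt-6 dialect).

    Standard 12 columns are accepted, optionally extended with columns
    13-14 = qlen, slen.  With only 12 columns, ``lengths`` (id -> sequence
    length, e.g. from the companion FASTA) must cover every referenced id.
    Lines starting with ``#`` are skipped.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                query, subject = fields[0], fields[1]
                identity = float(fields[2])
                aln_len = int(fields[3])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            if len(fields) == 14:
                qlen, slen = int(fields[12]), int(fields[13])
            else:
                if lengths is None:
                    raise ValueError(
                        f"{path}:{lineno}: 12-column row but no sequence "
                        "lengths supplied"
                    )
                try:
                    qlen, slen = lengths[query], lengths[subject]
                except KeyError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: no length known for id {exc}"
                    ) from None
            hits.append(
                HitRecord(
                    query=query, subject=subject, identity=identity,
                    aln_len=aln_len, evalue=evalue, qlen=qlen, slen=slen,
                )
            )
    return hits


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue RPKM matrix from TSV.

    First column is the gene id, header row carries tissue names.  Missing
    cells stay missing (NaN), they are never silently zero-filled; negative
    values and duplicated gene rows are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene rows: {dupes}")
    if (df < 0).any().any():
        bad = df.columns[(df < 0).any()].tolist()
        raise ValueError(f"negative expression values in columns {bad}")
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping | None = None,
    index: bool = True,
) -> None:
    """Write a report TSV plus a ``<path>.params.json`` sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    if params is not None:
        sidecar = path.with_name(path.name + ".params.json")
        with open(sidecar, "w") as fh:
            json.dump(dict(params), fh, indent=2, default=str)
            fh.write("\n")


def configure_logging(verbosity: int = 0) -> None:
    """Route pipeline logging to stderr; verbosity 0=warn, 1=info, 2=debug."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
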