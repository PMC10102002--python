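"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; the hyb-style 15-column
hybrid table and the TSV count tables are small, fully specified dialects
implemented here.

Coordinate convention: everything in memory is 0-based, half-open.  The
hyb dialect alone is 1-based, inclusive; conversion happens only inside
:func:`write_hyb` / :func:`parse_hyb`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize(seq: str, rna: bool = True) -> str:
    seq = seq.upper()
    if rna:
        seq = seq.replace("T", "U")
    return seq


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: id, RNA sequence 5'->3', and arm annotation."""

    id: str
    sequence: str
    arm: str = "unknown"  # guide | passenger | unknown

    def __post_init__(self) -> None:
        if not RNA_ALPHABET.issuperset(self.sequence):
            raise ValueError(f"miRNA {self.id}: non-RNA characters in sequence")
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"miRNA {self.id}: length {len(self.sequence)} outside 18-26 nt"
            )
        if self.arm not in ("guide", "passenger", "unknown"):
            raise ValueError(f"miRNA {self.id}: bad arm {self.arm!r}")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with an optional 3'UTR start offset.

    ``cds_end`` is the 0-based offset at which the 3'UTR begins; ``None``
    means the annotation is unavailable.
    """

    id: str
    gene: str
    sequence: str
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not RNA_ALPHABET.issuperset(self.sequence):
            raise ValueError(f"transcript {self.id}: non-RNA characters")
        if self.cds_end is not None and not 0 <= self.cds_end <= len(self.sequence):
            raise ValueError(f"transcript {self.id}: cds_end out of range")

    @property
    def utr3(self) -> str:
        if self.cds_end is None:
            raise ValueError(f"transcript {self.id} has no 3'UTR annotation")
        return self.sequence[self.cds_end :]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentHit:
    """One aligned block of a hybrid read (coordinates 0-based half-open)."""

    gene_id: str
    read_start: int
    read_end: int
    gene_start: int
    gene_end: int
    score: float

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start or self.gene_end <= self.gene_start:
            raise ValueError("FragmentHit: empty or inverted interval")


@dataclass(frozen=True)
class HybRecordLine:
    """One chimera record of the 15-column hyb-style table."""

    read_id: str
    read_sequence: str
    dg: float
    frag1: FragmentHit
    frag2: FragmentHit


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def parse_fasta(path: str | Path, rna: bool = True) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` tuples, order preserved.

    Sequences are uppercased; T is transliterated to U when ``rna`` (the
    default, since all downstream logic is RNA-only).
    """
    path = Path(path)
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: sequence data before first '>' header")
                break
    with open(path) as handle:
        return [
            (title.split()[0], _normalize(seq, rna))
            for title, seq in SimpleFastaParser(handle)
        ]


def parse_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a 4-line-record FASTQ file into ``(id, sequence, quality)``."""
    records: list[tuple[str, str, str]] = []
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                records.append((title.split()[0], seq.upper(), qual))
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed FASTQ at record {len(records) + 1}: {exc}"
            ) from exc
    return records


_KV = re.compile(r"(\w+)=(\S+)")


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    """Read miRNAs; an ``arm=guide|passenger`` token in the header is honored."""
    mirnas = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0]
            if name in seen:
                raise FormatError(f"{path}: duplicate miRNA id {name}")
            seen.add(name)
            attrs = dict(_KV.findall(title))
            mirnas.append(MiRNA(name, _normalize(seq), attrs.get("arm", "unknown")))
    return mirnas


def read_transcript_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts; ``gene=`` and ``cds_end=`` header tokens are honored."""
    out = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0]
            if name in seen:
                raise FormatError(f"{path}: duplicate transcript id {name}")
            seen.add(name)
            attrs = dict(_KV.findall(title))
            cds_end = int(attrs["cds_end"]) if "cds_end" in attrs else None
            out.append(Transcript(name, attrs.get("gene", name), _normalize(seq), cds_end))
    return out


def write_mirna_fasta(mirnas: Iterable[MiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.id} arm={m.arm}\n{m.sequence}\n")


def write_transcript_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            cds = f" cds_end={t.cds_end}" if t.cds_end is not None else ""
            fh.write(f">{t.id} gene={t.gene}{cds}\n{t.sequence}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` records with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# hyb-style 15-column hybrid table

_HYB_COLUMNS = 15


def write_hyb(records: Iterable[HybRecordLine], path: str | Path) -> None:
    """Serialize records to the tab-separated hyb dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for r in records:
            fields: list[str] = [r.read_id, r.read_sequence, f"{r.dg:.1f}"]
            for f in (r.frag1, r.frag2):
                fields += [
                    f.gene_id,
                    str(f.read_start + 1),
                    str(f.read_end),
                    str(f.gene_start + 1),
                    str(f.gene_end),
                    f"{f.score:g}",
                ]
            fh.write("\t".join(fields) + "\n")


def parse_hyb(path: str | Path) -> list[HybRecordLine]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _HYB_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HYB_COLUMNS} columns, got {len(cols)}"
                )
            try:
                frags = [
                    FragmentHit(
                        gene_id=cols[i],
                        read_start=int(cols[i + 1]) - 1,
                        read_end=int(cols[i + 2]),
                        gene_start=int(cols[i + 3]) - 1,
                        gene_end=int(cols[i + 4]),
                        score=float(cols[i + 5]),
                    )
                    for i in (3, 9)
                ]
                rec = HybRecordLine(cols[0], cols[1], float(cols[2]), *frags)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# TSV count tables


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of integer counts (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id(s) {dups}")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals) or not (vals % 1 == 0).all():
            raise FormatError(f"{path}: non-integer counts in sample {col}")
    return df.astype("int64")


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
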