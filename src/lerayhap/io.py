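"""Thin FASTA/FASTQ/TSV wrappers around Biopython and pandas."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open(path, "r") as fh:
        return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=name.split()[0], description=name) for name, seq in records)
    with _open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) triples."""
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
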