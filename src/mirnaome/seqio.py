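"""Sequence utilities and FASTA/FASTQ I/O helpers.

FASTA is read and written through Biopython; FASTQ reading uses Biopython's
``FastqGeneralIterator`` (the fast title/seq/qual path) because the pipeline
routinely streams millions of records.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples from a FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str, str]], batch: int = 10_000) -> int:
    """Write (id, sequence, quality) records; returns the record count."""
    n = 0
    buf: list[str] = []
    with open(path, "w") as handle:
        for rid, seq, qual in records:
            buf.append(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
            if len(buf) >= batch:
                handle.write("".join(buf))
                buf.clear()
        handle.write("".join(buf))
    return n


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) exact occurrence starts of needle."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
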