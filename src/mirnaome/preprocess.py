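"""Adapter trimming, insert-length selection, and QC summaries.

Small-RNA libraries ligate a known 3' adapter to every insert; with 75 bp
reads and 18-25 nt mature miRNAs the adapter is always sequenced, so reads
in which no adapter occurrence is found are discarded rather than passed
through.  Trimming keeps the insert 5' of the left-most adapter occurrence;
a partial adapter prefix at the read end is accepted from a configurable
minimum overlap with a bounded mismatch rate (N never counts as a match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    trimmed_reads: int = 0
    kept_reads: int = 0
    no_adapter_reads: int = 0
    length_discarded_reads: int = 0
    per_base_mean_quality: list[float] = field(default_factory=list)

    @property
    def min_per_base_quality(self) -> float:
        return min(self.per_base_mean_quality) if self.per_base_mean_quality else 0.0


def _matches(read: str, adapter: str, pos: int, length: int, max_mismatch_rate: float) -> bool:
    """Does adapter[:length] match read[pos:pos+length] within the rate? N never matches."""
    allowed = int(max_mismatch_rate * length)
    mm = 0
    for a, b in zip(read[pos : pos + length], adapter[:length]):
        if a != b or a == "N" or b == "N":
            mm += 1
            if mm > allowed:
                return False
    return True


def find_adapter(sequence: str, adapter: str, min_overlap: int = 8,
                 max_mismatch_rate: float = 0.125) -> int:
    """Left-most adapter start in ``sequence``, or -1.

    A full-length occurrence anywhere is found first (exact, then with the
    allowed mismatch rate); otherwise an adapter *prefix* of at least
    ``min_overlap`` nt ending flush with the read 3' end is accepted under
    the same mismatch rate.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, m = len(sequence), len(adapter)
    exact = sequence.find(adapter)
    candidates = []
    if exact != -1:
        candidates.append(exact)
    # mismatch-tolerant full occurrences left of the exact hit
    limit = exact if exact != -1 else n - m
    for pos in range(0, min(limit, n - m) + 1):
        if _matches(sequence, adapter, pos, m, max_mismatch_rate):
            candidates.append(pos)
            break
    if candidates:
        return min(candidates)
    # partial prefix at the read end
    for pos in range(max(0, n - m + 1), n - min_overlap + 1):
        if _matches(sequence, adapter, pos, n - pos, max_mismatch_rate):
            return pos
    return -1


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 8,
                 max_mismatch_rate: float = 0.125) -> ReadRecord | None:
    """Insert 5' of the left-most adapter occurrence, or None if untrimmable.

    An empty read, or a read with no adapter occurrence, is rejected
    (returns None); an adapter starting at position 0 yields an empty
    insert, which length filtering removes downstream.
    """
    if not read.sequence:
        return None
    pos = find_adapter(read.sequence, adapter, min_overlap, max_mismatch_rate)
    if pos < 0:
        return None
    return ReadRecord(read.id, read.sequence[:pos], read.quality[:pos])


def filter_by_length(reads: Iterable[ReadRecord], min_len: int = 18,
                     max_len: int = 25) -> tuple[list[ReadRecord], int, int]:
    """Keep reads with min_len <= length <= max_len (both inclusive).

    Returns (kept reads, kept count, discarded count).
    """
    kept, discarded = [], 0
    for r in reads:
        if min_len <= len(r.sequence) <= max_len:
            kept.append(r)
        else:
            discarded += 1
    return kept, len(kept), discarded


def qc_summary(reads: Sequence[ReadRecord]) -> PreprocessStats:
    """Per-position mean Phred quality (Phred+33) over a read set."""
    stats = PreprocessStats(raw_reads=len(reads))
    if not reads:
        return stats
    maxlen = max(len(r.quality) for r in reads)
    totals = np.zeros(maxlen)
    counts = np.zeros(maxlen, dtype=int)
    for r in reads:
        q = np.frombuffer(r.quality.encode(), dtype=np.uint8) - 33
        totals[: len(q)] += q
        counts[: len(q)] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
    stats.per_base_mean_quality = [float(x) for x in means]
    return stats


def _trim_positions_block(arr: np.ndarray, adapter: str, min_overlap: int,
                          max_mismatch_rate: float) -> np.ndarray:
    """Vectorized left-most adapter start for an (N, L) byte matrix; -1 if none.

    Scans ascending start positions so the left-most qualifying occurrence
    (full-length, then a >=min_overlap prefix flush with the read end) wins,
    matching :func:`find_adapter` exactly for equal-length reads.
    """
    n_reads, read_len = arr.shape
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    m = len(ad)
    pos = np.full(n_reads, -1, dtype=np.int64)
    unset = np.ones(n_reads, dtype=bool)
    full_allowed = int(max_mismatch_rate * m)
    for s in range(0, read_len - m + 1):
        if not unset.any():
            return pos
        mm = (arr[:, s : s + m] != ad).sum(axis=1)
        hit = unset & (mm <= full_allowed)
        pos[hit] = s
        unset &= ~hit
    for s in range(max(0, read_len - m + 1), read_len - min_overlap + 1):
        if not unset.any():
            break
        length = read_len - s
        allowed = int(max_mismatch_rate * length)
        mm = (arr[:, s:] != ad[:length]).sum(axis=1)
        hit = unset & (mm <= allowed)
        pos[hit] = s
        unset &= ~hit
    return pos


def preprocess_fastq(path, adapter: str, min_len: int = 18, max_len: int = 25,
                     min_overlap: int = 8, max_mismatch_rate: float = 0.125,
                     block: int = 200_000):
    """Stream a FASTQ library through trimming and length selection.

    Memory-light variant for full libraries: identical inserts are collapsed
    into a ``Counter`` (sequence -> read count), which is what discovery and
    quantification consume.  Reads of equal length are processed in
    vectorized blocks; odd-length reads fall back to the scalar trimmer.

    Returns (insert Counter, PreprocessStats).
    """
    from collections import Counter

    from mirnaome.seqio import read_fastq

    stats = PreprocessStats()
    inserts: Counter[str] = Counter()
    qual_tot = np.zeros(max_len)
    qual_cnt = np.zeros(max_len, dtype=np.int64)

    seqs: list[str] = []
    quals: list[str] = []

    def flush() -> None:
        if not seqs:
            return
        read_len = len(seqs[0])
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), read_len)
        pos = _trim_positions_block(arr, adapter, min_overlap, max_mismatch_rate)
        stats.no_adapter_reads += int((pos < 0).sum())
        stats.trimmed_reads += int((pos >= 0).sum())
        keep = (pos >= min_len) & (pos <= max_len)
        stats.length_discarded_reads += int(((pos >= 0) & ~keep).sum())
        for idx in np.nonzero(keep)[0]:
            p = int(pos[idx])
            inserts[seqs[idx][:p]] += 1
            q = np.frombuffer(quals[idx][:p].encode(), dtype=np.uint8) - 33
            qual_tot[: p] += q
            qual_cnt[: p] += 1
        stats.kept_reads += int(keep.sum())
        seqs.clear()
        quals.clear()

    for _, seq, qual in read_fastq(path):
        stats.raw_reads += 1
        if seqs and len(seq) != len(seqs[0]):
            flush()
        seqs.append(seq)
        quals.append(qual)
        if len(seqs) >= block:
            flush()
    flush()
    means = np.where(qual_cnt > 0, qual_tot / np.maximum(qual_cnt, 1), 0.0)
    stats.per_base_mean_quality = [float(x) for x in means]
    return inserts, stats


def preprocess_reads(records: Iterable[tuple[str, str, str]], adapter: str,
                     min_len: int = 18, max_len: int = 25, min_overlap: int = 8,
                     max_mismatch_rate: float = 0.125) -> tuple[list[ReadRecord], PreprocessStats]:
    """Full per-library pass: trim every read once, then length-filter.

    The count identity raw = no_adapter + length_discarded + kept holds.
    """
    stats = PreprocessStats()
    trimmed: list[ReadRecord] = []
    for rid, seq, qual in records:
        stats.raw_reads += 1
        rec = trim_adapter(ReadRecord(rid, seq, qual), adapter, min_overlap, max_mismatch_rate)
        if rec is None:
            stats.no_adapter_reads += 1
        else:
            trimmed.append(rec)
    stats.trimmed_reads = len(trimmed)
    kept, _, discarded = filter_by_length(trimmed, min_len, max_len)
    stats.length_discarded_reads = discarded
    stats.kept_reads = len(kept)
    stats.per_base_mean_quality = qc_summary(kept).per_base_mean_quality
    return kept, stats
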