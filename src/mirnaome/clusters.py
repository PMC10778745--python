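"""Genomic miRNA cluster detection.

Clusters follow the miRBase definition: two or more miRNA genes no more
than 10 kb apart (inclusive), transcribed in the same orientation, and not
separated by a transcription unit in the opposite orientation.  The gap is
measured between precursor bounding intervals (end of the upstream gene to
start of the downstream gene); without a transcription-unit annotation the
third condition passes vacuously.  Detection is single-linkage chaining
along each contig/strand, so cluster membership is a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

from mirnaome.annotation import AnnotatedGene, split_family


@dataclass
class TranscriptionUnit:
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class ClusterRecord:
    cluster_id: str
    members: list[str]          # gene names, sorted by position
    contig: str
    strand: str
    start: int
    end: int
    cluster_type: str = ""      # "homo" | "hetero"


def _separated_by_opposite_unit(a: AnnotatedGene, b: AnnotatedGene,
                                units: list[TranscriptionUnit]) -> bool:
    """True iff an opposite-strand unit lies wholly between a and b."""
    lo, hi = a.end, b.start
    for u in units:
        if (u.contig == a.contig and u.strand != a.strand
                and u.start >= lo and u.end <= hi):
            return True
    return False


def detect_clusters(genes: list[AnnotatedGene], max_gap: int = 10_000,
                    transcription_units: list[TranscriptionUnit] | None = None
                    ) -> list[ClusterRecord]:
    """Chain same-strand neighbours with gap <= max_gap into clusters.

    Singletons are not clusters.  Identical duplicated genes at different
    loci are independent members at each locus.
    """
    units = transcription_units or []
    by_key: dict[tuple[str, str], list[AnnotatedGene]] = {}
    for g in genes:
        by_key.setdefault((g.contig, g.strand), []).append(g)

    records: list[ClusterRecord] = []
    for (contig, strand), members in sorted(by_key.items()):
        members.sort(key=lambda g: (g.start, g.end, g.name))
        chain: list[AnnotatedGene] = []
        for g in members:
            if chain and (g.start - chain[-1].end <= max_gap
                          and not _separated_by_opposite_unit(chain[-1], g, units)):
                chain.append(g)
            else:
                if len(chain) >= 2:
                    records.append(_make_record(chain))
                chain = [g]
        if len(chain) >= 2:
            records.append(_make_record(chain))
    for i, r in enumerate(records, start=1):
        r.cluster_id = f"cluster_{i}"
        classify_cluster_type(r, genes)
    return records


def _make_record(chain: list[AnnotatedGene]) -> ClusterRecord:
    return ClusterRecord(
        cluster_id="", members=[g.name for g in chain],
        contig=chain[0].contig, strand=chain[0].strand,
        start=min(g.start for g in chain), end=max(g.end for g in chain))


def classify_cluster_type(cluster: ClusterRecord, genes: list[AnnotatedGene]) -> str:
    """"homo" iff all members share one family number, else "hetero".

    Letter variants (430a/430b/430c) belong to one family, so a cluster of
    them is a homo-cluster.
    """
    by_name = {g.name: g for g in genes}
    numbers = {split_family(by_name[m].family)[0] for m in cluster.members}
    cluster.cluster_type = "homo" if len(numbers) == 1 else "hetero"
    return cluster.cluster_type
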