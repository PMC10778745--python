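"""Conserved/novel classification, decoy screening, and miRBase-style naming.

Candidates that survive curation are aligned against a reference hairpin
database (miRBase-like) with an affine-gap Smith-Waterman and Karlin-Altschul
E-values; a significant hit (E <= 1e-5) makes the candidate a conserved
orthologue inheriting the hit's family.  Putative novel candidates are
screened against an other-ncRNA decoy database (discard reason "ncRNA") and
against the genome itself: significant alignment at more than five distinct
loci marks a repetitive element (discard reason "repetitive").

Nomenclature follows miRBase conventions: species prefix + family, numeric
copy suffixes (-1, -2, ...) for multiple genes of one family ordered by
genomic position, letter suffixes (a, b) for identical duplicated novel
precursors, and merged mature names when several gene copies share one
mature sequence (e.g. -21-1-2-5p, -7ab-5p).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio import Align

from mirnaome.seqio import find_all, revcomp


@dataclass
class AlignmentHit:
    query: str
    subject: str
    score: float
    evalue: float


@dataclass
class AnnotatedGene:
    name: str
    status: str                 # "conserved" | "novel"
    family: str                 # e.g. "21", "430a", "nov2"
    contig: str
    start: int
    end: int
    strand: str
    precursor: str
    mature5p: str
    mature3p: str
    copy_suffix: int | None = None
    letter_tag: str = ""        # duplicated-novel letter (a, b, ...)
    candidate: object = None


@dataclass
class UniqueMature:
    sequence: str
    arm: str                    # "5p" | "3p"
    name: str
    parent_genes: list[str] = field(default_factory=list)
    dominance: str = ""         # "guide" | "passenger" | "co-dominant" | "undetected"


def make_aligner(match: int = 5, mismatch: int = -4, gap_open: int = -8,
                 gap_extend: int = -2) -> Align.PairwiseAligner:
    """Local aligner with megablast-like scoring (affine gaps).

    ``gap_open`` is the score of the first gapped position, ``gap_extend``
    of each further one.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def fit_karlin_altschul(database: dict[str, str],
                        aligner: Align.PairwiseAligner | None = None,
                        query_length: int = 70, n_queries: int = 40,
                        seed: int = 0, both_strands: bool = True
                        ) -> tuple[float, float]:
    """Fit (lambda, K) from a random-query null against this database.

    Random queries are scored against the whole database (max over entries,
    optionally both strands) and the resulting extreme-value distribution
    is fit by moments: lambda = pi / (sd * sqrt(6)), location
    u = mean - gamma/lambda, K = exp(lambda * u) / (m * n).  The fixed
    textbook constants are not reliable for this +5/-4 affine scheme on
    small databases, so searches should use a per-database fit.

    For very large subjects, calibrate on sampled windows: the K returned
    rescales exactly with the search-space size used at query time.
    """
    import numpy as np

    aligner = aligner or make_aligner()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    scores = []
    for _ in range(n_queries):
        q = bases[rng.integers(0, 4, query_length)].tobytes().decode()
        best = 0.0
        for subject in database.values():
            s = aligner.score(q, subject)
            if both_strands:
                s = max(s, aligner.score(revcomp(q), subject))
            best = max(best, s)
        scores.append(best)
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null score distribution")
    lam = math.pi / (sd * math.sqrt(6.0))
    u = mean - 0.5772156649 / lam
    n_total = sum(len(s) for s in database.values())
    k = math.exp(lam * u) / (query_length * n_total)
    return lam, k


def local_align_evalue(query: str, database: dict[str, str],
                       aligner: Align.PairwiseAligner | None = None,
                       ka_lambda: float = 0.27, ka_k: float = 0.28,
                       both_strands: bool = True) -> list[AlignmentHit]:
    """Smith-Waterman score and Karlin-Altschul E-value per database entry.

    E = K * m * n * exp(-lambda * S) with m the query length and n the total
    database length (database-size correction).  Hits sorted by ascending
    E-value, then name.  The fixed (K, lambda) defaults are calibrated for
    the +5/-4 scoring scheme; a shuffled-null fit can replace them by
    passing different constants.
    """
    if not query:
        raise ValueError("empty query")
    if not database:
        raise ValueError("empty database")
    aligner = aligner or make_aligner()
    m = len(query)
    n_total = sum(len(s) for s in database.values())
    hits = []
    for name, subject in database.items():
        score = aligner.score(query, subject)
        if both_strands:
            score = max(score, aligner.score(revcomp(query), subject))
        evalue = ka_k * m * n_total * math.exp(-ka_lambda * score)
        hits.append(AlignmentHit(query=query, subject=name, score=float(score),
                                 evalue=evalue))
    hits.sort(key=lambda h: (h.evalue, h.subject))
    return hits


_NAME_RE = re.compile(r"^[a-z]{3}-(mir|let)-(\w+?)$", re.IGNORECASE)


def parse_family(reference_name: str) -> str:
    """Family label from a miRBase-style hairpin name (dre-mir-430a -> 430a)."""
    m = _NAME_RE.match(reference_name)
    if not m:
        raise ValueError(f"unparseable reference name: {reference_name}")
    return m.group(2)


def split_family(family: str) -> tuple[str, str]:
    """Split a family label into (number, letters): 7a -> (7, a); nov2 -> (nov2, )."""
    m = re.match(r"^(\d+)([a-z]*)$", family)
    if m:
        return m.group(1), m.group(2)
    return family, ""


def classify_conservation(precursor: str, reference_db: dict[str, str],
                          evalue_threshold: float = 1e-5,
                          aligner: Align.PairwiseAligner | None = None,
                          ka_lambda: float = 0.27, ka_k: float = 0.28
                          ) -> tuple[str, str | None]:
    """("conserved", family) if the best hit is significant, else ("novel", None).

    Equally scoring hits are broken toward the lower family number, then
    lexicographic letter.
    """
    hits = local_align_evalue(precursor, reference_db, aligner, ka_lambda, ka_k)
    significant = [h for h in hits if h.evalue <= evalue_threshold]
    if not significant:
        return "novel", None
    best_e = significant[0].evalue

    def sort_key(h):
        fam = parse_family(h.subject)
        num, letters = split_family(fam)
        return (0, int(num), letters) if num.isdigit() else (1, 0, fam)

    top = sorted((h for h in significant if h.evalue == best_e), key=sort_key)[0]
    return "conserved", parse_family(top.subject)


def count_genomic_loci(query: str, genome: dict[str, str], seed_size: int = 16,
                       seed_step: int = 4, evalue_threshold: float = 1e-5,
                       aligner: Align.PairwiseAligner | None = None,
                       ka_lambda: float = 0.27, ka_k: float = 0.28) -> int:
    """Distinct genomic loci where the query aligns significantly.

    BLAST-like two-step search: exact seed hits (both strands) are clustered
    into loci, each locus is re-scored by local alignment against a window
    around it, and loci with E <= threshold (E-value space n = genome size)
    are counted.
    """
    aligner = aligner or make_aligner()
    n_total = sum(len(s) for s in genome.values())
    m = len(query)
    seeds = [query[i:i + seed_size] for i in range(0, max(1, m - seed_size + 1), seed_step)]
    raw_hits: set[tuple[str, str, int]] = set()
    for contig, cseq in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for s_idx in range(len(seeds)):
                seed = seeds[s_idx] if strand == "+" else revcomp(seeds[s_idx])
                for pos in find_all(cseq, seed):
                    raw_hits.add((contig, strand, pos))
    # cluster seed hits into loci
    loci: list[tuple[str, str, int, int]] = []
    for contig, strand, pos in sorted(raw_hits):
        if loci and loci[-1][0] == contig and loci[-1][1] == strand and pos - loci[-1][3] <= 100:
            loci[-1] = (contig, strand, loci[-1][2], pos)
        else:
            loci.append((contig, strand, pos, pos))
    n_significant = 0
    for contig, strand, lo, hi in loci:
        window = genome[contig][max(0, lo - m): hi + seed_size + m]
        if strand == "-":
            window = revcomp(window)
        score = aligner.score(query, window)
        evalue = ka_k * m * n_total * math.exp(-ka_lambda * score)
        if evalue <= evalue_threshold:
            n_significant += 1
    return n_significant


def screen_novel(precursor: str, ncrna_db: dict[str, str], genome: dict[str, str],
                 evalue_threshold: float = 1e-5, repetitive_locus_cutoff: int = 5,
                 aligner: Align.PairwiseAligner | None = None,
                 ka_ncrna: tuple[float, float] = (0.27, 0.28),
                 ka_genome: tuple[float, float] = (0.27, 0.28)) -> tuple[bool, str]:
    """(keep, reason) for a putative novel precursor.

    Discards with reason "ncRNA" on a significant decoy-database hit, with
    reason "repetitive" on significant genome alignment at more than
    ``repetitive_locus_cutoff`` distinct loci; otherwise keeps ("novel").
    ``ka_ncrna``/``ka_genome`` are (lambda, K) pairs, ideally from
    :func:`fit_karlin_altschul` for the respective search space.
    """
    if ncrna_db:
        hits = local_align_evalue(precursor, ncrna_db, aligner, *ka_ncrna)
        if hits and hits[0].evalue <= evalue_threshold:
            return False, "ncRNA"
    n_loci = count_genomic_loci(precursor, genome, evalue_threshold=evalue_threshold,
                                aligner=aligner, ka_lambda=ka_genome[0], ka_k=ka_genome[1])
    if n_loci > repetitive_locus_cutoff:
        return False, "repetitive"
    return True, "novel"


def assign_gene_names(drafts: list[dict], species_prefix: str = "slu") -> list[AnnotatedGene]:
    """Name a set of classified gene drafts.

    Each draft dict needs: status, family (None for novel), contig, start,
    end, strand, precursor, mature5p, mature3p (and optionally candidate).
    Conserved families with several loci get numeric copy suffixes by
    genomic position; novel genes are numbered in discovery order
    (position), identical duplicated novel precursors sharing one number
    with letter tags.
    """
    genes: list[AnnotatedGene] = []

    conserved = [d for d in drafts if d["status"] == "conserved"]
    by_family: dict[str, list[dict]] = {}
    for d in conserved:
        by_family.setdefault(d["family"], []).append(d)
    for family in sorted(by_family):
        members = sorted(by_family[family], key=lambda d: (d["contig"], d["start"]))
        for i, d in enumerate(members):
            suffix = f"-{i + 1}" if len(members) > 1 else ""
            genes.append(AnnotatedGene(
                name=f"{species_prefix}-mir-{family}{suffix}",
                status="conserved", family=family,
                contig=d["contig"], start=d["start"], end=d["end"], strand=d["strand"],
                precursor=d["precursor"], mature5p=d["mature5p"], mature3p=d["mature3p"],
                copy_suffix=(i + 1) if len(members) > 1 else None,
                candidate=d.get("candidate")))

    novel = [d for d in drafts if d["status"] == "novel"]
    by_seq: dict[str, list[dict]] = {}
    for d in novel:
        by_seq.setdefault(d["precursor"], []).append(d)
    ordered = sorted(by_seq.values(), key=lambda ds: min((d["contig"], d["start"]) for d in ds))
    for k, ds in enumerate(ordered, start=1):
        ds = sorted(ds, key=lambda d: (d["contig"], d["start"]))
        for i, d in enumerate(ds):
            letter = "abcdefgh"[i] if len(ds) > 1 else ""
            genes.append(AnnotatedGene(
                name=f"{species_prefix}-mir-nov{k}{letter}",
                status="novel", family=f"nov{k}",
                contig=d["contig"], start=d["start"], end=d["end"], strand=d["strand"],
                precursor=d["precursor"], mature5p=d["mature5p"], mature3p=d["mature3p"],
                letter_tag=letter, candidate=d.get("candidate")))

    names = [g.name for g in genes]
    if len(names) != len(set(names)):
        raise ValueError("gene name collision after suffixing")
    return genes


def _merged_name(parents: list[AnnotatedGene], arm: str, prefix: str) -> str:
    numbers = {split_family(p.family)[0] for p in parents}
    if len(numbers) == 1:
        number = numbers.pop()
        letters = sorted({split_family(p.family)[1] + p.letter_tag for p in parents})
        letters = [x for x in letters if x]
        copies = sorted(p.copy_suffix for p in parents if p.copy_suffix is not None)
        name = f"{prefix}-mir-{number}{''.join(letters)}"
        if copies:
            name += "".join(f"-{c}" for c in copies)
        return f"{name}-{arm}"
    return "/".join(sorted(p.name for p in parents)) + f"-{arm}"


def merge_matures(genes: list[AnnotatedGene], species_prefix: str = "slu") -> list[UniqueMature]:
    """Deduplicate matures by (sequence, arm), merging names across copies.

    Idempotent and order-independent: output is sorted by merged name.
    """
    groups: dict[tuple[str, str], list[AnnotatedGene]] = {}
    for g in genes:
        for arm, seq in (("5p", g.mature5p), ("3p", g.mature3p)):
            groups.setdefault((seq, arm), []).append(g)
    out = []
    for (seq, arm), parents in groups.items():
        parents = sorted(parents, key=lambda p: p.name)
        out.append(UniqueMature(
            sequence=seq, arm=arm,
            name=_merged_name(parents, arm, species_prefix),
            parent_genes=[p.name for p in parents]))
    out.sort(key=lambda u: (u.name, u.arm))
    names = [u.name for u in out]
    if len(names) != len(set(names)):
        raise ValueError("unique-mature name collision")
    return out


def arm_dominance(count5p: float, count3p: float, ratio: float = 10.0,
                  min_major: float = 10.0) -> dict[str, str]:
    """Guide/passenger labels for the two arms of one gene.

    The minor arm is a passenger iff major/minor >= ratio (a zero-count
    minor arm is passenger once the major reaches ``min_major`` reads);
    otherwise both arms are co-dominant.  Both zero -> undetected.
    """
    if count5p == 0 and count3p == 0:
        return {"5p": "undetected", "3p": "undetected"}
    major_arm = "5p" if count5p >= count3p else "3p"
    minor_arm = "3p" if major_arm == "5p" else "5p"
    major = max(count5p, count3p)
    minor = min(count5p, count3p)
    if minor == 0:
        if major >= min_major:
            return {major_arm: "guide", minor_arm: "passenger"}
        return {major_arm: "co-dominant", minor_arm: "co-dominant"}
    if major / minor >= ratio:
        return {major_arm: "guide", minor_arm: "passenger"}
    return {"5p": "co-dominant", "3p": "co-dominant"}
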