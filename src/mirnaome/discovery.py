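"""Candidate miRNA discovery: exact mapping, read stacks, excision, curation.

The discovery strategy mirrors the classic excision approach at desk scale:
collapsed reads are exact-matched to both genome strands, overlapping
same-strand alignments form read stacks, each stack is excised with a
genomic flank as a putative 5p arm or 3p arm of a hairpin, the better-pairing
window is folded, and the resulting precursor candidate is judged against
five curation criteria:

1. detected (>=1 mismatch-free read on either arm) in >=2 libraries;
2. >=10 mismatch-free reads on the 5p arm AND on the 3p arm, summed over
   libraries;
3. each mature leaves a 0-4 nt 3' overhang relative to the pairing with the
   opposing arm (the Drosha/Dicer signature);
4. 5' homogeneity: the modal 5' start carries more than half of each arm's
   reads;
5. more than 60% of each mature's bases pair with the opposing arm in the
   hairpin (strictly greater).

Reads whose sequence occurs at more than ``max_read_loci`` genomic loci are
flagged multi-locus and never seed candidates (repetitive elements).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from mirnaome.folding import HairpinFold, can_pair, fold_hairpin
from mirnaome.seqio import find_all, revcomp


@dataclass
class Alignment:
    """One exact alignment of a collapsed read; multiplicity is per sample."""

    read: str
    sample: str
    multiplicity: int
    contig: str
    start: int
    strand: str
    mismatches: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.read)


@dataclass
class ReadStack:
    contig: str
    strand: str
    alignments: list[Alignment]

    @property
    def start(self) -> int:
        return min(a.start for a in self.alignments)

    @property
    def end(self) -> int:
        return max(a.end for a in self.alignments)

    @property
    def total_reads(self) -> int:
        return sum(a.multiplicity for a in self.alignments)


@dataclass
class Arm:
    """One arm of a candidate: modal read sequence and its read support."""

    sequence: str
    window_start: int                      # 0-based, window (transcript) coords
    counts_per_sample: dict[str, int] = field(default_factory=dict)
    modal_fraction: float = 0.0
    predicted: bool = False                # star arm inferred from the fold

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.sequence)

    @property
    def total_reads(self) -> int:
        return sum(self.counts_per_sample.values())


@dataclass
class PrecursorCandidate:
    contig: str
    start: int          # genomic, 0-based half-open, precursor extent
    end: int
    strand: str
    sequence: str       # precursor, transcript sense
    fold: HairpinFold
    arm5p: Arm
    arm3p: Arm
    window_start: int   # genomic start of the folded window
    window_sequence: str
    criterion_flags: dict[str, bool] = field(default_factory=dict)
    passes: bool = False
    overhangs: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return self.arm5p.total_reads + self.arm3p.total_reads


class GenomeIndex:
    """Exact-match index: every k-mer start position, for seed-and-verify lookup."""

    def __init__(self, genome: dict[str, str], k: int = 18):
        self.genome = genome
        self.k = k
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.kmers[seq[i:i + k]].append((contig, i))

    def find(self, seq: str) -> list[tuple[str, int]]:
        """All exact forward-strand occurrence loci of ``seq``."""
        if len(seq) < self.k:
            return [(c, p) for c, s in self.genome.items() for p in find_all(s, seq)]
        hits = []
        for contig, pos in self.kmers.get(seq[: self.k], ()):
            if self.genome[contig].startswith(seq, pos):
                hits.append((contig, pos))
        return hits


def map_reads(reads_by_sample: dict[str, Counter | dict], genome: dict[str, str],
              max_read_loci: int = 5, index: GenomeIndex | None = None
              ) -> tuple[list[Alignment], dict[str, int], int]:
    """Exact-match collapsed reads to both genome strands.

    ``reads_by_sample`` maps sample -> {read sequence: count}.  Returns
    (alignments, multi-locus read sequences with locus counts, number of
    unmapped collapsed sequences).  A read on the minus strand is recorded
    at the genomic interval its reverse complement matches.
    """
    index = index or GenomeIndex(genome)
    all_seqs = sorted({s for reads in reads_by_sample.values() for s in reads})

    alignments: list[Alignment] = []
    multi_locus: dict[str, int] = {}
    unmapped = 0
    for seq in all_seqs:
        loci = [(c, p, "+") for c, p in index.find(seq)]
        loci += [(c, p, "-") for c, p in index.find(revcomp(seq))]
        if not loci:
            unmapped += 1
            continue
        if len(loci) > max_read_loci:
            multi_locus[seq] = len(loci)
            continue
        for sample, reads in reads_by_sample.items():
            mult = reads.get(seq, 0)
            if mult == 0:
                continue
            for contig, pos, strand in loci:
                alignments.append(Alignment(seq, sample, mult, contig, pos, strand))
    return alignments, multi_locus, unmapped


def build_read_stacks(alignments: list[Alignment], min_stack_reads: int = 5,
                      stack_gap: int = 25) -> list[ReadStack]:
    """Chain same-strand alignments whose starts differ by <= stack_gap."""
    by_key: dict[tuple[str, str], list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_key[(a.contig, a.strand)].append(a)
    stacks: list[ReadStack] = []
    for (contig, strand), alns in sorted(by_key.items()):
        alns.sort(key=lambda a: (a.start, a.read, a.sample))
        current: list[Alignment] = []
        last_start = None
        for a in alns:
            if last_start is not None and a.start - last_start > stack_gap:
                stacks.append(ReadStack(contig, strand, current))
                current = []
            current.append(a)
            last_start = a.start
        if current:
            stacks.append(ReadStack(contig, strand, current))
    return [s for s in stacks if s.total_reads >= min_stack_reads]


def _to_window_coords(aln: Alignment, win_start: int, win_len: int, strand: str) -> int:
    """Transcript-sense start of an alignment inside a window, or -1."""
    g0, g1 = aln.start - win_start, aln.end - win_start
    if g0 < 0 or g1 > win_len:
        return -1
    if strand == "+":
        return g0
    return win_len - g1


def _group_arms(alignments: list[Alignment], win_start: int, win_len: int,
                strand: str, gap: int = 15) -> list[list[tuple[int, Alignment]]]:
    """Cluster in-window alignments into arm groups by 5' start adjacency."""
    positioned = []
    for a in alignments:
        w = _to_window_coords(a, win_start, win_len, strand)
        if w >= 0:
            positioned.append((w, a))
    positioned.sort(key=lambda t: (t[0], t[1].read, t[1].sample))
    groups: list[list[tuple[int, Alignment]]] = []
    for w, a in positioned:
        if groups and w - groups[-1][-1][0] <= gap:
            groups[-1].append((w, a))
        else:
            groups.append([(w, a)])
    return groups


def _modal_arm(group: list[tuple[int, Alignment]]) -> Arm:
    seq_counts: Counter = Counter()
    start_counts: Counter = Counter()
    per_sample: dict[str, int] = defaultdict(int)
    pos_of_seq: dict[str, int] = {}
    for w, a in group:
        seq_counts[a.read] += a.multiplicity
        start_counts[w] += a.multiplicity
        per_sample[a.sample] += a.multiplicity
        pos_of_seq[a.read] = w
    modal_seq = min(seq_counts, key=lambda s: (-seq_counts[s], s))
    total = sum(start_counts.values())
    modal_fraction = max(start_counts.values()) / total if total else 0.0
    return Arm(sequence=modal_seq, window_start=pos_of_seq[modal_seq],
               counts_per_sample=dict(per_sample), modal_fraction=modal_fraction)


def five_prime_homogeneity(start_counts: dict[int, int],
                           threshold: float = 0.5) -> tuple[float, bool]:
    """Modal 5'-start fraction of an arm's reads; pass iff strictly > threshold."""
    total = sum(start_counts.values())
    if total == 0:
        return 0.0, False
    frac = max(start_counts.values()) / total
    return frac, frac > threshold


def _predicted_star(fold: HairpinFold, arm: Arm, win_len: int) -> Arm | None:
    """Infer the opposing arm from the pairing partners of a read-defined arm."""
    partners = [fold.partner[i] for i in range(arm.window_start, arm.window_end)
                if 0 <= i < win_len and fold.partner[i] >= 0]
    if len(partners) < 10:
        return None
    lo, hi = min(partners), max(partners) + 1
    # 2 nt 3' overhang, clipped to the window
    hi = min(hi + 2, win_len)
    return Arm(sequence="", window_start=lo, predicted=True), lo, hi


def excise_and_fold(stack: ReadStack, genome: dict[str, str],
                    all_alignments: list[Alignment], flank: int = 70
                    ) -> PrecursorCandidate | None:
    """Excise the two flanked windows around a stack, keep the better fold.

    The stack is treated as either the 5' arm (window extends 3' of it) or
    the 3' arm (window extends 5' of it); the window whose fold pairs more
    stack bases across the loop is retained, ties keep the 5'-proximal
    (left) window.  Arms are the modal read sequences of the two largest
    read groups in the retained window; with a single read group the star
    arm is inferred from the fold (and carries zero read support).
    """
    contig_seq = genome[stack.contig]
    clen = len(contig_seq)
    if stack.strand == "+":
        windows = [(stack.start, min(stack.end + flank, clen)),
                   (max(stack.start - flank, 0), stack.end)]
    else:  # transcript 5' is at higher genomic coordinate
        windows = [(max(stack.start - flank, 0), stack.end),
                   (stack.start, min(stack.end + flank, clen))]

    best = None
    for w_idx, (g0, g1) in enumerate(windows):
        if g1 - g0 < 10:
            continue
        wseq = contig_seq[g0:g1]
        if stack.strand == "-":
            wseq = revcomp(wseq)
        fold = fold_hairpin(wseq)
        # score: stack bases paired with partners outside the stack region
        lo = min((w for w in (_to_window_coords(a, g0, g1 - g0, stack.strand)
                              for a in stack.alignments) if w >= 0), default=-1)
        if lo < 0:
            continue
        hi = min(lo + (stack.end - stack.start), g1 - g0)
        score = sum(1 for i in range(lo, hi)
                    if fold.partner[i] >= 0 and not (lo <= fold.partner[i] < hi))
        if best is None or score > best[0]:
            best = (score, g0, g1, wseq, fold)
    if best is None:
        return None
    _, g0, g1, wseq, fold = best
    win_len = g1 - g0

    in_window = [a for a in all_alignments
                 if a.contig == stack.contig and a.strand == stack.strand
                 and a.start >= g0 and a.end <= g1]
    groups = _group_arms(in_window, g0, win_len, stack.strand)
    groups.sort(key=lambda g: -sum(a.multiplicity for _, a in g))
    arms: list[Arm] = [_modal_arm(g) for g in groups[:2]]
    if len(arms) == 1:
        star = _predicted_star(fold, arms[0], win_len)
        if star is None:
            return None
        star_arm, lo, hi = star
        star_arm.sequence = wseq[lo:hi]
        arms.append(star_arm)
    arms.sort(key=lambda a: a.window_start)
    arm5p, arm3p = arms[0], arms[1]

    p0, p1 = arm5p.window_start, arm3p.window_end
    if p1 - p0 < 10 or p1 - p0 > 200:
        return None
    # re-fold the trimmed precursor: criteria judge the hairpin itself, not
    # the excision window (whose flanks offer spurious pairing partners)
    pre_seq = wseq[p0:p1]
    pre_fold = fold_hairpin(pre_seq)
    arm5p.window_start -= p0
    arm3p.window_start -= p0
    if stack.strand == "+":
        g_start, g_end = g0 + p0, g0 + p1
    else:
        g_start, g_end = g0 + (win_len - p1), g0 + (win_len - p0)
    return PrecursorCandidate(
        contig=stack.contig, start=g_start, end=g_end, strand=stack.strand,
        sequence=pre_seq, fold=pre_fold, arm5p=arm5p, arm3p=arm3p,
        window_start=g0, window_sequence=wseq,
    )


@dataclass
class DuplexRegister:
    """Best gapless pairing register between the 5p and 3p arm sequences.

    The Drosha/Dicer product is an (approximately) contiguous RNA duplex;
    scoring the arms at their single best ungapped offset measures exactly
    that duplex and, unlike bulge-tolerant matchings, does not credit the
    diffuse complementarity two random sequences always share.

    ``pair5[i]`` is True when base i of the 5p arm is paired (complementary,
    G:U allowed) with its in-register 3p partner; likewise ``pair3``.
    """

    offset: int
    pair5: list[bool]
    pair3: list[bool]
    n_pairs: int

    def overhang(self, arm: str) -> int:
        """Unpaired 3'-terminal run of the arm; large sentinel if no pairing."""
        flags = self.pair5 if arm == "5p" else self.pair3
        for k, paired in enumerate(reversed(flags)):
            if paired:
                return k
        return 10_000

    def paired_fraction(self, arm: str) -> float:
        flags = self.pair5 if arm == "5p" else self.pair3
        return sum(flags) / len(flags) if flags else 0.0


def duplex_register(seq5: str, seq3: str, max_offset: int = 6) -> DuplexRegister:
    """Best ungapped duplex register of a 5p/3p arm pair.

    In a hairpin duplex base i of the 5p arm faces base L3-1-(i+o) of the
    3p arm; the register o with the most complementary (Watson-Crick or
    G:U) pairs wins, ties going to the smallest |o| (negative before
    positive).
    """
    n5, n3 = len(seq5), len(seq3)
    best_offset = 0
    best_pairs = -1
    for o in sorted(range(-max_offset, max_offset + 1), key=lambda o: (abs(o), o)):
        pairs = 0
        for i in range(n5):
            j = n3 - 1 - (i + o)
            if 0 <= j < n3 and can_pair(seq5[i], seq3[j]):
                pairs += 1
        if pairs > best_pairs:
            best_pairs = pairs
            best_offset = o
    o = best_offset
    pair5 = [False] * n5
    pair3 = [False] * n3
    for i in range(n5):
        j = n3 - 1 - (i + o)
        if 0 <= j < n3 and can_pair(seq5[i], seq3[j]):
            pair5[i] = True
            pair3[j] = True
    return DuplexRegister(offset=o, pair5=pair5, pair3=pair3, n_pairs=best_pairs)


def evaluate_criteria(candidate: PrecursorCandidate, min_samples: int = 2,
                      min_arm_reads: int = 10, overhang_min: int = 0,
                      overhang_max: int = 4, homogeneity_threshold: float = 0.5,
                      pairing_threshold: float = 0.60) -> dict[str, bool]:
    """Apply the five curation criteria; sets flags and the overall verdict."""
    a5, a3 = candidate.arm5p, candidate.arm3p

    samples = {s for arm in (a5, a3) for s, c in arm.counts_per_sample.items() if c > 0}
    c1 = len(samples) >= min_samples

    c2 = a5.total_reads >= min_arm_reads and a3.total_reads >= min_arm_reads

    register = duplex_register(a5.sequence, a3.sequence)
    oh5 = register.overhang("5p")
    oh3 = register.overhang("3p")
    candidate.overhangs = {"5p": oh5, "3p": oh3}
    c3 = (overhang_min <= oh5 <= overhang_max) and (overhang_min <= oh3 <= overhang_max)

    c4 = all(arm.predicted or arm.total_reads == 0
             or arm.modal_fraction > homogeneity_threshold
             for arm in (a5, a3))

    c5 = (register.paired_fraction("5p") > pairing_threshold
          and register.paired_fraction("3p") > pairing_threshold)

    flags = {"c1_samples": c1, "c2_reads": c2, "c3_overhang": c3,
             "c4_homogeneity": c4, "c5_pairing": c5}
    candidate.criterion_flags = flags
    candidate.passes = all(flags.values())
    return flags


def deduplicate_candidates(candidates: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Merge candidates whose precursor intervals overlap on one strand.

    The 5p-seeded and 3p-seeded stacks of one gene excise near-identical
    windows; keep the candidate with the most read support (ties: leftmost).
    """
    out: list[PrecursorCandidate] = []
    for c in sorted(candidates, key=lambda c: (c.contig, c.strand, c.start, -c.total_reads)):
        merged = False
        for i, kept in enumerate(out):
            if (kept.contig == c.contig and kept.strand == c.strand
                    and c.start < kept.end and kept.start < c.end):
                overlap = min(kept.end, c.end) - max(kept.start, c.start)
                if overlap >= 0.5 * min(kept.end - kept.start, c.end - c.start):
                    if c.total_reads > kept.total_reads:
                        out[i] = c
                    merged = True
                    break
        if not merged:
            out.append(c)
    return out


def discover_candidates(reads_by_sample: dict[str, Counter], genome: dict[str, str],
                        min_stack_reads: int = 5, stack_gap: int = 25,
                        flank: int = 70, max_read_loci: int = 5,
                        index: GenomeIndex | None = None,
                        **criteria_kwargs) -> dict:
    """Full discovery pass: map, stack, excise, evaluate, deduplicate.

    Returns a dict with ``candidates`` (deduplicated, flags evaluated),
    ``multi_locus`` reads, and counts of unmapped sequences and stacks.
    """
    alignments, multi_locus, unmapped = map_reads(reads_by_sample, genome,
                                                  max_read_loci, index)
    stacks = build_read_stacks(alignments, min_stack_reads, stack_gap)
    candidates = []
    for stack in stacks:
        cand = excise_and_fold(stack, genome, alignments, flank)
        if cand is not None:
            candidates.append(cand)
    candidates = deduplicate_candidates(candidates)
    for cand in candidates:
        evaluate_criteria(cand, **criteria_kwargs)
    return {"candidates": candidates, "multi_locus": multi_locus,
            "unmapped": unmapped, "n_stacks": len(stacks)}
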