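"""Synthetic small-RNA study generator with a machine-readable truth manifest.

Builds a toy genome in which miRNA hairpin genes are planted alongside
labelled decoys, then simulates adapter-ligated 75 bp single-end reads for a
multi-group study (developmental stages plus adult organs, two replicate
libraries per group) and qPCR Cq tables for reference-gene stability
testing.  Every planted feature is recorded in a :class:`TruthManifest` so
downstream stages can be validated without any external data.

Hairpin construction: a mature 5p arm ``m5``, a short loop, and a 3p arm
``rc(m5[2:]) + nn`` — a near-perfect stem in which both matures are >90%
paired with each other and the 3p mature carries a 2 nt 3' overhang, i.e. a
textbook Dicer product that passes all five curation criteria by
construction.  Decoys are built to violate exactly the screen they are
labelled with (repetitive multi-locus elements, other-ncRNA look-alikes,
unstructured or under-supported read stacks).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirnaome.config import DEFAULT_ADAPTER
from mirnaome.seqio import revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: study groups (developmental stages, fingerling spleens, adult organs)
DEFAULT_GROUPS = [
    "eyed_egg", "larvae_2dph", "larvae_15dph", "larvae_26dph",
    "fingerling_3g", "fingerling_35g",
    "liver", "head_kidney", "spleen", "gills",
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


@dataclass
class PlantedGene:
    """One planted miRNA gene locus (coordinates 0-based, half-open)."""

    name: str
    contig: str
    start: int
    end: int
    strand: str
    precursor: str
    mature5p: str
    mature3p: str
    guide_arm: str          # "5p" | "3p" | "both"
    conserved: bool
    family: str
    guide_ratio: float      # guide:passenger abundance ratio
    modal_fraction: float   # planted 5' homogeneity of read stacks
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.mature5p not in self.precursor or self.mature3p not in self.precursor:
            raise ValueError(f"{self.name}: matures must be substrings of the precursor")
        if not (55 <= len(self.precursor) <= 90):
            raise ValueError(f"{self.name}: precursor length {len(self.precursor)} outside 55-90")
        for m in (self.mature5p, self.mature3p):
            if not (18 <= len(m) <= 25):
                raise ValueError(f"{self.name}: mature length {len(m)} outside 18-25")


@dataclass
class PlantedDecoy:
    """A planted feature that must be rejected, labelled with the screen it violates.

    kinds: ``repetitive`` (>5 genomic loci), ``ncrna`` (present in the
    other-ncRNA database), ``structure`` (two unpairable read stacks),
    ``support`` (reads in a single library), ``ragged`` (no dominant 5' end).
    """

    name: str
    kind: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str           # primary-locus sequence, transcript sense
    arm1: str
    arm2: str
    extra_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    modal_fraction: float = 0.9
    single_library: bool = False

    @property
    def n_loci(self) -> int:
        return 1 + len(self.extra_loci)


@dataclass
class ClusterTruth:
    cluster_id: str
    members: list[str]
    contig: str
    strand: str


@dataclass
class SimulationConfig:
    seed: int = 42
    n_contigs: int = 2
    contig_length: int = 100_000
    depth: int = 100_000
    read_length: int = 75
    adapter: str = DEFAULT_ADAPTER
    n_replicates: int = 2
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    preset: str = "default"   # "default" | "tiny" (controls the gene catalog)
    extra_decoys: list[str] = field(default_factory=list)  # extra decoy kinds

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("contig count and length must be positive")


@dataclass
class TruthManifest:
    genes: list[PlantedGene]
    decoys: list[PlantedDecoy]
    clusters: list[ClusterTruth]
    groups: list[str]
    n_replicates: int
    design: dict[str, dict[str, float]]     # gene -> group -> guide-arm mean count
    de_effects: list[dict]                  # gene / contrast / true_log2fc
    contig_lengths: dict[str, int]
    seed: int
    depth: int
    read_length: int
    adapter: str

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_r{i + 1}" for g in self.groups for i in range(self.n_replicates)]

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_names,
             "group": [g for g in self.groups for _ in range(self.n_replicates)]}
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "TruthManifest":
        d = json.loads(s)
        d["genes"] = [PlantedGene(**g) for g in d["genes"]]
        decoys = []
        for x in d["decoys"]:
            x["extra_loci"] = [tuple(t) for t in x["extra_loci"]]
            decoys.append(PlantedDecoy(**x))
        d["decoys"] = decoys
        d["clusters"] = [ClusterTruth(**c) for c in d["clusters"]]
        return cls(**d)

    def validate(self, genome: dict[str, str]) -> None:
        """Check the planted-feature invariants against the genome."""
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(genome[g.contig])):
                raise ValueError(f"{g.name} outside genome bounds")
            seg = genome[g.contig][g.start:g.end]
            if g.strand == "-":
                seg = revcomp(seg)
            if seg != g.precursor:
                raise ValueError(f"{g.name} genome sequence mismatch")
        for c in self.clusters:
            members = sorted(
                (g for g in self.genes if g.name in c.members), key=lambda g: g.start
            )
            for a, b in zip(members, members[1:]):
                if a.contig != b.contig or a.strand != b.strand:
                    raise ValueError(f"cluster {c.cluster_id}: mixed contig/strand")
                if b.start - a.end > 10_000:
                    raise ValueError(f"cluster {c.cluster_id}: gap > 10 kb")


# --------------------------------------------------------------------------
# gene catalogs

# (family, conserved, n_identical_loci, cluster id)
_DEFAULT_CATALOG: list[tuple[str, bool, int, str | None]] = [
    ("21", True, 2, "C3"),
    ("430a", True, 1, "C1"), ("430b", True, 1, "C1"), ("430c", True, 1, "C1"),
    ("462", True, 1, "C2"), ("731", True, 1, "C2"),
    ("17", True, 1, "C4"), ("19a", True, 1, "C4"), ("92a", True, 1, "C4"),
    ("30c", True, 1, None), ("107", True, 1, None), ("26a", True, 1, None),
    ("143", True, 1, None), ("122", True, 1, None),
    ("7a", True, 1, None), ("7b", True, 1, None),
    ("10b", True, 1, None), ("130a", True, 1, None), ("199a", True, 1, None),
    ("202", True, 1, None), ("205", True, 1, None), ("206", True, 1, None),
    ("1388", True, 1, None), ("551", True, 1, None), ("454", True, 1, None),
    ("133a", True, 1, None),
    ("nov1", False, 1, None), ("nov2", False, 2, None),
]

_TINY_CATALOG: list[tuple[str, bool, int, str | None]] = [
    ("21", True, 2, "C1"),
    ("462", True, 1, "C2"), ("731", True, 1, "C2"),
    ("30c", True, 1, None), ("122", True, 1, None), ("10b", True, 1, None),
    ("205", True, 1, None),
    ("nov1", False, 1, None),
]

# uniform high-abundance (reference-candidate) families and their means
_STABLE_MEANS = {"30c": 6000.0, "107": 4000.0, "26a": 3000.0, "143": 5000.0}

# group-specific expression overrides: family -> (groups, mean_in, mean_out)
_PROFILE = {
    "122": (["liver"], 25_000.0, 150.0),
    "430a": (["eyed_egg", "larvae_2dph"], 4000.0, 60.0),
    "430b": (["eyed_egg", "larvae_2dph"], 3500.0, 60.0),
    "430c": (["eyed_egg", "larvae_2dph"], 3000.0, 60.0),
    "10b": (["larvae_15dph", "larvae_26dph"], 1600.0, 400.0),
    "205": (["fingerling_3g"], 1800.0, 450.0),
    "462": (["head_kidney"], 2400.0, 300.0),
    "731": (["head_kidney"], 2400.0, 300.0),
    "1388": (["spleen"], 1800.0, 300.0),
    "130a": (["gills"], 1800.0, 300.0),
}

#: families whose two arms are co-dominantly expressed
_CODOMINANT = {"199a", "454"}

#: extra reference-database hairpins unrelated to any planted gene
_EXTRA_REF_FAMILIES = ["99", "100", "155", "181a", "499"]


def _make_hairpin(rng: np.random.Generator) -> tuple[str, str, str]:
    """(precursor, mature5p, mature3p): near-perfect stem-loop.

    The 3p mature pairs the 5p mature over all but its last two bases
    (2 nt 3' overhang) with two central stem mismatches, so each mature is
    ~80-90% paired — comfortably above the 60% curation bound — while the
    stem is imperfect enough that no read variant exact-matches the
    opposite genome strand (real hairpins are likewise not palindromes).
    """
    m5_len = int(rng.integers(22, 25))
    loop_len = int(rng.integers(11, 17))
    m5 = _rand_seq(rng, m5_len)
    loop = _rand_seq(rng, loop_len)
    m3 = revcomp(m5[2:]) + _rand_seq(rng, 2)
    mid = len(m3) // 2
    m3 = _mutate(rng, m3, [mid - 1, mid + 1])
    return m5 + loop + m3, m5, m3


class _Layout:
    """Sequential genome layout with alternating strands.

    Unit pitch guarantees >10 kb between consecutive same-strand units, so
    the only clusters in the genome are the ones planted deliberately.
    """

    def __init__(self, rng: np.random.Generator, n_contigs: int, contig_length: int):
        self.rng = rng
        self.contigs = [f"contig_{i + 1}" for i in range(n_contigs)]
        self.length = contig_length
        self.cursor = {c: 400 for c in self.contigs}
        self.idx = 0
        self.flip = 0
        self.gaps: list[tuple[str, int, int]] = []

    def place(self, span: int) -> tuple[str, int, str]:
        """Reserve a span; returns (contig, start, strand)."""
        gap = 5_300 + int(self.rng.integers(0, 1_500))
        for _ in range(len(self.contigs)):
            contig = self.contigs[self.idx]
            start = self.cursor[contig]
            if start + span + 400 <= self.length:
                self.gaps.append((contig, start + span + 300, start + span + gap - 300))
                self.cursor[contig] = start + span + gap
                strand = "+" if self.flip % 2 == 0 else "-"
                self.flip += 1
                return contig, start, strand
            self.idx = (self.idx + 1) % len(self.contigs)
        raise ValueError(
            f"contigs too short: cannot host a {span} nt unit; "
            f"increase contig_length or n_contigs"
        )

    def place_in_gap(self, span: int) -> tuple[str, int, str]:
        """Place a decoy locus inside a previously reserved inter-gene gap."""
        for i, (contig, lo, hi) in enumerate(self.gaps):
            if hi - lo >= span + 400:
                self.gaps[i] = (contig, lo + span + 400, hi)
                return contig, lo, "+"
        raise ValueError("no inter-gene gap left for decoy placement")


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], TruthManifest]:
    """Build the genome and its truth manifest. Deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    catalog = _TINY_CATALOG if config.preset == "tiny" else _DEFAULT_CATALOG

    genome_arr = {
        f"contig_{i + 1}": _BASES[rng.integers(0, 4, config.contig_length)].copy()
        for i in range(config.n_contigs)
    }
    layout = _Layout(rng, config.n_contigs, config.contig_length)

    genes: list[PlantedGene] = []
    clusters: dict[str, ClusterTruth] = {}
    shared_m5: dict[str, str] = {}   # family-number -> shared 5p mature (7a/7b)

    def plant(seq: str, contig: str, start: int, strand: str) -> None:
        ins = revcomp(seq) if strand == "-" else seq
        genome_arr[contig][start : start + len(ins)] = np.frombuffer(ins.encode(), np.uint8)

    # group catalog entries by cluster so cluster members are laid out as a block
    entries_by_cluster: dict[str | None, list] = {}
    for entry in catalog:
        entries_by_cluster.setdefault(entry[3], []).append(entry)

    sibling_count: dict[str, int] = {}

    def build_gene(family: str, conserved: bool) -> tuple[str, str, str]:
        pre, m5, m3 = _make_hairpin(rng)
        num = family.rstrip("abcdefghij")
        if conserved and family != num and num in shared_m5:
            # letter variants of one family share the 5p mature (e.g. 7a/7b);
            # their 3p arms get the usual central stem mismatches plus one
            # sibling-specific substitution so sister 3p matures never
            # collapse to the same read variants
            k = sibling_count[num]
            sibling_count[num] = k + 1
            m5 = shared_m5[num]
            loop = _rand_seq(rng, int(rng.integers(11, 17)))
            m3 = revcomp(m5[2:]) + _rand_seq(rng, 2)
            mid = len(m3) // 2
            extra = (4, 6, 16, 18)[(k - 1) % 4]
            m3 = _mutate(rng, m3, [mid - 1, mid + 1, extra])
            pre = m5 + loop + m3
        elif conserved and family != num:
            shared_m5[num] = m5
            sibling_count[num] = 1
        return pre, m5, m3

    arm_params: dict[str, tuple[str, float, float]] = {}

    def gene_record(family, conserved, contig, start, strand, pre, m5, m3,
                    copy_tag, cluster_id):
        name = f"slu-mir-{family}{copy_tag}"
        if family not in arm_params:
            # identical duplicated loci share these by construction
            guide = "both" if family in _CODOMINANT else ("5p" if rng.random() < 0.5 else "3p")
            ratio = 1.5 if family in _CODOMINANT else float(rng.choice([15.0, 20.0, 25.0]))
            modal = float(rng.uniform(0.7, 0.95))
            arm_params[family] = (guide, ratio, modal)
        guide, ratio, modal = arm_params[family]
        return PlantedGene(
            name=name, contig=contig, start=start, end=start + len(pre), strand=strand,
            precursor=pre, mature5p=m5, mature3p=m3, guide_arm=guide,
            conserved=conserved, family=family, guide_ratio=ratio,
            modal_fraction=modal, cluster_id=cluster_id,
        )

    # clustered blocks first (deterministic catalog order), then singletons
    for cluster_id, entries in entries_by_cluster.items():
        if cluster_id is None:
            continue
        built = []
        for family, conserved, n_loci, _ in entries:
            pre, m5, m3 = build_gene(family, conserved)
            for copy_i in range(n_loci):
                tag = f"-{copy_i + 1}" if n_loci > 1 else ""
                built.append((family, conserved, pre, m5, m3, tag))
        gaps = [int(rng.integers(2_000, 4_000)) for _ in built[:-1]]
        span = sum(len(b[2]) for b in built) + sum(gaps)
        contig, start, strand = layout.place(span)
        pos = start
        members = []
        order = built if strand == "+" else built[::-1]  # keep 5'->3' sense per strand
        for i, (family, conserved, pre, m5, m3, tag) in enumerate(order):
            plant(pre, contig, pos, strand)
            g = gene_record(family, conserved, contig, pos, strand, pre, m5, m3, tag, cluster_id)
            genes.append(g)
            members.append(g.name)
            if i < len(gaps):
                pos += len(pre) + gaps[i]
        clusters[cluster_id] = ClusterTruth(cluster_id, members, contig, strand)

    for family, conserved, n_loci, _ in entries_by_cluster.get(None, []):
        pre, m5, m3 = build_gene(family, conserved)
        for copy_i in range(n_loci):
            tag = f"-{copy_i + 1}" if n_loci > 1 else ""
            if not conserved and n_loci > 1:
                tag = "ab"[copy_i]
            contig, start, strand = layout.place(len(pre))
            plant(pre, contig, start, strand)
            genes.append(
                gene_record(family, conserved, contig, start, strand, pre, m5, m3, tag, None))

    # ---- decoys ---------------------------------------------------------
    decoys: list[PlantedDecoy] = []
    n_repetitive = 5 if config.preset == "default" else 1
    n_ncrna = 2 if config.preset == "default" else 1

    for d in range(n_repetitive):
        pre, m5, m3 = _make_hairpin(rng)
        contig, start, strand = layout.place_in_gap(len(pre))
        plant(pre, contig, start, strand)
        extra = []
        for _ in range(5):  # 6 loci total: > 5-locus repetitive cutoff
            # each extra copy is mutated inside both mature cores so reads
            # from the primary locus map uniquely, while the copies remain
            # alignable (the repetitive screen must still find all 6 loci)
            core5 = len(m5) // 2
            core3 = len(pre) - len(m3) + len(m3) // 2
            copy = _mutate(rng, pre, [core5 - 1, core5, core3 - 1, core3])
            c2, s2, st2 = layout.place_in_gap(len(copy))
            plant(copy, c2, s2, st2)
            extra.append((c2, s2, s2 + len(copy), st2))
        decoys.append(PlantedDecoy(
            name=f"decoy-rep{d + 1}", kind="repetitive", contig=contig, start=start,
            end=start + len(pre), strand=strand, sequence=pre, arm1=m5, arm2=m3,
            extra_loci=extra))

    ncrna_db: dict[str, str] = {}
    for d in range(n_ncrna):
        pre, m5, m3 = _make_hairpin(rng)
        contig, start, strand = layout.place_in_gap(len(pre))
        plant(pre, contig, start, strand)
        ncrna_db[f"tRNA-like-{d + 1}"] = _mutate(rng, pre, [len(pre) // 3, 2 * len(pre) // 3])
        decoys.append(PlantedDecoy(
            name=f"decoy-ncrna{d + 1}", kind="ncrna", contig=contig, start=start,
            end=start + len(pre), strand=strand, sequence=pre, arm1=m5, arm2=m3))
    for i in range(3):  # unrelated decoy-database entries
        ncrna_db[f"snoRNA-like-{i + 1}"] = _rand_seq(rng, int(rng.integers(70, 120)))

    for kind in config.extra_decoys:
        k = sum(1 for x in decoys if x.kind == kind) + 1
        if kind == "structure":
            region = _rand_seq(rng, 84)
            contig, start, strand = layout.place_in_gap(len(region))
            plant(region, contig, start, strand)
            decoys.append(PlantedDecoy(
                name=f"decoy-struct{k}", kind="structure", contig=contig, start=start,
                end=start + len(region), strand=strand, sequence=region,
                arm1=region[:22], arm2=region[60:82]))
        elif kind in ("support", "ragged"):
            pre, m5, m3 = _make_hairpin(rng)
            contig, start, strand = layout.place_in_gap(len(pre))
            plant(pre, contig, start, strand)
            decoys.append(PlantedDecoy(
                name=f"decoy-{kind}{k}", kind=kind, contig=contig, start=start,
                end=start + len(pre), strand=strand, sequence=pre, arm1=m5, arm2=m3,
                modal_fraction=0.35 if kind == "ragged" else 0.9,
                single_library=(kind == "support")))
        else:
            raise ValueError(f"unknown decoy kind: {kind}")

    genome = {c: a.tobytes().decode() for c, a in genome_arr.items()}

    # ---- expression design ---------------------------------------------
    design: dict[str, dict[str, float]] = {}
    for g in genes:
        base = _STABLE_MEANS.get(g.family, float(np.round(rng.uniform(200, 1200), 1)))
        row = {}
        for grp in config.groups:
            if g.family in _PROFILE:
                in_groups, mean_in, mean_out = _PROFILE[g.family]
                row[grp] = mean_in if grp in in_groups else mean_out
            else:
                row[grp] = base
        design[g.name] = row
    for d in decoys:
        mean = 30.0 if d.single_library else 250.0
        design[d.name] = {grp: mean for grp in config.groups}

    # scale the whole design down if a library's planted mass would exceed
    # the sequencing depth (leaving room for background reads)
    def _group_mass(grp: str) -> float:
        total = 0.0
        for g in genes:
            total += design[g.name][grp] * (1.0 + 1.0 / g.guide_ratio)
        for d in decoys:
            total += design[d.name][grp] * (1.5 if d.kind == "structure" else 1.05)
        return total

    max_mass = max(_group_mass(grp) for grp in config.groups)
    limit = 0.7 * config.depth
    if max_mass > limit:
        scale = limit / max_mass
        design = {name: {grp: round(v * scale, 3) for grp, v in row.items()}
                  for name, row in design.items()}

    manifest = TruthManifest(
        genes=genes, decoys=decoys, clusters=list(clusters.values()),
        groups=list(config.groups), n_replicates=config.n_replicates,
        design=design, de_effects=[], contig_lengths={c: len(s) for c, s in genome.items()},
        seed=config.seed, depth=config.depth, read_length=config.read_length,
        adapter=config.adapter,
    )
    manifest.de_effects = _derive_de_effects(manifest)
    manifest.validate(genome)
    return genome, manifest


def _derive_de_effects(manifest: TruthManifest) -> list[dict]:
    """True log2 fold changes of every gene under the study's contrasts."""
    from mirnaome.diffexp import STUDY_CONTRASTS

    effects = []
    for name, (groups_a, groups_b) in STUDY_CONTRASTS.items():
        if not set(groups_a + groups_b) <= set(manifest.groups):
            continue
        for g in manifest.genes:
            row = manifest.design[g.name]
            mean_a = float(np.mean([row[x] for x in groups_a]))
            mean_b = float(np.mean([row[x] for x in groups_b]))
            lfc = float(np.log2(mean_b / mean_a)) if mean_a > 0 and mean_b > 0 else float("nan")
            effects.append({"gene": g.name, "contrast": name, "true_log2fc": round(lfc, 4)})
    return effects


# --------------------------------------------------------------------------
# read simulation

#: (5' offset, 3' trim) insert variants and their within-modal-class weights
_TRIM3_WEIGHTS = {0: 0.5, 1: 0.3, 2: 0.2}


def _arm_variants(arm: str, modal_fraction: float, ragged: bool) -> tuple[list[str], list[float]]:
    seqs, probs = [], []
    if ragged:
        offsets = {0: modal_fraction, 1: modal_fraction, 2: 1 - 2 * modal_fraction}
    else:
        offsets = {0: modal_fraction, 1: 1 - modal_fraction}
    for off, p_off in offsets.items():
        for trim, p_trim in _TRIM3_WEIGHTS.items():
            sub = arm[off : len(arm) - trim]
            seqs.append(sub)
            probs.append(p_off * p_trim)
    return seqs, probs


def simulate_reads(manifest: TruthManifest, out_dir, depth: int | None = None,
                   seed: int | None = None) -> tuple[dict[str, Path], pd.DataFrame]:
    """Simulate one FASTQ per library; returns (paths, expected-count table).

    Each read is a mature-derived insert (modal 5' start with fraction
    ``modal_fraction``, 3' end trimmed 0-2 nt), the 3' adapter, and random
    fill to the read length; per-(gene, arm) read counts are one multinomial
    draw per library with probabilities design_mean/depth, the leftover mass
    emitted as random unmappable background inserts.
    """
    depth = depth or manifest.depth
    seed = manifest.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(len(manifest.sample_names))

    features = []  # (feature name, arm label, variants, probs, per-group mean fn)
    for g in manifest.genes:
        for arm_label, arm in (("5p", g.mature5p), ("3p", g.mature3p)):
            if g.guide_arm == "both":
                scale = 1.0 if arm_label == "5p" else 1.0 / g.guide_ratio
            elif g.guide_arm == arm_label:
                scale = 1.0
            else:
                scale = 1.0 / g.guide_ratio
            variants = _arm_variants(arm, g.modal_fraction, ragged=False)
            features.append((g.name, arm_label, variants, scale, False))
    for d in manifest.decoys:
        arm2_scale = 0.5 if d.kind == "structure" else 0.05
        for arm_label, arm in (("arm1", d.arm1), ("arm2", d.arm2)):
            variants = _arm_variants(arm, d.modal_fraction, ragged=(d.kind == "ragged"))
            features.append((d.name, arm_label, variants,
                             1.0 if arm_label == "arm1" else arm2_scale,
                             d.single_library))

    expected_rows = []
    paths: dict[str, Path] = {}
    sheet = manifest.sample_sheet()
    for s_idx, (sample, group) in enumerate(zip(sheet["sample"], sheet["group"])):
        rng = np.random.default_rng(streams[s_idx])
        replicate_is_first = sample.endswith("_r1")
        means = []
        for name, arm_label, _, scale, single in features:
            m = manifest.design[name][group] * scale
            if single and not (replicate_is_first and group == manifest.groups[0]):
                m = 0.0
            means.append(m)
            expected_rows.append(
                {"sample": sample, "feature": name, "arm": arm_label, "expected": m})
        total = float(np.sum(means))
        if total <= 0:
            raise ValueError(f"sample {sample}: zero total design mass")
        if total > depth:
            raise ValueError(f"sample {sample}: design mass {total:.0f} exceeds depth {depth}")
        probs = np.array(means + [depth - total]) / depth
        counts = rng.multinomial(depth, probs)

        def reads():
            read_i = 0
            for f_idx, (name, arm_label, (vseqs, vprobs), _, _) in enumerate(features):
                c = int(counts[f_idx])
                if c == 0:
                    continue
                vcounts = rng.multinomial(c, np.array(vprobs) / np.sum(vprobs))
                for vseq, vc in zip(vseqs, vcounts):
                    if vc == 0:
                        continue
                    stem = vseq + manifest.adapter
                    fill_len = manifest.read_length - len(stem)
                    fills = _BASES[rng.integers(0, 4, (vc, fill_len))]
                    for row in fills:
                        read_i += 1
                        yield (f"{sample}_{read_i}", stem + row.tobytes().decode(),
                               "I" * manifest.read_length)
            # background: random inserts that map nowhere
            for _ in range(int(counts[-1])):
                ins_len = int(rng.integers(18, 26))
                ins = _rand_seq(rng, ins_len)
                stem = ins + manifest.adapter
                fill = _rand_seq(rng, manifest.read_length - len(stem))
                read_i += 1
                yield (f"{sample}_{read_i}", stem + fill, "I" * manifest.read_length)

        path = out_dir / f"{sample}.fastq"
        write_fastq(path, reads())
        paths[sample] = path

    expected = pd.DataFrame(expected_rows)
    return paths, expected


# --------------------------------------------------------------------------
# qPCR simulation

def simulate_cq(candidates: list[str], groups: list[str], seed: int,
                n_replicates: int = 2, base_cq: dict[str, float] | None = None,
                noise_sd: dict[str, float] | None = None,
                group_effect: dict[str, dict[str, float]] | None = None,
                sample_effect_sd: float = 0.3) -> pd.DataFrame:
    """Cq table: base + shared sample effect + assay group effect + noise.

    The shared per-sample effect models template-input variation (it shifts
    every assay of a sample equally, which stability statistics must ignore).
    """
    rng = np.random.default_rng(seed)
    base_cq = base_cq or {}
    noise_sd = noise_sd or {}
    group_effect = group_effect or {}
    for a, sd in noise_sd.items():
        if sd < 0:
            raise ValueError(f"negative noise SD for {a}")
    rows = []
    for g in groups:
        for r in range(n_replicates):
            sample = f"{g}_r{r + 1}"
            s_eff = rng.normal(0, sample_effect_sd)
            for a in candidates:
                cq = (base_cq.get(a, 20.0) + s_eff
                      + group_effect.get(a, {}).get(g, 0.0)
                      + (rng.normal(0, noise_sd[a]) if noise_sd.get(a, 0.0) > 0 else 0.0))
                rows.append({"sample": sample, "group": g, "assay": a, "Cq": round(cq, 4)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# reference databases + fixture writing

def reference_databases(manifest: TruthManifest, seed: int) -> tuple[dict[str, str], dict[str, str]]:
    """(miRBase-like hairpin DB, other-ncRNA decoy DB).

    Conserved planted families appear as slightly diverged orthologues under
    a zebrafish-style prefix; novel families are absent.  The decoy DB holds
    the planted ncRNA decoys (diverged copies) plus unrelated entries.
    """
    rng = np.random.default_rng(seed + 7)
    ref: dict[str, str] = {}
    for g in manifest.genes:
        if not g.conserved:
            continue
        name = f"dre-mir-{g.family}"
        if name not in ref:
            n = len(g.precursor)
            ref[name] = _mutate(rng, g.precursor, sorted(rng.choice(n, 3, replace=False).tolist()))
    for fam in _EXTRA_REF_FAMILIES:
        ref[f"dre-mir-{fam}"] = _rand_seq(rng, int(rng.integers(60, 90)))
    ncrna: dict[str, str] = {}
    for d in manifest.decoys:
        if d.kind == "ncrna":
            n = len(d.sequence)
            ncrna[f"tRNA-like-{d.name}"] = _mutate(
                rng, d.sequence, sorted(rng.choice(n, 2, replace=False).tolist()))
    for i in range(3):
        ncrna[f"snoRNA-like-{i + 1}"] = _rand_seq(rng, int(rng.integers(70, 120)))
    return ref, ncrna


def write_fixture(out_dir, config: SimulationConfig) -> dict[str, object]:
    """Write genome, databases, reads, Cq table, and manifest to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, manifest = generate_genome(config)
    write_fasta(out_dir / "genome.fasta", genome)
    ref_db, ncrna_db = reference_databases(manifest, config.seed)
    write_fasta(out_dir / "reference_hairpins.fasta", ref_db)
    write_fasta(out_dir / "ncrna_db.fasta", ncrna_db)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    (out_dir / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
    manifest.sample_sheet().to_csv(out_dir / "samples.tsv", sep="\t", index=False)

    reads_dir = out_dir / "reads"
    paths, expected = simulate_reads(manifest, reads_dir)
    expected.to_csv(out_dir / "expected_counts.tsv", sep="\t", index=False)

    # Cq table for stability testing: four stable assays and one unstable
    assays = ["mir-30c-5p", "mir-107-3p", "mir-26a-5p", "mir-143-5p", "mir-unstable"]
    cq = simulate_cq(
        assays, manifest.groups, seed=config.seed + 13,
        n_replicates=config.n_replicates,
        base_cq={a: 20.0 + 0.5 * i for i, a in enumerate(assays)},
        noise_sd={a: 0.12 for a in assays[:-1]} | {"mir-unstable": 1.5},
        group_effect={"mir-unstable": {g: (2.0 if i % 2 else -2.0)
                                       for i, g in enumerate(manifest.groups)}},
    )
    cq.to_csv(out_dir / "cq.tsv", sep="\t", index=False)

    return {
        "genome": out_dir / "genome.fasta",
        "reference_hairpins": out_dir / "reference_hairpins.fasta",
        "ncrna_db": out_dir / "ncrna_db.fasta",
        "manifest": out_dir / "manifest.json",
        "samples": out_dir / "samples.tsv",
        "reads": paths,
        "expected_counts": out_dir / "expected_counts.tsv",
        "cq": out_dir / "cq.tsv",
    }
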