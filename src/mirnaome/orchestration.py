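"""Pipeline driver: fixtures, the end-to-end run, reports.

Stage order: preprocess -> discovery -> annotation -> clusters -> quantify
-> diffexp (-> refstability/qpcr when a Cq table is supplied).  Every
tabular output carries a header comment with the serialized-config hash;
reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mirnaome import __version__, annotation, clusters, diffexp, quantify, refstability
from mirnaome.config import PipelineConfig
from mirnaome.discovery import GenomeIndex, discover_candidates
from mirnaome.preprocess import preprocess_fastq
from mirnaome.seqio import read_fasta, write_fasta
from mirnaome.synthetic_data import SimulationConfig, write_fixture

_PRESETS = {
    "tiny": dict(n_contigs=2, contig_length=30_000, depth=3_000, preset="tiny"),
    "default": dict(n_contigs=2, contig_length=100_000, depth=100_000, preset="default"),
}


def make_fixture(out_dir, preset: str = "tiny", seed: int = 42) -> dict:
    """Write a packaged synthetic dataset (genome, DBs, reads, Cq, manifest)."""
    if preset not in _PRESETS:
        raise ValueError(f"preset must be one of {sorted(_PRESETS)}")
    sim = SimulationConfig(seed=seed, **_PRESETS[preset])
    return write_fixture(out_dir, sim)


def _stamp(path: Path, df: pd.DataFrame, config: PipelineConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mirnaome {__version__} config_hash={config.hash()}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_stamped(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _genes_to_gff3(genes: list[annotation.AnnotatedGene]) -> str:
    """GFF3 (1-based inclusive) with pre_miRNA parents and miRNA children."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        gid = g.name
        lines.append("\t".join([
            g.contig, "mirnaome", "pre_miRNA", str(g.start + 1), str(g.end),
            ".", g.strand, ".", f"ID={gid};status={g.status};family={g.family}"]))
        for arm, seq in (("5p", g.mature5p), ("3p", g.mature3p)):
            off = g.precursor.find(seq)
            if off < 0:
                continue
            if g.strand == "+":
                s, e = g.start + off, g.start + off + len(seq)
            else:
                s, e = g.end - off - len(seq), g.end - off
            lines.append("\t".join([
                g.contig, "mirnaome", "miRNA", str(s + 1), str(e),
                ".", g.strand, ".", f"ID={gid}-{arm};Parent={gid}"]))
    return "\n".join(lines) + "\n"


def run_pipeline(inputs: dict, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run all stages on the given inputs; write outputs; return results.

    ``inputs``: genome, reference_hairpins, ncrna_db (FASTA paths),
    samples (TSV path with sample/group), reads (dict sample -> FASTQ path),
    and optionally cq (TSV path).  Raises on a missing input file, naming it.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for key in ("genome", "reference_hairpins", "ncrna_db", "samples"):
        if key not in inputs or not Path(inputs[key]).exists():
            raise FileNotFoundError(f"missing input '{key}': {inputs.get(key)}")
    genome = read_fasta(inputs["genome"])
    reference_db = read_fasta(inputs["reference_hairpins"])
    ncrna_db = read_fasta(inputs["ncrna_db"])
    sample_sheet = pd.read_csv(inputs["samples"], sep="\t")
    sample_groups = dict(zip(sample_sheet["sample"], sample_sheet["group"]))

    # ---- preprocess -----------------------------------------------------
    reads_by_sample = {}
    stats_rows = []
    for sample in sample_sheet["sample"]:
        path = inputs["reads"][sample]
        counter, stats = preprocess_fastq(
            path, config.adapter, config.min_insert_len, config.max_insert_len,
            config.adapter_min_overlap, config.adapter_max_mismatch_rate)
        reads_by_sample[sample] = counter
        stats_rows.append({
            "sample": sample, "raw": stats.raw_reads, "trimmed": stats.trimmed_reads,
            "no_adapter": stats.no_adapter_reads,
            "length_discarded": stats.length_discarded_reads, "kept": stats.kept_reads,
            "min_per_base_quality": round(stats.min_per_base_quality, 2)})
    stats_df = pd.DataFrame(stats_rows).set_index("sample")
    _stamp(out_dir / "preprocess_stats.tsv", stats_df, config)

    # ---- discovery ------------------------------------------------------
    index = GenomeIndex(genome)
    disc = discover_candidates(
        reads_by_sample, genome,
        min_stack_reads=config.min_stack_reads, stack_gap=config.stack_gap,
        flank=config.excision_flank, max_read_loci=config.max_read_loci, index=index,
        min_samples=config.min_samples_detected, min_arm_reads=config.min_arm_reads,
        overhang_min=config.overhang_min, overhang_max=config.overhang_max,
        homogeneity_threshold=config.homogeneity_fraction,
        pairing_threshold=config.pairing_fraction)
    candidates = disc["candidates"]
    cand_rows = []
    for c in candidates:
        cand_rows.append({
            "contig": c.contig, "start": c.start, "end": c.end, "strand": c.strand,
            "reads_5p": c.arm5p.total_reads, "reads_3p": c.arm3p.total_reads,
            **c.criterion_flags, "passes": c.passes})
    cand_df = pd.DataFrame(cand_rows)
    _stamp(out_dir / "candidates.tsv", cand_df, config, index=False)

    # ---- annotation -----------------------------------------------------
    aligner = annotation.make_aligner(config.match_score, config.mismatch_score,
                                      config.gap_open_score, config.gap_extend_score)
    # per-search-space Karlin-Altschul calibration (random-query null)
    ka_ref = annotation.fit_karlin_altschul(reference_db, aligner, seed=config.seed)
    ka_ncrna = (annotation.fit_karlin_altschul(ncrna_db, aligner, seed=config.seed)
                if ncrna_db else (config.ka_lambda, config.ka_k))
    rng = np.random.default_rng(config.seed)
    windows = {}
    for i in range(15):
        contig = sorted(genome)[int(rng.integers(0, len(genome)))]
        size = min(1000, len(genome[contig]))
        start = int(rng.integers(0, len(genome[contig]) - size + 1))
        windows[f"w{i}"] = genome[contig][start:start + size]
    ka_genome = annotation.fit_karlin_altschul(windows, aligner, seed=config.seed,
                                               n_queries=25)

    drafts, discarded = [], []
    for c in candidates:
        if not c.passes:
            discarded.append({"contig": c.contig, "start": c.start, "end": c.end,
                              "strand": c.strand, "reason": "criteria"})
            continue
        status, family = annotation.classify_conservation(
            c.sequence, reference_db, config.evalue_threshold, aligner,
            ka_ref[0], ka_ref[1])
        if status == "novel":
            keep, reason = annotation.screen_novel(
                c.sequence, ncrna_db, genome, config.evalue_threshold,
                config.repetitive_locus_cutoff, aligner, ka_ncrna, ka_genome)
            if not keep:
                discarded.append({"contig": c.contig, "start": c.start, "end": c.end,
                                  "strand": c.strand, "reason": reason})
                continue
        drafts.append({"status": status, "family": family, "contig": c.contig,
                       "start": c.start, "end": c.end, "strand": c.strand,
                       "precursor": c.sequence, "mature5p": c.arm5p.sequence,
                       "mature3p": c.arm3p.sequence, "candidate": c})
    genes = annotation.assign_gene_names(drafts, config.species_prefix)
    matures = annotation.merge_matures(genes, config.species_prefix)
    discarded_df = pd.DataFrame(discarded, columns=["contig", "start", "end", "strand", "reason"])
    _stamp(out_dir / "discarded_candidates.tsv", discarded_df, config, index=False)

    gene_df = pd.DataFrame([{
        "name": g.name, "status": g.status, "family": g.family, "contig": g.contig,
        "start": g.start, "end": g.end, "strand": g.strand,
        "mature5p": g.mature5p, "mature3p": g.mature3p} for g in genes])
    _stamp(out_dir / "genes.tsv", gene_df, config, index=False)
    (out_dir / "genes.gff3").write_text(_genes_to_gff3(genes))
    write_fasta(out_dir / "precursors.fasta", [(g.name, g.precursor) for g in genes])
    write_fasta(out_dir / "matures.fasta", [(m.name, m.sequence) for m in matures])

    # ---- clusters -------------------------------------------------------
    cluster_records = clusters.detect_clusters(genes, config.cluster_max_gap)
    cluster_df = pd.DataFrame([{
        "cluster_id": r.cluster_id, "members": ",".join(r.members), "contig": r.contig,
        "strand": r.strand, "start": r.start, "end": r.end, "type": r.cluster_type}
        for r in cluster_records])
    _stamp(out_dir / "clusters.tsv", cluster_df, config, index=False)

    # ---- quantify -------------------------------------------------------
    counts, unassigned = quantify.count_matures(
        reads_by_sample, matures, config.count_max_mismatches,
        config.count_max_offset5, config.count_max_offset3)
    norm, size_factors = quantify.normalize(counts)
    _stamp(out_dir / "counts.tsv", counts, config)
    _stamp(out_dir / "normalized.tsv", norm, config)
    _stamp(out_dir / "size_factors.tsv", size_factors.to_frame(), config)
    diversity = quantify.group_diversity(norm, sample_groups, config.diversity_threshold)
    _stamp(out_dir / "diversity.tsv", diversity.to_frame(), config)
    abundance = pd.concat([
        quantify.relative_abundance(norm, sample_groups, g).assign(group=g)
        for g in sorted(set(sample_groups.values()))])
    _stamp(out_dir / "top_abundance.tsv", abundance, config, index=False)

    # ---- arm dominance --------------------------------------------------
    mature_by_key = {(m.sequence, m.arm): m for m in matures}
    total_counts = counts.sum(axis=1)
    gene_dominance = {}
    for g in genes:
        c5 = float(total_counts.get(mature_by_key[(g.mature5p, "5p")].name, 0.0))
        c3 = float(total_counts.get(mature_by_key[(g.mature3p, "3p")].name, 0.0))
        gene_dominance[g.name] = annotation.arm_dominance(c5, c3, config.passenger_ratio)
    dominance: dict[str, str] = {}
    for m in matures:
        labels = {gene_dominance[p][m.arm] for p in m.parent_genes}
        m.dominance = "passenger" if labels == {"passenger"} else (
            labels.pop() if len(labels) == 1 else "co-dominant")
        dominance[m.name] = m.dominance
    mature_df = pd.DataFrame([{
        "name": m.name, "arm": m.arm, "dominance": m.dominance,
        "parents": ",".join(m.parent_genes), "sequence": m.sequence} for m in matures])
    _stamp(out_dir / "matures.tsv", mature_df, config, index=False)

    # ---- differential expression ---------------------------------------
    contrast_list = diffexp.define_contrasts(sample_sheet)
    de_results = {}
    for con in contrast_list:
        res = diffexp.run_de(
            norm, con, dominance,
            min_normalized=config.de_min_normalized, min_abs_lfc=config.de_min_abs_lfc,
            max_padj=config.de_max_padj, pseudocount=config.de_pseudocount,
            dispersion_floor=config.dispersion_floor)
        de_results[con.name] = res
        _stamp(out_dir / f"de_{con.name}.tsv", res, config)

    # ---- reference stability (sequencing prescreen + optional Cq) -------
    prescreen = refstability.prescreen_candidates(
        norm, config.prescreen_low, config.prescreen_high, config.prescreen_max_rsd)
    _stamp(out_dir / "refstability_prescreen.tsv", prescreen, config)
    stability = None
    if inputs.get("cq"):
        cq = pd.read_csv(inputs["cq"], sep="\t")
        from mirnaome.qpcr import exclude_high_cq

        cq = exclude_high_cq(cq, config.cq_cutoff)
        cq_kept = cq[~cq["excluded"]]
        groups = (dict(zip(cq["sample"], cq["group"])) if "group" in cq.columns
                  else None)
        stability = refstability.stability_report(
            cq_kept, groups, default_efficiency=config.default_efficiency)
        _stamp(out_dir / "stability.tsv", stability, config)

    # ---- run report -----------------------------------------------------
    report = {
        "version": __version__,
        "config_hash": config.hash(),
        "reads": {
            "raw": int(stats_df["raw"].sum()), "kept": int(stats_df["kept"].sum()),
            "no_adapter": int(stats_df["no_adapter"].sum()),
            "length_discarded": int(stats_df["length_discarded"].sum())},
        "discovery": {
            "stacks": disc["n_stacks"], "candidates": len(candidates),
            "passing": sum(c.passes for c in candidates),
            "multi_locus_sequences": len(disc["multi_locus"]),
            "unmapped_sequences": disc["unmapped"]},
        "annotation": {
            "genes": len(genes),
            "conserved": sum(g.status == "conserved" for g in genes),
            "novel": sum(g.status == "novel" for g in genes),
            "families": len({g.family for g in genes}),
            "unique_matures": len(matures),
            "matures_5p": sum(m.arm == "5p" for m in matures),
            "matures_3p": sum(m.arm == "3p" for m in matures),
            "discarded": {r: sum(d["reason"] == r for d in discarded)
                          for r in ("criteria", "ncRNA", "repetitive")}},
        "clusters": {
            "n": len(cluster_records),
            "homo": sum(r.cluster_type == "homo" for r in cluster_records),
            "hetero": sum(r.cluster_type == "hetero" for r in cluster_records),
            "clustered_genes": sum(len(r.members) for r in cluster_records)},
        "quantify": {
            "assigned": int(counts.to_numpy().sum()),
            "unassigned": int(unassigned.sum())},
        "diffexp": {name: int(res["significant"].sum()) for name, res in de_results.items()},
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out_dir / "report.txt").write_text(make_report(out_dir))

    return {"config": config, "genes": genes, "matures": matures,
            "clusters": cluster_records, "counts": counts, "normalized": norm,
            "size_factors": size_factors, "de": de_results, "report": report,
            "candidates": candidates, "discarded": discarded,
            "multi_locus": disc["multi_locus"], "prescreen": prescreen,
            "stability": stability, "dominance": dominance}


def make_report(out_dir) -> str:
    """Human-readable summary regenerated from the serialized outputs alone."""
    out_dir = Path(out_dir)
    rep = json.loads((out_dir / "run_report.json").read_text())
    lines = [
        f"mirnaome {rep['version']} run summary  [config {rep['config_hash']}]",
        "=" * 60,
        "",
        f"[reads | config {rep['config_hash']}]",
        f"  raw {rep['reads']['raw']}, kept {rep['reads']['kept']} "
        f"(no adapter {rep['reads']['no_adapter']}, "
        f"length-discarded {rep['reads']['length_discarded']})",
        "",
        f"[miRNA gene inventory | config {rep['config_hash']}]",
        f"  {rep['annotation']['genes']} genes "
        f"({rep['annotation']['conserved']} conserved + {rep['annotation']['novel']} novel), "
        f"{rep['annotation']['families']} families",
        f"  {rep['annotation']['unique_matures']} unique matures "
        f"({rep['annotation']['matures_5p']} 5p / {rep['annotation']['matures_3p']} 3p)",
        f"  discarded candidates: {rep['annotation']['discarded']}",
        "",
        f"[clusters | config {rep['config_hash']}]",
        f"  {rep['clusters']['n']} clusters "
        f"({rep['clusters']['homo']} homo / {rep['clusters']['hetero']} hetero), "
        f"{rep['clusters']['clustered_genes']} clustered genes",
        "",
        f"[differential expression | config {rep['config_hash']}]",
    ]
    if rep["diffexp"]:
        for name, n in rep["diffexp"].items():
            lines.append(f"  {name}: {n} significant matures")
    else:
        lines.append("  no significant miRNAs")
    diversity_path = out_dir / "diversity.tsv"
    if diversity_path.exists():
        div = read_stamped(diversity_path)
        lines += ["", f"[diversity (detected matures per group) | config {rep['config_hash']}]"]
        for _, row in div.iterrows():
            lines.append(f"  {row.iloc[0]}: {row.iloc[1]}")
    stability_path = out_dir / "stability.tsv"
    if stability_path.exists():
        stab = read_stamped(stability_path)
        lines += ["", f"[reference-gene stability | config {rep['config_hash']}]"]
        for _, row in stab.iterrows():
            lines.append(f"  {row.iloc[0]}: geomean rank {row['geomean_rank']:.3f}")
    return "\n".join(lines) + "\n"


def fixture_inputs(fixture_dir) -> dict:
    """Input mapping for :func:`run_pipeline` from a written fixture directory."""
    fixture_dir = Path(fixture_dir)
    samples = pd.read_csv(fixture_dir / "samples.tsv", sep="\t")["sample"]
    return {
        "genome": fixture_dir / "genome.fasta",
        "reference_hairpins": fixture_dir / "reference_hairpins.fasta",
        "ncrna_db": fixture_dir / "ncrna_db.fasta",
        "samples": fixture_dir / "samples.tsv",
        "reads": {s: fixture_dir / "reads" / f"{s}.fastq" for s in samples},
        "cq": fixture_dir / "cq.tsv",
    }
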