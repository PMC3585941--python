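"""End-to-end orchestration: generate -> clean -> annotate -> profile ->
predict -> express -> edit, with deterministic, re-runnable TSV outputs
and a run manifest (config hash + input checksums)."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import annotate, editing, expression, known, novel, seqio, synth


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    synthetic: synth.SyntheticConfig | None = None
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    mature_fasta: str | None = None
    precursor_fasta: str | None = None
    fastq: dict = field(default_factory=dict)  # stage -> path
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    predictor: novel.PredictorConfig = field(
        default_factory=novel.PredictorConfig)
    alpha: float = 0.01
    log2fc_min: float = 1.0
    editing_min_reads: int = 5
    kmeans_k: int = 20


def _sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    outdir: str
    table: seqio.TagTable
    trim_stats: dict
    summary: pd.DataFrame
    categories: dict
    known_counts: pd.DataFrame
    detected: dict
    novel_report: pd.DataFrame
    candidates: list
    de_results: pd.DataFrame
    de_tallies: dict
    editing_events: list
    truth: synth.SyntheticTruth | None = None


def run_all(config: RunConfig) -> RunResult:
    """Run every stage and write all reports under ``config.outdir``.

    Re-running with identical inputs and config reproduces identical
    report bytes; the manifest records the config hash and input
    checksums.
    """
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    truth = None
    if config.synthetic is not None:
        scfg = config.synthetic
        genome, features, mature, precursors, truth = synth.build_reference(
            scfg)
        fastq_dir = os.path.join(out, "fastq")
        paths, provenance = synth.emit_libraries(truth, scfg, fastq_dir)
        fastq = paths
        adapter3 = scfg.adapter3
        with open(os.path.join(out, "genome.fa"), "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n{seq}\n")
        features.write_gff3(os.path.join(out, "annotations.gff3"))
        known.write_fasta(mature, os.path.join(out, "mature.fa"))
        known.write_fasta(precursors, os.path.join(out, "precursors.fa"))
        provenance.to_csv(os.path.join(out, "provenance.tsv"), sep="\t",
                          index=False)
        for name, frame in (("truth_loci", truth.locus_table),
                            ("truth_expression", truth.expression),
                            ("truth_de", truth.de_truth),
                            ("truth_editing", truth.editing_truth),
                            ("truth_novel", truth.novel_truth)):
            frame.to_csv(os.path.join(out, f"{name}.tsv"), sep="\t",
                         index=name == "truth_expression")
    else:
        for path in (config.genome_fasta, config.annotation_gff3,
                     config.mature_fasta, config.precursor_fasta,
                     *config.fastq.values()):
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(f"missing input: {path}")
        genome = {k: seqio.to_dna(v)
                  for k, v in known.read_fasta(config.genome_fasta).items()}
        features = annotate.FeatureSet.read_gff3(config.annotation_gff3)
        mature = known.read_fasta(config.mature_fasta)
        precursors = known.read_fasta(config.precursor_fasta)
        fastq = dict(config.fastq)
        adapter3 = config.adapter3

    # clean + collapse
    clean = {}
    trim_stats = {}
    for stage, path in fastq.items():
        tags, stats = seqio.load_fastq(path, adapter3)
        clean[stage] = tags
        trim_stats[stage] = stats.as_dict()
    table = seqio.collapse(clean)
    table.write_tsv(os.path.join(out, "tags.tsv"))
    seqio.length_distribution(table).to_csv(
        os.path.join(out, "length_distribution.tsv"), sep="\t")
    pd.DataFrame(trim_stats).to_csv(os.path.join(out, "trim_stats.tsv"),
                                    sep="\t")

    # map + classify + summarize
    index = annotate.GenomeIndex(genome)
    hits_by_tag, n_hits = annotate.map_tags(table, index)
    records = known.build_records(mature, precursors)
    known_set = known.known_match_set(table, records)
    bounds = {c: len(s) for c, s in genome.items()}
    categories = annotate.classify(hits_by_tag, features, known_set,
                                   genome_bounds=bounds)
    summary = annotate.summarize(categories, table, hits_by_tag)
    summary.to_csv(os.path.join(out, "category_summary.tsv"), sep="\t")
    pd.Series(categories, name="category").rename_axis("sequence").to_csv(
        os.path.join(out, "tag_categories.tsv"), sep="\t")

    # known-miRNA profiling
    known_counts, detected = known.match_known(table, records)
    known_counts.to_csv(os.path.join(out, "known_counts.tsv"), sep="\t")

    # novel prediction
    novel_report, candidates = novel.predict_novel(
        table, hits_by_tag, n_hits, categories, features, genome,
        config.predictor)
    novel_report.to_csv(os.path.join(out, "novel_mirnas.tsv"), sep="\t",
                        index=False)

    # expression + DE
    totals = table.totals
    de_results, de_tallies = expression.call_de(
        known_counts, totals, alpha=config.alpha,
        log2fc_min=config.log2fc_min)
    de_results.to_csv(os.path.join(out, "de_results.tsv"), sep="\t",
                      index=False)
    pd.DataFrame(de_tallies, index=["significant", "up", "down"]).T.to_csv(
        os.path.join(out, "de_tallies.tsv"), sep="\t")
    tpm = expression.normalize(known_counts, totals)
    tpm.to_csv(os.path.join(out, "tpm.tsv"), sep="\t")
    expression.stage_preference(tpm).to_csv(
        os.path.join(out, "stage_preference.tsv"), sep="\t", index=False)

    # editing
    unannot = {seq: table.counts[seq] for seq, cat in categories.items()
               if cat == "no_annotation"}
    mature_by_family = {}
    fam = known.collapse_families(records)
    for seq, fid in fam.items():
        mature_by_family[fid] = seq
    mature_map = {fid: seq for fid, seq in mature_by_family.items()}
    events = editing.scan_editing(unannot, mature_map, known_counts,
                                  table.libraries,
                                  min_reads=config.editing_min_reads)
    editing.edited_variant_guard(events, mature_map, index)
    editing.events_frame(events, table.libraries).to_csv(
        os.path.join(out, "editing_events.tsv"), sep="\t", index=False)
    type_frame, pos_frame, fractions = editing.tally(events, table.libraries)
    type_frame.to_csv(os.path.join(out, "substitution_types.tsv"), sep="\t")
    pos_frame.to_csv(os.path.join(out, "substitution_positions.tsv"),
                     sep="\t")

    # manifest
    cfg_desc = {
        "seed": config.seed, "alpha": config.alpha,
        "log2fc_min": config.log2fc_min,
        "editing_min_reads": config.editing_min_reads,
        "predictor": asdict(config.predictor),
        "synthetic_seed": (config.synthetic.seed
                           if config.synthetic else None),
    }
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_desc, sort_keys=True).encode()).hexdigest()
    manifest = {"config": cfg_desc, "config_hash": cfg_hash,
                "inputs": {stage: _sha(path)
                           for stage, path in sorted(fastq.items())}}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(out, table, trim_stats, summary, categories,
                     known_counts, detected, novel_report, candidates,
                     de_results, de_tallies, events, truth)
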