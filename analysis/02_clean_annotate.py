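"""Clean the libraries and build the category-summary table.

Trims adapters, collapses reads to unique tags, maps them to the toy
genome and classifies each tag through the annotation cascade, writing
the Table-1-shaped category summary and the length distribution under
results/annotation/.
"""

import pathlib

import pandas as pd

from oryzamir import annotate, known, seqio

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "sim"
OUT = ROOT / "annotation"
STAGES = ("5DAF", "7DAF", "12DAF", "17DAF")
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clean = {}
    for stage in STAGES:
        tags, stats = seqio.load_fastq(SIM / "fastq" / f"{stage}.fastq",
                                       ADAPTER3)
        clean[stage] = tags
        print(f"{stage}: {stats.clean} clean of {stats.total_reads} reads")
    table = seqio.collapse(clean)
    table.write_tsv(OUT / "tags.tsv")
    seqio.length_distribution(table).to_csv(OUT / "length_distribution.tsv",
                                            sep="\t")

    genome = {k: seqio.to_dna(v)
              for k, v in known.read_fasta(SIM / "genome.fa").items()}
    features = annotate.FeatureSet.read_gff3(SIM / "annotations.gff3")
    records = known.build_records(known.read_fasta(SIM / "mature.fa"),
                                  known.read_fasta(SIM / "precursors.fa"))
    index = annotate.GenomeIndex(genome)
    hits, n_hits = annotate.map_tags(table, index)
    cats = annotate.classify(hits, features,
                             known.known_match_set(table, records))
    summary = annotate.summarize(cats, table, hits)
    summary.to_csv(OUT / "category_summary.tsv", sep="\t")
    pd.Series(cats, name="category").rename_axis("sequence").to_csv(
        OUT / "tag_categories.tsv", sep="\t")
    print(f"{len(table)} unique tags; per-stage totals {table.totals}")
    print("total-read category percentages:")
    print(summary[[f"{s}_total_pct" for s in STAGES]])


if __name__ == "__main__":
    main()
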