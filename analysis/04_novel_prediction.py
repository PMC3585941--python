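"""Predict novel miRNA hairpins and score recovery against the truth.

Runs the full predictor (locus extraction, precursor excision/folding,
duplex criteria, post-filters) on the unannotated tags and compares the
calls with the planted hairpins and single-flaw decoys.
"""

import pathlib

import pandas as pd

from oryzamir import annotate, known, novel, seqio

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "novel"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = seqio.TagTable.read_tsv(ROOT / "annotation" / "tags.tsv")
    cats = pd.read_csv(ROOT / "annotation" / "tag_categories.tsv", sep="\t",
                       index_col=0)["category"].to_dict()
    genome = {k: seqio.to_dna(v) for k, v in
              known.read_fasta(ROOT / "sim" / "genome.fa").items()}
    features = annotate.FeatureSet.read_gff3(
        ROOT / "sim" / "annotations.gff3")
    index = annotate.GenomeIndex(genome)
    hits, n_hits = annotate.map_tags(table, index)
    report, candidates = novel.predict_novel(table, hits, n_hits, cats,
                                             features, genome)
    report.to_csv(OUT / "novel_mirnas.tsv", sep="\t", index=False)

    truth = pd.read_csv(ROOT / "sim" / "truth_novel.tsv", sep="\t")
    planted = set(truth.mature_seq)
    called = set(report.mature_seq) if len(report) else set()
    tp = len(planted & called)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(planted) if planted else 0.0
    print(f"{len(report)} novel miRNAs called "
          f"({int(report.star_supported.sum()) if len(report) else 0} "
          f"with miRNA* support)")
    print(f"recovery vs planted truth: precision {precision:.2f}, "
          f"recall {recall:.2f}")
    rejected = [c for c in candidates if not c.passed and c.failures]
    reasons = pd.Series([c.failures[0] for c in rejected]).value_counts()
    print("top rejection reasons:")
    print(reasons.head(8).to_string())


if __name__ == "__main__":
    main()
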