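"""Generate the synthetic four-stage small-RNA study.

Builds the toy reference (genome, annotations, known/novel hairpins,
planted expression, editing sites) and emits the four adapter-ligated
FASTQ libraries plus the ground-truth tables under results/sim/.
"""

import pathlib
import sys

from oryzamir import known, synth

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "sim"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.SyntheticConfig(seed=seed)
    genome, features, mature, precursors, truth = synth.build_reference(cfg)
    with open(OUT / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    features.write_gff3(OUT / "annotations.gff3")
    known.write_fasta(mature, OUT / "mature.fa")
    known.write_fasta(precursors, OUT / "precursors.fa")
    paths, provenance = synth.emit_libraries(truth, cfg, OUT / "fastq")
    provenance.to_csv(OUT / "provenance.tsv", sep="\t", index=False)
    truth.locus_table.to_csv(OUT / "truth_loci.tsv", sep="\t", index=False)
    truth.expression.to_csv(OUT / "truth_expression.tsv", sep="\t")
    truth.de_truth.to_csv(OUT / "truth_de.tsv", sep="\t", index=False)
    truth.editing_truth.to_csv(OUT / "truth_editing.tsv", sep="\t",
                               index=False)
    truth.novel_truth.to_csv(OUT / "truth_novel.tsv", sep="\t", index=False)
    print(f"simulated {len(paths)} libraries "
          f"({sum(cfg.library_depths)} reads) into {OUT}")
    print(f"planted: {len(truth.expression)} known miRNAs, "
          f"{len(truth.novel_truth)} novel hairpins, "
          f"{len(truth.editing_truth)} editing sites")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
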