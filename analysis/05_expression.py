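"""Differential expression across the grain-filling transitions.

Normalizes known-miRNA counts to TPM, tests every adjacent-stage pair
with the Audic-Claverie exact test (P < 0.01, fold change > 2), tallies
up/down calls per transition, calls stage-preferential miRNAs by the
ratio > 2 / Z > 2 rule, and clusters the DE profiles with k-means.
"""

import pathlib

import pandas as pd

from oryzamir import expression, seqio

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "expression"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = seqio.TagTable.read_tsv(ROOT / "annotation" / "tags.tsv")
    counts = pd.read_csv(ROOT / "known" / "known_counts.tsv", sep="\t",
                         index_col=0)
    totals = table.totals
    tpm = expression.normalize(counts, totals)
    tpm.to_csv(OUT / "tpm.tsv", sep="\t")

    results, tallies = expression.call_de(counts, totals)
    results.to_csv(OUT / "de_results.tsv", sep="\t", index=False)
    tally_frame = pd.DataFrame(tallies, index=["significant", "up",
                                               "down"]).T
    tally_frame.to_csv(OUT / "de_tallies.tsv", sep="\t")
    de_ids = sorted(set(results.loc[results.direction != "ns", "mirna"]))
    print(f"{len(de_ids)} known miRNAs differentially expressed in at "
          f"least one transition")
    print(tally_frame.to_string())

    prefs = expression.stage_preference(tpm)
    prefs.to_csv(OUT / "stage_preference.tsv", sep="\t", index=False)
    print(f"{prefs.mirna.nunique()} stage-preferential miRNAs "
          f"(ratio > 2, Z > 2):")
    if len(prefs):
        print(prefs.stage.value_counts().to_string())

    if len(de_ids) >= 2:
        k = min(20, len(de_ids))
        assign, _ = expression.cluster_profiles(tpm.loc[de_ids], k=k,
                                                seed=seed)
        assign.to_csv(OUT / "clusters.tsv", sep="\t")
        print(f"k-means grouped the DE profiles into {k} clusters")

    truth = pd.read_csv(ROOT / "sim" / "truth_de.tsv", sep="\t")
    sig = results[results.direction != "ns"]
    hits = 0
    for row in truth.itertuples(index=False):
        match = sig[(sig.mirna == row.miRNA)
                    & (sig.transition == row.transition)
                    & (sig.direction == row.direction)]
        hits += bool(len(match))
    print(f"planted fold changes recovered: {hits}/{len(truth)}")


if __name__ == "__main__":
    main()
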