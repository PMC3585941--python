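"""Profile the known miRNAs: counts, shared fraction, isomiRs, stars.

Counts perfect mature matches per library, reports how many miRNAs are
shared by all four stages, and profiles read stacks along each precursor
for +/-2 nt isomiR variants and miRNA* species.
"""

import pathlib

import pandas as pd

from oryzamir import known, seqio
from oryzamir.fold import fold

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "known"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = seqio.TagTable.read_tsv(ROOT / "annotation" / "tags.tsv")
    records = known.build_records(
        known.read_fasta(ROOT / "sim" / "mature.fa"),
        known.read_fasta(ROOT / "sim" / "precursors.fa"))
    counts, detected = known.match_known(table, records)
    counts.to_csv(OUT / "known_counts.tsv", sep="\t")
    shared, union, pct = known.shared_fraction(detected)
    per_lib = {lib: len(ids) for lib, ids in detected.items()}
    print(f"detected per library: {per_lib}")
    print(f"{shared} of {union} known miRNAs shared by all four stages "
          f"({pct:.2f}%)")

    stacks = known.build_stacks(table, records)
    rows = []
    for rec in records:
        stack = stacks[rec.precursor_id]
        variants = known.detect_variants(stack, rec)
        structure, _ = fold(rec.precursor_seq)
        try:
            mat, star, dom, ratio = known.star_ratio(stack, rec, structure)
        except ValueError:
            mat = star = 0
            dom, ratio = False, float("nan")
        rows.append({"miRNA": rec.mature_id, "mature_reads": mat,
                     "star_reads": star, "star_dominant": dom,
                     "n_variants": len(variants),
                     "variant_dominant": bool(
                         variants.variant_dominant.any())
                     if len(variants) else False})
    profile = pd.DataFrame(rows)
    profile.to_csv(OUT / "precursor_profile.tsv", sep="\t", index=False)
    n_star = int((profile.star_reads > 0).sum())
    print(f"{n_star} precursors with sequenced miRNA*; "
          f"{int(profile.variant_dominant.sum())} with a dominant isomiR")


if __name__ == "__main__":
    main()
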