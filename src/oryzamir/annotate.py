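"""Genome mapping and the single-category annotation cascade.

Every tag is mapped to the genome by exact match (hash index over 18-nt
seeds with full verification) and then assigned exactly one category via a
configurable priority cascade: structural RNAs first, then repeats, then
mRNA fragments (exon/intron, split sense/antisense), then known miRNAs,
then a double-stranded siRNA heuristic, with everything left over - mapped
or not - falling into ``no_annotation``.  The per-library summary has the
shape of the published category table: unique-tag and total-read counts
with percentages of the clean totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from intervaltree import IntervalTree

from .seqio import TagTable, to_dna, revcomp_dna

SEED_LEN = 18

#: cascade order used when none is supplied; mirrors the removal order of
#: the structural-RNA / repeat / mRNA-fragment filtering cascade, with the
#: known-miRNA match and siRNA heuristic at the end.
DEFAULT_PRIORITY = ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA", "repeat",
                    "exon", "intron", "miRNA", "siRNA")

#: leaf categories of the summary table (these partition total_clean)
LEAF_CATEGORIES = ("miRNA", "siRNA", "rRNA", "snRNA", "snoRNA", "tRNA",
                   "repeat", "exon_antisense", "exon_sense",
                   "intron_antisense", "intron_sense", "no_annotation")

_FEATURE_TO_CATEGORY = {
    "rRNA": "rRNA", "scRNA": "scRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
    "tRNA": "tRNA", "repeat_region": "repeat", "exon": "exon",
    "intron": "intron",
}


@dataclass(frozen=True)
class AlignmentHit:
    sequence: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int = 0


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    ftype: str
    fid: str


class FeatureSet:
    """Strand-annotated genomic features with interval-tree lookup."""

    def __init__(self, features=()):
        self.features: list[Feature] = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for feat in self.features:
            self._trees.setdefault(feat.chrom, IntervalTree()).addi(
                feat.start, feat.end, feat)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda f: (f.start, f.end, f.ftype, f.fid))

    def write_gff3(self, path) -> None:
        with open(path, "w") as out:
            out.write("##gff-version 3\n")
            for f in sorted(self.features,
                            key=lambda f: (f.chrom, f.start, f.end, f.fid)):
                out.write(f"{f.chrom}\toryzamir\t{f.ftype}\t{f.start + 1}\t"
                          f"{f.end}\t.\t{f.strand}\t.\tID={f.fid}\n")

    @classmethod
    def read_gff3(cls, path) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attrs"],
                         dtype={"chrom": str})
        feats = []
        for row in df.itertuples(index=False):
            fid = ""
            for part in str(row.attrs).split(";"):
                if part.startswith("ID="):
                    fid = part[3:]
            feats.append(Feature(row.chrom, int(row.start) - 1, int(row.end),
                                 row.strand, row.type, fid))
        return cls(feats)


class GenomeIndex:
    """Exact-match mapper: hash index over fixed-length seeds + verification."""

    def __init__(self, genome: dict):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._index: dict[str, list] = {}
        for chrom, seq in sorted(self.genome.items()):
            for i in range(len(seq) - SEED_LEN + 1):
                self._index.setdefault(seq[i:i + SEED_LEN], []).append(
                    (chrom, i))

    def map_sequence(self, tag: str) -> list[AlignmentHit]:
        """All exact genomic loci of an RNA tag, both strands, sorted."""
        dna = to_dna(tag)
        hits = []
        for strand, query in (("+", dna), ("-", revcomp_dna(dna))):
            for chrom, pos in self._index.get(query[:SEED_LEN], ()):
                if self.genome[chrom][pos:pos + len(query)] == query:
                    hits.append(AlignmentHit(tag, chrom, pos, pos + len(query),
                                             strand, 0))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits

    def contains(self, tag: str) -> bool:
        return bool(self.map_sequence(tag))


def map_tags(table: TagTable, index: GenomeIndex, max_hits: int = 20):
    """Map every tag; returns ``(hits_by_tag, n_hits_by_tag)``.

    Tags with more than ``max_hits`` loci keep their full hit count in
    ``n_hits_by_tag`` (the "multi" flag) but only the lexicographically
    first ``max_hits`` hits are retained.
    """
    hits_by_tag: dict[str, list[AlignmentHit]] = {}
    n_hits: dict[str, int] = {}
    for seq in table.counts:
        hits = index.map_sequence(seq)
        n_hits[seq] = len(hits)
        hits_by_tag[seq] = hits[:max_hits]
    return hits_by_tag, n_hits


def _strand_trees(hits_by_tag: dict) -> dict:
    trees: dict = {}
    for hits in hits_by_tag.values():
        if not hits:
            continue
        rep = hits[0]
        trees.setdefault((rep.chrom, rep.strand), IntervalTree()).addi(
            rep.start, rep.end)
    return trees


def classify(hits_by_tag: dict, features: FeatureSet, known_matches: set,
             priority=DEFAULT_PRIORITY, genome_bounds: dict | None = None,
             sirna_min_len: int = 21, sirna_max_len: int = 24) -> dict:
    """Assign exactly one category to every tag.

    ``known_matches`` is the set of tag sequences that match a known
    mature miRNA or precursor perfectly.  Multi-hit tags are judged at
    their representative hit (first in (chrom, start, strand) order).
    The siRNA category is operational: a mapped, otherwise-unannotated
    21-24 nt tag whose representative locus overlaps the representative
    locus of a tag mapped on the opposite strand.
    """
    if genome_bounds:
        for f in features.features:
            if f.end > genome_bounds.get(f.chrom, f.end) or f.start < 0:
                raise ValueError(
                    f"annotation {f.fid} outside genome bounds: "
                    f"{f.chrom}:{f.start}-{f.end}")
    opposite = _strand_trees(hits_by_tag)
    categories: dict[str, str] = {}
    for seq, hits in hits_by_tag.items():
        if not hits:
            categories[seq] = "miRNA" if (
                "miRNA" in priority and seq in known_matches
            ) else "no_annotation"
            continue
        rep = hits[0]
        cats_present = set()
        strands = {}
        for feat in features.overlapping(rep.chrom, rep.start, rep.end):
            cat = _FEATURE_TO_CATEGORY.get(feat.ftype)
            if cat:
                cats_present.add(cat)
                strands.setdefault(cat, feat.strand)
        if seq in known_matches:
            cats_present.add("miRNA")
        assigned = None
        for cat in priority:
            if cat == "siRNA":
                if (sirna_min_len <= len(seq) <= sirna_max_len):
                    other = opposite.get(
                        (rep.chrom, "-" if rep.strand == "+" else "+"))
                    if other is not None and other.overlap(rep.start, rep.end):
                        assigned = "siRNA"
                        break
                continue
            if cat in cats_present:
                if cat in ("exon", "intron"):
                    sense = strands[cat] == rep.strand
                    assigned = f"{cat}_{'sense' if sense else 'antisense'}"
                else:
                    assigned = cat
                break
        categories[seq] = assigned or "no_annotation"
    return categories


def round_pct(numer: int, denom: int, ndigits: int = 2) -> float:
    """Percentage of ``numer`` in ``denom``, rounded half-up to 2 decimals."""
    if denom == 0:
        return 0.0
    q = Decimal(numer) * 100 / Decimal(denom)
    return float(q.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def category_percentages(counts: dict, clean_total: int) -> dict:
    """Half-up 2-dp percentages for a mapping category -> count."""
    return {cat: round_pct(n, clean_total) for cat, n in counts.items()}


def summarize(categories: dict, table: TagTable,
              hits_by_tag: dict) -> pd.DataFrame:
    """Per-library category summary shaped like the published Table 1.

    Rows: total_clean, match_genome (roll-ups) then the leaf categories.
    Columns per library: ``<lib>_unique``, ``<lib>_unique_pct``,
    ``<lib>_total``, ``<lib>_total_pct``.
    """
    rows = ["total_clean", "match_genome", *LEAF_CATEGORIES]
    data: dict[str, list] = {}
    totals = table.totals
    for li, lib in enumerate(table.libraries):
        uniq = {r: 0 for r in rows}
        reads = {r: 0 for r in rows}
        for seq, vec in table.counts.items():
            n = int(vec[li])
            if n == 0:
                continue
            uniq["total_clean"] += 1
            reads["total_clean"] += n
            if hits_by_tag.get(seq):
                uniq["match_genome"] += 1
                reads["match_genome"] += n
            cat = categories[seq]
            uniq[cat] += 1
            reads[cat] += n
        clean_u, clean_t = uniq["total_clean"], reads["total_clean"]
        assert clean_t == totals[lib]
        data[f"{lib}_unique"] = [uniq[r] for r in rows]
        data[f"{lib}_unique_pct"] = [round_pct(uniq[r], clean_u) for r in rows]
        data[f"{lib}_total"] = [reads[r] for r in rows]
        data[f"{lib}_total_pct"] = [round_pct(reads[r], clean_t) for r in rows]
    out = pd.DataFrame(data, index=rows)
    out.index.name = "category"
    return out
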