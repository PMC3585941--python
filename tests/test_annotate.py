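"""Genome mapping and the single-category annotation cascade."""

import numpy as np
import pytest

from oryzamir import annotate, published
from oryzamir.annotate import (AlignmentHit, Feature, FeatureSet,
                               GenomeIndex, classify, map_tags, round_pct,
                               summarize)
from oryzamir.seqio import TagTable, collapse, revcomp_dna, to_rna


def _random_genome(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestGenomeIndex:
    def test_planted_forward_hit(self, rng):
        g = _random_genome(rng, 2000)
        tag = to_rna(g[100:121])
        hits = GenomeIndex({"chr1": g}).map_sequence(tag)
        assert AlignmentHit(tag, "chr1", 100, 121, "+", 0) in hits

    def test_planted_reverse_hit(self, rng):
        g = _random_genome(rng, 2000)
        tag = to_rna(revcomp_dna(g[500:522]))
        hits = GenomeIndex({"chr1": g}).map_sequence(tag)
        assert any(h.start == 500 and h.end == 522 and h.strand == "-"
                   for h in hits)

    def test_absent_tag_unmapped(self, rng):
        g = "ACGT" * 200
        hits = GenomeIndex({"chr1": g}).map_sequence("U" * 21)
        assert hits == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex({})

    def test_agrees_with_brute_force_scan(self, rng):
        """On genomes <= 5 kb the index equals a direct scan of every
        offset and strand."""
        g = _random_genome(rng, 3000)
        # plant a duplicated tag to exercise multi-hits
        g = g[:700] + g[100:125] + g[725:]
        index = GenomeIndex({"chr1": g})
        tags = [to_rna(g[i:i + 21]) for i in rng.integers(0, 2970, 25)]
        tags += [to_rna(revcomp_dna(g[i:i + 24]))
                 for i in rng.integers(0, 2970, 10)]
        tags += [to_rna(_random_genome(rng, 21)) for _ in range(5)]
        for tag in tags:
            expected = set()
            dna, rc = tag.replace("U", "T"), revcomp_dna(tag)
            for i in range(len(g) - len(tag) + 1):
                window = g[i:i + len(tag)]
                if window == dna:
                    expected.add((i, "+"))
                if window == rc:
                    expected.add((i, "-"))
            got = {(h.start, h.strand) for h in index.map_sequence(tag)}
            assert got == expected


class TestClassify:
    def _table(self, seqs):
        return collapse({"A": list(seqs)})

    def test_structural_rna_beats_exon(self, rng):
        g = _random_genome(rng, 1000)
        tag = to_rna(g[100:121])
        feats = FeatureSet([Feature("chr1", 90, 200, "+", "rRNA", "r1"),
                            Feature("chr1", 50, 300, "+", "exon", "e1")])
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        cats = classify(hits, feats, set())
        assert cats[tag] == "rRNA"

    def test_unannotated_mapped_tag(self, rng):
        g = _random_genome(rng, 1000)
        tag = to_rna(g[100:121])
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        assert classify(hits, FeatureSet(), set())[tag] == "no_annotation"

    def test_known_mirna_match(self, rng):
        g = _random_genome(rng, 1000)
        tag = to_rna(g[100:121])
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        assert classify(hits, FeatureSet(), {tag})[tag] == "miRNA"

    def test_unmapped_tag_no_annotation(self, rng):
        g = "ACGT" * 250
        tag = "U" * 21
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        assert classify(hits, FeatureSet(), set())[tag] == "no_annotation"

    def test_sense_antisense_split(self, rng):
        g = _random_genome(rng, 1000)
        sense = to_rna(g[100:121])
        anti = to_rna(revcomp_dna(g[300:321]))
        feats = FeatureSet([Feature("chr1", 50, 200, "+", "exon", "e1"),
                            Feature("chr1", 250, 400, "+", "intron", "i1")])
        hits, _ = map_tags(self._table([sense, anti]),
                           GenomeIndex({"chr1": g}))
        cats = classify(hits, feats, set())
        assert cats[sense] == "exon_sense"
        assert cats[anti] == "intron_antisense"

    def test_sirna_requires_opposite_strand_partner(self, rng):
        g = _random_genome(rng, 1000)
        fwd = to_rna(g[100:124])
        rev = to_rna(revcomp_dna(g[110:134]))
        lone = to_rna(g[500:524])
        hits, _ = map_tags(self._table([fwd, rev, lone]),
                           GenomeIndex({"chr1": g}))
        cats = classify(hits, FeatureSet(), set())
        assert cats[fwd] == "siRNA" and cats[rev] == "siRNA"
        assert cats[lone] == "no_annotation"

    def test_priority_monotonicity(self, rng):
        """Moving a category earlier in the priority never decreases its
        tag count."""
        g = _random_genome(rng, 1000)
        tag = to_rna(g[100:121])
        feats = FeatureSet([Feature("chr1", 90, 200, "+", "repeat_region",
                                    "r1"),
                            Feature("chr1", 50, 300, "+", "exon", "e1")])
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        default = classify(hits, feats, set())
        promoted = classify(hits, feats, set(),
                            priority=("exon", "repeat", "miRNA", "siRNA"))
        assert default[tag] == "repeat"
        assert promoted[tag] == "exon_sense"

    def test_annotation_outside_bounds_rejected(self, rng):
        g = _random_genome(rng, 300)
        tag = to_rna(g[10:31])
        feats = FeatureSet([Feature("chr1", 200, 900, "+", "rRNA", "r1")])
        hits, _ = map_tags(self._table([tag]), GenomeIndex({"chr1": g}))
        with pytest.raises(ValueError, match="outside genome bounds"):
            classify(hits, feats, set(), genome_bounds={"chr1": 300})


class TestSummarize:
    def test_published_percentages_reproduced(self):
        """Feeding the printed per-category counts through the summary
        arithmetic reproduces the printed percentages."""
        for lib in published.LIBRARIES:
            uniq_den, total_den = published.CATEGORY_COUNTS[
                "total_clean"][lib]
            u, t = published.CATEGORY_COUNTS["match_genome"][lib]
            assert round_pct(u, uniq_den) == \
                published.MATCH_GENOME_UNIQUE_PCT[lib]
            assert round_pct(t, total_den) == \
                published.MATCH_GENOME_TOTAL_PCT[lib]
        # spot values quoted in the text
        assert round_pct(15561105, 17029030) == 91.38
        assert round_pct(2450748, 15860692) == 15.45

    def test_single_category_library(self, rng):
        g = _random_genome(rng, 1000)
        tag = to_rna(g[100:121])
        table = collapse({"A": [tag] * 4})
        index = GenomeIndex({"chr1": g})
        hits, _ = map_tags(table, index)
        feats = FeatureSet([Feature("chr1", 90, 150, "+", "rRNA", "r1")])
        cats = classify(hits, feats, set())
        summary = summarize(cats, table, hits)
        assert summary.at["rRNA", "A_total_pct"] == 100.00
        assert summary.at["miRNA", "A_total_pct"] == 0.00

    def test_partition_invariant(self, default_run):
        """Leaf category totals partition the clean reads in every
        library; genome-matched mass never exceeds the clean total."""
        summary = default_run.summary
        for lib in default_run.table.libraries:
            col = summary[f"{lib}_total"]
            leaf_sum = sum(col[cat] for cat in annotate.LEAF_CATEGORIES)
            assert leaf_sum == col["total_clean"]
            assert col["match_genome"] <= col["total_clean"]
            ucol = summary[f"{lib}_unique"]
            leaf_u = sum(ucol[cat] for cat in annotate.LEAF_CATEGORIES)
            assert leaf_u == ucol["total_clean"]
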