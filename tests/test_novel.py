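"""Novel-miRNA predictor: locus extraction, duplex criteria, post-filters
and recovery of the planted hairpins against single-flaw decoys."""

import dataclasses

import pytest

from oryzamir.fold import fold
from oryzamir.novel import (HairpinCandidate, Locus, PredictorConfig,
                            evaluate_duplex, extract_loci)

MATURE = "UGACAGAAGAGAGUGAGCACA"
STAR = "UGUGCUCACUCUCUUCUGUCA"


def _candidate(precursor, mature, config=None):
    structure, mfe = fold(precursor)
    cand = HairpinCandidate(
        locus=Locus("chr1", "+", 0, len(mature), []),
        chrom="chr1", start=0, end=len(precursor), strand="+",
        precursor_seq=precursor, structure=structure, mfe=mfe,
        mature_seq=mature, mature_offset=precursor.find(mature))
    return evaluate_duplex(cand, config or PredictorConfig())


class TestExtractLoci:
    def test_tags_within_max_space_merge(self):
        loci = extract_loci([("A" * 21, "chr1", 100, 121, "+", 5),
                             ("C" * 21, "chr1", 171, 192, "+", 3)])
        assert len(loci) == 1

    def test_tags_beyond_max_space_split(self):
        loci = extract_loci([("A" * 21, "chr1", 100, 121, "+", 5),
                             ("C" * 21, "chr1", 521, 542, "+", 3)])
        assert len(loci) == 2

    def test_opposite_strands_never_merge(self):
        loci = extract_loci([("A" * 21, "chr1", 100, 121, "+", 5),
                             ("C" * 21, "chr1", 130, 151, "-", 3)])
        assert len(loci) == 2

    def test_most_abundant_tag_is_mature(self):
        loci = extract_loci([("A" * 21, "chr1", 100, 121, "+", 5),
                             ("C" * 21, "chr1", 150, 171, "+", 50)])
        assert loci[0].mature[0] == "C" * 21

    def test_abundance_tie_breaks_five_prime(self):
        loci = extract_loci([("C" * 21, "chr1", 150, 171, "+", 5),
                             ("A" * 21, "chr1", 100, 121, "+", 5)])
        assert loci[0].mature[1] == 100
        minus = extract_loci([("C" * 21, "chr1", 150, 171, "-", 5),
                              ("A" * 21, "chr1", 100, 121, "-", 5)])
        assert minus[0].mature[1] == 150  # 5'-most on the minus strand


class TestEvaluateDuplex:
    def test_clean_hairpin_passes(self):
        precursor = "GGGGG" + MATURE + "CACACACACACA" + STAR + "GGGGG"
        cand = _candidate(precursor, MATURE)
        assert cand.passed, cand.failures
        assert cand.duplex_pairs >= 16
        assert cand.mfe <= -18

    def test_too_few_duplex_pairs_fails(self):
        # explicit duplex structure with exactly 15 of 21 positions paired
        precursor = MATURE + "CACACACACACA" + STAR
        n = len(MATURE)
        unpaired = {3, 6, 9, 12, 15, 18}
        structure = ["."] * len(precursor)
        for i in range(n):
            if i not in unpaired:
                structure[i] = "("
                structure[len(precursor) - 1 - i] = ")"
        cand = HairpinCandidate(
            locus=Locus("chr1", "+", 0, n, []), chrom="chr1", start=0,
            end=len(precursor), strand="+", precursor_seq=precursor,
            structure="".join(structure), mfe=-30.0, mature_seq=MATURE,
            mature_offset=0)
        cand = evaluate_duplex(cand, PredictorConfig())
        assert not cand.passed
        assert cand.failures == ("min_duplex_pairs",)
        assert cand.duplex_pairs == 15

    def test_weak_mfe_fails(self):
        precursor = "GGGGG" + MATURE + "CACACACACACA" + STAR + "GGGGG"
        config = PredictorConfig(max_mfe=-200.0)
        cand = _candidate(precursor, MATURE, config)
        assert "max_mfe" in cand.failures

    def test_no_star_arm(self):
        precursor = "AAAAA" + "A" * 21 + "AAAAAAAA"
        cand = _candidate(precursor, "A" * 21)
        assert not cand.passed
        assert "no_star_arm" in cand.failures

    def test_mature_length_bounds(self):
        precursor = "GGGGG" + MATURE + "CACACACACACA" + STAR + "GGGGG"
        config = PredictorConfig(min_mirna_len=22, max_mirna_len=25)
        cand = _candidate(precursor, MATURE, config)
        assert "mature_len" in cand.failures

    def test_threshold_monotonicity(self, default_run):
        """Tightening any bound never turns a failing candidate into a
        passing one (and the passing set shrinks)."""
        base = PredictorConfig()
        passing = [c for c in default_run.candidates if c.passed]
        assert passing
        for tighter in (
                dataclasses.replace(base, min_duplex_pairs=20),
                dataclasses.replace(base, max_bulge=1),
                dataclasses.replace(base, max_asymmetry=1),
                dataclasses.replace(base, max_mfe=-150.0),
                dataclasses.replace(base, min_mirna_len=22)):
            for cand in passing:
                clone = dataclasses.replace(cand)
                evaluate_duplex(clone, tighter)
            failing = [c for c in default_run.candidates if not c.passed
                       and c.structure
                       and c.failures != ("repeat_overlap",)]
            for cand in failing:
                clone = dataclasses.replace(cand)
                evaluate_duplex(clone, tighter)
                assert not clone.passed


class TestPostFilters:
    def _decoy_candidates(self, default_run):
        truth = default_run.truth.decoy_truth.set_index("mature_seq")
        out = {}
        for cand in default_run.candidates:
            if cand.mature_seq in truth.index:
                out[truth.loc[cand.mature_seq, "kind"]] = \
                    out.get(truth.loc[cand.mature_seq, "kind"], []) + [cand]
        return out

    def test_every_decoy_rejected_for_its_planted_flaw(self, default_run):
        expected_reason = {"low_reads": "min_reads",
                           "multi_locus": "multi_locus",
                           "both_strand": "both_strand",
                           "repeat_overlap": "repeat_overlap"}
        by_kind = self._decoy_candidates(default_run)
        for kind, reason in expected_reason.items():
            for cand in by_kind.get(kind, []):
                assert not cand.passed
                assert reason in cand.failures, (kind, cand.failures)
        for cand in by_kind.get("unstructured", []):
            assert not cand.passed
            assert set(cand.failures) & {"min_duplex_pairs", "max_bulge",
                                         "max_asymmetry", "no_star_arm",
                                         "max_mfe", "max_space"}

    def test_low_read_decoys_may_vanish_but_never_pass(self, default_run):
        """A low-read decoy can draw zero reads and produce no candidate
        at all; it must never be called."""
        called = set(default_run.novel_report.mature_seq)
        for seq in default_run.truth.decoy_truth.mature_seq:
            assert seq not in called

    def test_planted_novels_recovered(self, default_run):
        planted = set(default_run.truth.novel_truth.mature_seq)
        called = set(default_run.novel_report.mature_seq)
        assert planted <= called

    def test_star_support_flags(self, default_run):
        """Planted hairpins emitted with star reads are flagged; the two
        planted without star sources are not."""
        truth = default_run.truth.novel_truth.set_index("mature_seq")
        report = default_run.novel_report.set_index("mature_seq")
        for seq, row in truth.iterrows():
            if seq in report.index:
                assert bool(report.loc[seq, "star_supported"]) == \
                    bool(row.star_supported)
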