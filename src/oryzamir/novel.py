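"""Novel miRNA prediction from unannotated mapped tags.

The predictor follows the classic hairpin-excision recipe: cluster
unannotated same-strand tags into loci (max miRNA/miRNA* spacing 300 nt),
take the most abundant tag as the mature candidate, excise candidate
precursor windows on both sides, fold them, and demand a canonical
miRNA/miRNA* duplex: mature length 18-25 nt, precursor MFE <= -18
kcal/mol, >= 16 duplex base pairs, bulge <= 4 nt, duplex asymmetry <= 4
nt, mature-star spacing <= 300 nt.  Surviving candidates then pass four
post-filters: >= 5 supporting reads, a single genomic locus, no
opposite-strand read stack over the precursor, and no repeat-annotation
overlap.  A Dicer-consistency check additionally requires >= 50% of locus
reads to share the mature 5' end.

All read-count and locus predicates are cheap and run before any folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .annotate import AlignmentHit, FeatureSet
from .fold import fold as _bundled_fold, pair_table
from .seqio import TagTable, to_rna, revcomp_dna, to_dna

#: precursor window spans tried on each side of the mature candidate
WINDOW_SPANS = (60, 150, 300)


@dataclass(frozen=True)
class PredictorConfig:
    min_mirna_len: int = 18
    max_mirna_len: int = 25
    max_mfe: float = -18.0  # kcal/mol
    max_space: int = 300  # nt between miRNA and miRNA*
    min_duplex_pairs: int = 16
    max_bulge: int = 4  # nt
    max_asymmetry: int = 4  # nt
    flank_len: int = 20  # nt
    min_reads: int = 5
    dicer_mode_frac: float = 0.5

    def __post_init__(self):
        if self.min_mirna_len > self.max_mirna_len:
            raise ValueError("min_mirna_len > max_mirna_len")
        if self.max_mfe >= 0:
            raise ValueError("max_mfe must be negative")


@dataclass
class Locus:
    chrom: str
    strand: str
    start: int
    end: int
    tags: list = field(default_factory=list)  # (seq, start, end, reads)

    @property
    def mature(self):
        """Most abundant tag; ties go to the 5'-most placement."""
        def key(t):
            seq, start, end, reads = t
            five_prime = start if self.strand == "+" else -end
            return (-reads, five_prime, seq)
        return min(self.tags, key=key)

    def total_reads(self) -> int:
        return sum(t[3] for t in self.tags)

    def mode_fraction(self) -> float:
        """Share of locus reads whose 5' end matches the mature tag's."""
        _, m_start, m_end, _ = self.mature
        mode5 = m_start if self.strand == "+" else m_end
        total = self.total_reads()
        if total == 0:
            return 0.0
        share = sum(r for s, st, en, r in self.tags
                    if (st if self.strand == "+" else en) == mode5)
        return share / total


@dataclass
class HairpinCandidate:
    locus: Locus
    chrom: str = ""
    start: int = 0  # precursor window, 0-based half-open, genome coords
    end: int = 0
    strand: str = "+"
    precursor_seq: str = ""
    structure: str = ""
    mfe: float = 0.0
    mature_seq: str = ""
    mature_offset: int = 0  # on precursor
    star_offset: int = -1
    star_end: int = -1
    duplex_pairs: int = 0
    bulge_max: int = 0
    asymmetry: int = 0
    loop_space: int = 0
    passed: bool = False
    failures: tuple = ()
    n_genomic_loci: int = 1
    both_strand: bool = False
    repeat_overlap: bool = False
    star_supported: bool = False

    @property
    def star_seq(self) -> str:
        if self.star_offset < 0:
            return ""
        return self.precursor_seq[self.star_offset:self.star_end]


def extract_loci(tag_loci, max_space: int = 300) -> list[Locus]:
    """Cluster same-strand tags within ``max_space`` nt into loci.

    ``tag_loci`` is an iterable of (seq, chrom, start, end, strand, reads).
    """
    entries = sorted(tag_loci, key=lambda t: (t[1], t[4], t[2], t[3], t[0]))
    loci: list[Locus] = []
    for seq, chrom, start, end, strand, reads in entries:
        cur = loci[-1] if loci else None
        if (cur is not None and cur.chrom == chrom and cur.strand == strand
                and start - cur.end <= max_space):
            cur.end = max(cur.end, end)
            cur.tags.append((seq, start, end, reads))
        else:
            loci.append(Locus(chrom, strand, start, end,
                              [(seq, start, end, reads)]))
    return loci


def evaluate_duplex(cand: HairpinCandidate,
                    config: PredictorConfig) -> HairpinCandidate:
    """Apply the duplex criteria to a folded candidate.

    The star arm is the set of partners of the mature positions in the MFE
    structure, extended by the canonical 2-nt 3' overhang.  Bulge is the
    longest unpaired run on either duplex strand; asymmetry is the absolute
    difference of the two strands' unpaired totals.
    """
    failures = []
    m_len = len(cand.mature_seq)
    if not config.min_mirna_len <= m_len <= config.max_mirna_len:
        failures.append("mature_len")
    if cand.mfe > config.max_mfe:
        failures.append("max_mfe")
    pt = pair_table(cand.structure)
    i, j = cand.mature_offset, cand.mature_offset + m_len - 1
    partners = {p: pt[p] for p in range(i, j + 1)
                if p in pt and not i <= pt[p] <= j}
    if not partners:
        cand.failures = tuple(failures + ["no_star_arm"])
        cand.passed = False
        return cand
    s_lo = min(partners.values())
    s_hi = max(partners.values())
    # 2-nt 3' overhang on the star arm
    if s_lo > j:  # star downstream of mature
        s_hi = min(s_hi + 2, len(cand.precursor_seq) - 1)
        space = s_lo - j - 1
    else:
        s_lo = max(s_lo - 2, 0)
        space = i - s_hi - 1
    cand.star_offset, cand.star_end = s_lo, s_hi + 1
    cand.duplex_pairs = len(partners)
    cand.loop_space = max(space, 0)

    def runs(span, is_paired):
        longest = run = unpaired = 0
        for p in span:
            if is_paired(p):
                run = 0
            else:
                run += 1
                unpaired += 1
                longest = max(longest, run)
        return longest, unpaired

    run_m, un_m = runs(range(i, j + 1), lambda p: p in partners)
    run_s, un_s = runs(range(s_lo, s_hi + 1),
                       lambda p: i <= pt.get(p, -1) <= j)
    cand.bulge_max = max(run_m, run_s)
    cand.asymmetry = abs(un_m - un_s)
    if cand.duplex_pairs < config.min_duplex_pairs:
        failures.append("min_duplex_pairs")
    if cand.bulge_max > config.max_bulge:
        failures.append("max_bulge")
    if cand.asymmetry > config.max_asymmetry:
        failures.append("max_asymmetry")
    if cand.loop_space > config.max_space:
        failures.append("max_space")
    cand.failures = tuple(failures)
    cand.passed = not failures
    return cand


def excise_and_fold(genome: dict, locus: Locus, config: PredictorConfig,
                    fold_fn=_bundled_fold) -> HairpinCandidate:
    """Scan candidate precursor windows on both sides of the mature tag.

    For each span in ``WINDOW_SPANS`` a window extending that far beyond
    the mature on one side (plus ``flank_len`` on both) is excised, folded
    and evaluated.  Among passing windows the one with the most duplex
    pairs wins (ties to the lower MFE): the genuine Dicer duplex out-pairs
    incidental pairings of the mature into flanking sequence.  With no
    passing window the lowest-MFE candidate is reported with its failures.
    """
    seq = genome[locus.chrom]
    m_seq, m_start, m_end, _ = locus.mature
    best = None
    best_pass = None
    for side in ("left", "right"):
        for span in WINDOW_SPANS:
            if side == "left":
                w_start = m_start - span - config.flank_len
                w_end = m_end + config.flank_len
            else:
                w_start = m_start - config.flank_len
                w_end = m_end + span + config.flank_len
            w_start, w_end = max(w_start, 0), min(w_end, len(seq))
            window = seq[w_start:w_end]
            if locus.strand == "+":
                rna = to_rna(window)
                off = m_start - w_start
            else:
                rna = to_rna(revcomp_dna(window))
                off = w_end - m_end
            if off < 0 or off + len(m_seq) > len(rna):
                continue
            structure, mfe = fold_fn(rna)
            cand = HairpinCandidate(
                locus=locus, chrom=locus.chrom, start=w_start, end=w_end,
                strand=locus.strand, precursor_seq=rna, structure=structure,
                mfe=mfe, mature_seq=m_seq, mature_offset=off)
            cand = evaluate_duplex(cand, config)
            if cand.passed:
                if (best_pass is None
                        or (cand.duplex_pairs, -cand.mfe)
                        > (best_pass.duplex_pairs, -best_pass.mfe)):
                    best_pass = cand
            elif best is None or cand.mfe < best.mfe:
                best = cand
    if best_pass is not None:
        return best_pass
    if best is None:
        raise ValueError(f"no foldable window at locus "
                         f"{locus.chrom}:{locus.start}-{locus.end}")
    return best


def _genome_span(cand: HairpinCandidate, lo: int, hi: int) -> tuple[int, int]:
    """Map a precursor interval [lo, hi) to genome coordinates."""
    if cand.strand == "+":
        return cand.start + lo, cand.start + hi
    return cand.end - hi, cand.end - lo


def predict_novel(table: TagTable, hits_by_tag: dict, n_hits: dict,
                  categories: dict, features: FeatureSet, genome: dict,
                  config: PredictorConfig | None = None,
                  fold_fn=_bundled_fold):
    """Run the full predictor; returns ``(report_frame, candidates)``.

    ``candidates`` contains every locus that survived the cheap filters,
    with its duplex evaluation; the report frame holds only the called
    novel miRNAs (named Osa-1, Osa-2, ... in genome order).
    """
    config = config or PredictorConfig()
    eligible = [seq for seq, cat in categories.items()
                if cat in ("no_annotation", "siRNA") and hits_by_tag.get(seq)]
    tag_loci = []
    for seq in eligible:
        rep = hits_by_tag[seq][0]
        tag_loci.append((seq, rep.chrom, rep.start, rep.end, rep.strand,
                         table.total_reads(seq)))
    loci = extract_loci(tag_loci, config.max_space)

    # opposite-strand stacks over any mapped tag (not just eligible ones)
    from intervaltree import IntervalTree
    strand_trees: dict = {}
    for hits in hits_by_tag.values():
        if hits:
            rep = hits[0]
            strand_trees.setdefault((rep.chrom, rep.strand),
                                    IntervalTree()).addi(rep.start, rep.end)

    candidates = []
    for locus in loci:
        m_seq, m_start, m_end, _ = locus.mature
        cheap_failures = []
        if table.total_reads(m_seq) < config.min_reads:
            cheap_failures.append("min_reads")
        if n_hits.get(m_seq, 0) != 1:
            cheap_failures.append("multi_locus")
        other = strand_trees.get(
            (locus.chrom, "-" if locus.strand == "+" else "+"))
        both = bool(other and other.overlap(m_start - config.flank_len,
                                            m_end + config.flank_len))
        if both:
            cheap_failures.append("both_strand")
        if locus.mode_fraction() < config.dicer_mode_frac:
            cheap_failures.append("dicer_mode")
        if cheap_failures:
            cand = HairpinCandidate(locus=locus, chrom=locus.chrom,
                                    strand=locus.strand, mature_seq=m_seq,
                                    failures=tuple(cheap_failures))
            cand.n_genomic_loci = n_hits.get(m_seq, 0)
            cand.both_strand = both
            candidates.append(cand)
            continue
        cand = excise_and_fold(genome, locus, config, fold_fn)
        cand.n_genomic_loci = n_hits.get(m_seq, 0)
        cand.both_strand = both
        if cand.passed:
            g_lo, g_hi = cand.start, cand.end
            cand.repeat_overlap = any(
                f.ftype == "repeat_region"
                for f in features.overlapping(cand.chrom, g_lo, g_hi))
            if cand.repeat_overlap:
                cand.failures = ("repeat_overlap",)
                cand.passed = False
        candidates.append(cand)

    called = [c for c in candidates if c.passed]
    called.sort(key=lambda c: (c.chrom, c.start, c.strand))
    rows = []
    lib_cols = table.libraries
    for idx, cand in enumerate(called, start=1):
        cand.star_supported = star_support(cand, hits_by_tag, table)
        counts = table.counts.get(cand.mature_seq)
        row = {
            "id": f"Osa-{idx}", "chrom": cand.chrom, "start": cand.start,
            "end": cand.end, "strand": cand.strand,
            "mature_seq": cand.mature_seq, "star_seq": cand.star_seq,
            "mfe": cand.mfe, "duplex_pairs": cand.duplex_pairs,
            "bulge_max": cand.bulge_max, "asymmetry": cand.asymmetry,
            "loop_space": cand.loop_space,
            "star_supported": cand.star_supported,
        }
        for li, lib in enumerate(lib_cols):
            row[f"count_{lib}"] = int(counts[li]) if counts is not None else 0
        rows.append(row)
    report = pd.DataFrame(rows)
    return report, candidates


def star_support(cand: HairpinCandidate, hits_by_tag: dict,
                 table: TagTable, slack: int = 6) -> bool:
    """True when at least one read maps within the star region.

    The region is padded by ``slack`` nt on both sides: the structural
    star span excludes duplex positions the MFE structure leaves unpaired,
    so a genuine star read can begin a few nt outside it.
    """
    if cand.star_offset < 0:
        return False
    g_lo, g_hi = _genome_span(cand, cand.star_offset, cand.star_end)
    for seq, hits in hits_by_tag.items():
        if seq == cand.mature_seq or table.total_reads(seq) == 0:
            continue
        for hit in hits:
            if (hit.chrom == cand.chrom and hit.strand == cand.strand
                    and hit.start >= g_lo - slack
                    and hit.end <= g_hi + slack):
                return True
    return False
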