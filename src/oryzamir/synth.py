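"""Synthetic small-RNA study generator with fully known planted truth.

Builds a toy rice-like reference (default 200 kb) carrying known miRNA
hairpins, novel hairpins that satisfy every predictor criterion (verified
at generation time against the predictor itself), single-flaw decoy loci,
structural-RNA / repeat / mRNA contaminant loci, double-stranded siRNA
regions and diffuse intergenic background, then emits four adapter-ligated
FASTQ libraries (one per grain-filling stage: 5, 7, 12 and 17 DAF).

The emission model is multinomial: every read source (a specific insert
sequence) carries an expected TPM per stage, the per-stage TPMs sum to
exactly 1e6, and a library of depth ``D`` is a single multinomial draw of
``D`` reads over the sources.  Planted editing sites split their parent
miRNA's reads binomially at the planted per-site rate.  Planted
fold changes between adjacent stages are encoded in the per-stage TPM
profiles.  Everything is deterministic for a fixed seed.

Default study conditions: 30 known miRNAs on a geometric abundance grid
(100-12000 TPM), 10 novel hairpins, 10 decoys, 8 planted fold changes of
|log2FC| in {2,3} with at least 100 expected reads on the low side, six
editing sites (including a dominant A->U at position 14 and one position-1
site), a 24-then-21 nt bimodal length profile with >= 85% of reads in the
20-24 nt window, ~9% unmappable reads, and 1e5 reads per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import Feature, FeatureSet, GenomeIndex
from .known import MiRNARecord, star_region
from .novel import (Locus, PredictorConfig, _genome_span, excise_and_fold)


def _novel_genome_span(cand):
    return _genome_span(cand, cand.star_offset, cand.star_end)
from .seqio import to_rna, to_dna, revcomp_dna

STAGES = ("5DAF", "7DAF", "12DAF", "17DAF")
_NT = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# insert-length distributions (sharp = siRNA-like 24-nt classes,
# mid = degraded structural/mRNA fragments); keys are lengths in nt
LEN_PMF_SHARP = {18: .002, 19: .003, 20: .04, 21: .03, 22: .05, 23: .08,
                 24: .72, 25: .035, 26: .015, 27: .01, 28: .008, 29: .004,
                 30: .003}
LEN_PMF_MID = {18: .02, 19: .025, 20: .07, 21: .12, 22: .14, 23: .14,
               24: .33, 25: .055, 26: .04, 27: .025, 28: .02, 29: .01,
               30: .005}
LEN_PMF_SIRNA = {21: .2, 22: .1, 23: .15, 24: .55}

#: decoy kinds; each decoy is planted to fail exactly the named predicate
DECOY_KINDS = ("low_reads", "low_reads", "multi_locus", "multi_locus",
               "both_strand", "both_strand", "repeat_overlap",
               "repeat_overlap", "unstructured", "unstructured")

# per-stage expected TPM mass per contaminant class
CLASS_MASS = {
    "rRNA": 50_000.0, "tRNA": 20_000.0, "snRNA": 3_000.0, "snoRNA": 3_000.0,
    "repeat": 220_000.0, "exon_sense": 40_000.0, "exon_antisense": 30_000.0,
    "intron_sense": 25_000.0, "intron_antisense": 20_000.0,
    "siRNA": 40_000.0, "unmapped": 90_000.0,
}
CLASS_SOURCES = {
    "rRNA": 400, "tRNA": 100, "snRNA": 40, "snoRNA": 40, "repeat": 800,
    "exon_sense": 250, "exon_antisense": 200, "intron_sense": 180,
    "intron_antisense": 150, "siRNA": 160, "unmapped": 600,
}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    genome_length: int = 200_000
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 10
    n_decoys: int = 10
    n_contaminant_loci: dict = field(default_factory=lambda: {
        "rRNA": 2, "tRNA": 4, "snRNA": 3, "snoRNA": 3, "repeat": 6,
        "mRNA": 3})
    n_sirna_regions: int = 8
    n_background_regions: int = 120
    n_background_sources: int = 3000
    library_depths: tuple = (100_000, 100_000, 100_000, 100_000)
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    seed: int = 0
    #: optional overrides; None selects the built-in study conditions
    stage_tpm_profiles: dict | None = None
    planted_de: tuple | None = None
    editing_plan: tuple | None = None
    sequencing_error: float = 0.0

    def validate(self) -> None:
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be positive")
        if len(self.adapter3) < 8:
            raise ValueError("3' adapter too short")
        if not 0 <= self.sequencing_error <= 1:
            raise ValueError("sequencing_error outside [0,1]")
        if self.editing_plan:
            for _, pos, _, rate in self.editing_plan:
                if not 0 <= rate <= 1:
                    raise ValueError("editing rate outside [0,1]")
                if pos < 1:
                    raise ValueError("editing position is 1-based")


@dataclass
class SyntheticTruth:
    stages: tuple
    locus_table: pd.DataFrame
    expression: pd.DataFrame        # expected source TPM per stage (matures)
    mature_expected: pd.DataFrame   # expected observed mature TPM (after edits)
    de_truth: pd.DataFrame
    editing_truth: pd.DataFrame
    novel_truth: pd.DataFrame
    decoy_truth: pd.DataFrame
    sources: pd.DataFrame


def _rand_dna(rng, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _rand_loop(rng, n: int) -> str:
    # A/C-only loop: cannot pair internally under the WC/GU rules
    return "".join(np.array(["A", "C"])[rng.integers(0, 2, n)])


def _rand_mature(rng, adapter3: str, n: int = 21) -> str:
    """Random mature avoiding the adapter seed (and its revcomp, which
    would surface in the star-arm reads) so trimming is never ambiguous."""
    seed = to_dna(adapter3)[:8]
    rc = revcomp_dna(seed)
    while True:
        m = _rand_dna(rng, n)
        if seed not in m and rc not in m:
            return m


def _sample_len(rng, pmf: dict) -> int:
    ks = list(pmf)
    ps = np.array([pmf[k] for k in ks])
    return int(rng.choice(ks, p=ps / ps.sum()))


def _hairpin_block(rng, mature_dna: str, arm: str, flank: int = 20,
                   loop_len: int = 12, star_mismatches: int = 2):
    """(block, mature_offset, star_seq, star_offset) for a stem hairpin.

    The star arm is the reverse complement of the mature carrying two
    non-pairing substitutions (real stems are imperfect, and a perfect
    stem would make mature and star reads map to both arms on both
    strands, falsely tripping the multi-locus and both-strand filters).
    A substituted star base copies its mature partner, which pairs with
    nothing under the WC/GU rules, leaving 19 of 21 duplex pairs.
    """
    star = list(revcomp_dna(mature_dna))
    n = len(mature_dna)
    pos_pool = list(range(3, n - 4))
    for p in sorted(rng.choice(pos_pool, size=star_mismatches,
                               replace=False).tolist()):
        # star position p faces mature position n-1-p
        star[p] = mature_dna[n - 1 - p]
    star = "".join(star)
    loop = _rand_loop(rng, loop_len)
    f5, f3 = _rand_dna(rng, flank), _rand_dna(rng, flank)
    if arm == "5p":
        block = f5 + mature_dna + loop + star + f3
        return block, flank, star, flank + n + loop_len
    block = f5 + star + loop + mature_dna + f3
    return block, flank + n + loop_len, star, flank


def _default_known_profiles(n: int):
    """Per-miRNA expected TPM per stage encoding the planted fold changes.

    Returns (profiles: id->np.array(4), de_plan, editing_plan, spike_ids).
    """
    base = np.geomspace(12_000.0, 100.0, n)
    ids = [f"osa-miR9{i:03d}" for i in range(n)]
    profiles = {mid: np.full(4, b) for mid, b in zip(ids, base)}
    # planted DE: (id, transition index, log2fc); low side >= 100 expected
    # reads at the default 1e5 depth in every case
    de_plan = [(ids[2], 0, 2.0), (ids[3], 0, 2.0), (ids[8], 0, 3.0),
               (ids[5], 1, 2.0), (ids[9], 1, 2.0), (ids[11], 2, 2.0),
               (ids[4], 2, -2.0), (ids[6], 2, -2.0)]
    for mid, t, fc in de_plan:
        profiles[mid][t + 1:] *= 2.0 ** fc
    # stage-preferential spikes (ratio > 2, Z > 2 archetypes)
    spikes = []
    if n > 28:
        profiles[ids[27]] = profiles[ids[27]] * np.array([1, 8, 1, 1.0])
        profiles[ids[28]] = profiles[ids[28]] * np.array([1, 1, 1, 8.0])
        spikes = [(ids[27], "7DAF"), (ids[28], "17DAF")]
    # planted editing: (id, 1-based position, alt, rate); parents are
    # flat-profile miRNAs so substitution-type fractions are stable
    editing = [(ids[0], 14, "U", 0.7), (ids[12], 2, None, 0.3),
               (ids[13], 3, None, 0.5), (ids[14], 8, None, 0.3),
               (ids[15], 1, None, 0.2), (ids[16], 14, None, 0.15)]
    return ids, profiles, de_plan, editing, spikes


def build_reference(config: SyntheticConfig):
    """Generate genome, annotations, references and planted truth.

    Returns ``(genome, features, mature, precursors, truth)`` where
    ``genome`` maps chromosome -> DNA sequence, ``features`` is the GFF3
    annotation set, and ``mature``/``precursors`` are RNA-alphabet
    reference dicts.  Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chr1"
    n_known = config.n_known_mirnas

    ids, profiles, de_plan, editing_plan, spikes = _default_known_profiles(
        max(n_known, 1))
    ids = ids[:n_known]
    profiles = {k: profiles[k] for k in ids}
    de_plan = [d for d in de_plan if d[0] in profiles]
    spikes = [s for s in spikes if s[0] in profiles]
    if config.editing_plan is not None:
        editing_plan = list(config.editing_plan)
    else:
        editing_plan = [e for e in editing_plan if e[0] in profiles]
    if config.planted_de is not None:
        de_plan = list(config.planted_de)
        profiles = {mid: np.full(4, v) for mid, v in zip(
            ids, np.geomspace(12_000.0, 100.0, max(n_known, 1)))}
        for mid, t, fc in de_plan:
            profiles[mid][t + 1:] *= 2.0 ** fc
    if config.stage_tpm_profiles is not None:
        profiles = {k: np.asarray(v, dtype=float)
                    for k, v in config.stage_tpm_profiles.items()}
        ids = list(profiles)

    # ---- draw known mature sequences (edit-site refs constrained) --------
    forced = {mid: (pos, alt) for mid, pos, alt, _ in editing_plan}

    def draw_mature(mid: str) -> str:
        seq = _rand_mature(rng, config.adapter3)
        if mid in forced:
            pos, alt = forced[mid]
            if alt is not None:
                # make sure the reference base differs from the planted alt
                ref = "A" if alt == "U" else "T"
                seq = seq[:pos - 1] + ref + seq[pos:]
        return seq

    mature_dna: dict[str, str] = {mid: draw_mature(mid) for mid in ids}

    # ---- assemble the genome block by block ------------------------------
    segments: list[str] = []
    cursor = 0
    features: list[Feature] = []
    locus_rows: list[dict] = []

    def place(seq: str, cls: str | None = None, fid: str = "",
              strand: str = "+") -> int:
        nonlocal cursor
        segments.append(seq)
        start = cursor
        cursor += len(seq)
        if cursor > config.genome_length:
            raise GenerationError(
                f"genome_length={config.genome_length} exhausted while "
                f"placing {cls or 'gap'} loci")
        if cls:
            locus_rows.append({"class": cls, "chrom": chrom, "start": start,
                               "end": start + len(seq), "strand": strand,
                               "id": fid})
        return start

    def gap():
        place(_rand_dna(rng, 375))

    precursors_rna: dict[str, str] = {}
    mature_rna: dict[str, str] = {}
    known_records: list[MiRNARecord] = []
    known_spans: dict[str, tuple] = {}
    star_by_mid: dict[str, str] = {}

    for i, mid in enumerate(ids):
        arm = "5p" if i % 2 == 0 else "3p"
        for attempt in range(40):
            block, m_off, star_seq, _ = _hairpin_block(
                rng, mature_dna[mid], arm)
            rec = MiRNARecord(mid, to_rna(mature_dna[mid]), f"{mid}-pre",
                              to_rna(block), m_off, arm)
            try:
                star_region(rec)
            except ValueError:
                mature_dna[mid] = draw_mature(mid)
                continue
            break
        else:
            raise GenerationError(f"could not build a valid hairpin for {mid}")
        gap()
        start = place(block, "pre_miRNA", f"{mid}-pre")
        features.append(Feature(chrom, start, start + len(block), "+",
                                "pre_miRNA", f"{mid}-pre"))
        features.append(Feature(chrom, start + m_off,
                                start + m_off + 21, "+", "miRNA", mid))
        precursors_rna[f"{mid}-pre"] = to_rna(block)
        mature_rna[mid] = to_rna(mature_dna[mid])
        known_records.append(rec)
        known_spans[mid] = (start, start + len(block), start + m_off)
        star_by_mid[mid] = star_seq

    # novel hairpins and decoys; their genome slots are filled now and the
    # hairpins are re-validated (and re-drawn in place) against the real
    # genome context below
    novel_slots: list[dict] = []
    for j in range(config.n_novel_hairpins):
        nid = f"novel{j}"
        strand = "+" if j % 2 == 0 else "-"
        m = _rand_mature(rng, config.adapter3)
        block, m_off, star_seq, _ = _hairpin_block(rng, m, "5p")
        placed = block if strand == "+" else revcomp_dna(block)
        gap()
        start = place(placed, "novel", nid, strand)
        novel_slots.append({"id": nid, "seg_index": len(segments) - 1,
                            "start": start, "strand": strand,
                            "mature": m, "m_off": m_off, "star": star_seq,
                            "block_len": len(block)})

    decoy_rows: list[dict] = []
    decoy_slots: list[dict] = []
    multi_seqs: list[str] = []
    for j, kind in enumerate(DECOY_KINDS[:config.n_decoys]):
        did = f"decoy{j}_{kind}"
        m = _rand_mature(rng, config.adapter3)
        if kind == "unstructured":
            block = _rand_dna(rng, 20) + m + _rand_dna(rng, 54)
            m_off = 20
        else:
            block, m_off, _, _ = _hairpin_block(rng, m, "5p")
        gap()
        start = place(block, "decoy", did)
        slot = {"id": did, "kind": kind, "seg_index": len(segments) - 1,
                "start": start, "mature": m, "m_off": m_off,
                "block_len": len(block)}
        if kind == "multi_locus":
            gap()
            place(block, "decoy", did + "_copy")
        if kind == "repeat_overlap":
            # repeat annotation over loop + star arm, clear of the mature
            rep_lo = start + m_off + 25
            features.append(Feature(chrom, rep_lo, rep_lo + 30, "+",
                                    "repeat_region", did + "_rep"))
        decoy_slots.append(slot)
        decoy_rows.append({"id": did, "kind": kind, "mature_seq": to_rna(m)})

    # contaminant loci
    contaminant_spans: dict[str, list] = {}
    counts_by_class = config.n_contaminant_loci
    sizes = {"rRNA": 1500, "tRNA": 80, "snRNA": 150, "snoRNA": 120,
             "repeat": 600}
    for cls, n_loci in counts_by_class.items():
        for k in range(n_loci):
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if cls == "mRNA":
                gene_parts = [("exon", 200), ("intron", 300), ("exon", 200),
                              ("intron", 300), ("exon", 200)]
                gap()
                for p, (ftype, ln) in enumerate(gene_parts):
                    fid = f"mRNA{k}_{ftype}{p}"
                    start = place(_rand_dna(rng, ln), ftype, fid, strand)
                    features.append(Feature(chrom, start, start + ln, strand,
                                            ftype, fid))
                    contaminant_spans.setdefault(ftype, []).append(
                        (start, start + ln, strand))
            else:
                ln = sizes[cls]
                fid = f"{cls}{k}"
                gap()
                start = place(_rand_dna(rng, ln), cls, fid, strand)
                ftype = "repeat_region" if cls == "repeat" else cls
                features.append(Feature(chrom, start, start + ln, strand,
                                        ftype, fid))
                contaminant_spans.setdefault(cls, []).append(
                    (start, start + ln, strand))

    sirna_spans = []
    for k in range(config.n_sirna_regions):
        gap()
        start = place(_rand_dna(rng, 150), "sirna_region", f"sir{k}")
        sirna_spans.append((start, start + 150))

    background_spans = []
    for k in range(config.n_background_regions):
        gap()
        start = place(_rand_dna(rng, 160), "background", f"bg{k}")
        background_spans.append((start, start + 160))

    # paralog locus for the genomic-flag guard: the edited form of the
    # fourth editing site also exists in the genome
    guard_block_index = None
    guard_entry = editing_plan[3] if len(editing_plan) > 3 else None
    if guard_entry is not None:
        gap()
        place(_rand_dna(rng, 21), "edited_paralog", "paralog0")
        guard_block_index = len(segments) - 1

    gap()
    tail = config.genome_length - cursor
    if tail > 0:
        place(_rand_dna(rng, tail))
    genome = {chrom: "".join(segments)}

    # ---- re-validate planted novels in their real genome context ---------
    pred_cfg = PredictorConfig()

    def predictor_call(slot):
        strand = slot.get("strand", "+")
        if strand == "+":
            m_start = slot["start"] + slot["m_off"]
        else:
            m_start = slot["start"] + slot["block_len"] - slot["m_off"] - 21
        m_end = m_start + 21
        m_seq = to_rna(slot["mature"])  # the tag as sequenced
        locus = Locus(chrom, strand, m_start, m_end,
                      [(m_seq, m_start, m_end, 10)])
        return excise_and_fold(genome, locus, pred_cfg)

    def hairpin_passes(slot) -> bool:
        """True when the predictor recovers the hairpin with the planted
        star arm (a spurious duplex against flanking sequence can pass
        the criteria on the wrong side; such draws are rejected)."""
        strand = slot.get("strand", "+")
        cand = predictor_call(slot)
        if not cand.passed:
            return False
        # planted star arm: flank + mature + loop downstream of the
        # mature on the transcript (5p-arm construction)
        star_lo_block = slot["m_off"] + 21 + 12
        if strand == "+":
            p_lo = slot["start"] + star_lo_block
        else:
            p_lo = slot["start"] + slot["block_len"] - star_lo_block - 21
        p_hi = p_lo + 21
        g_lo, g_hi = _novel_genome_span(cand)
        return min(g_hi, p_hi) - max(g_lo, p_lo) >= 10

    def redraw(slot, hairpin=True):
        m = _rand_mature(rng, config.adapter3)
        if hairpin:
            block, m_off, star_seq, _ = _hairpin_block(rng, m, "5p")
            slot["star"] = star_seq
        else:
            block = _rand_dna(rng, 20) + m + _rand_dna(rng, 54)
            m_off = 20
        slot["mature"], slot["m_off"] = m, m_off
        placed = block if slot.get("strand", "+") == "+" \
            else revcomp_dna(block)
        segments[slot["seg_index"]] = placed
        genome[chrom] = "".join(segments)

    for slot in novel_slots + [s for s in decoy_slots
                               if s["kind"] == "repeat_overlap"]:
        for attempt in range(40):
            if hairpin_passes(slot):
                break
            redraw(slot)
        else:
            raise GenerationError(
                f"hairpin {slot['id']} failed predictor criteria "
                f"after bounded retries")
    # unstructured decoys must genuinely fail the duplex stage: a random
    # 21-mer occasionally finds an incidental qualifying duplex in its
    # flanking sequence, so verify and redraw until it does not
    for slot in decoy_slots:
        if slot["kind"] != "unstructured":
            continue
        for attempt in range(40):
            if not predictor_call(slot).passed:
                break
            redraw(slot, hairpin=False)
        else:
            raise GenerationError(
                f"decoy {slot['id']} kept passing the duplex criteria "
                f"after bounded retries")
    for slot in decoy_slots:  # keep the truth table in sync with redraws
        for row in decoy_rows:
            if row["id"] == slot["id"]:
                row["mature_seq"] = to_rna(slot["mature"])

    index = GenomeIndex(genome)

    # splice the guard paralog now that the editing parent's sequence is
    # final (the paralog block length matches the placed placeholder)
    if guard_entry is not None:
        mid, pos, alt, _ = guard_entry
        if mid in mature_rna:
            mseq = mature_rna[mid]
            ref = mseq[pos - 1]
            alt = alt or _other_nt(rng, ref)
            editing_plan[3] = (mid, pos, alt, guard_entry[3])
            edited = mseq[:pos - 1] + alt + mseq[pos:]
            segments[guard_block_index] = to_dna(edited)
            genome[chrom] = "".join(segments)
            index = GenomeIndex(genome)

    # ---- build the source table ------------------------------------------
    g = genome[chrom]
    sources: list[dict] = []

    def add_source(sid, kind, seq_dna, tpm, mirna="", edit_rate=0.0,
                   edited_seq="", edit_pos=0, edit_ref="", edit_alt=""):
        row = {"source_id": sid, "kind": kind, "seq": seq_dna,
               "mirna": mirna, "edit_rate": edit_rate,
               "edited_seq": edited_seq, "edit_pos": edit_pos,
               "edit_ref": edit_ref, "edit_alt": edit_alt}
        for s, stage in enumerate(STAGES):
            row[f"tpm_{stage}"] = float(tpm[s])
        sources.append(row)

    editing_rows = []
    edit_by_mirna = {}
    for mid, pos, alt, rate in editing_plan:
        if mid not in mature_rna:
            continue
        mseq = mature_rna[mid]
        ref = mseq[pos - 1]
        if alt is None:
            alt = _other_nt(rng, ref)
        edited = mseq[:pos - 1] + alt + mseq[pos:]
        edit_by_mirna[mid] = (rate, edited, pos, ref, alt)
        editing_rows.append({"miRNA": mid, "position": pos, "ref": ref,
                             "alt": alt, "rate": rate,
                             "edited_seq": edited,
                             "genomic": index.contains(edited)})

    mature_expected_rows = {}
    for mid in ids:
        tpm = profiles[mid]
        rate = edit_by_mirna.get(mid, (0.0,))[0]
        if mid in edit_by_mirna:
            rate, edited, pos, ref, alt = edit_by_mirna[mid]
            add_source(f"mat_{mid}", "known_mature", mature_dna[mid], tpm,
                       mirna=mid, edit_rate=rate, edited_seq=to_dna(edited),
                       edit_pos=pos, edit_ref=ref, edit_alt=alt)
        else:
            add_source(f"mat_{mid}", "known_mature", mature_dna[mid], tpm,
                       mirna=mid)
        mature_expected_rows[mid] = tpm * (1.0 - rate)

    for mid in ids[:6]:
        add_source(f"star_{mid}", "known_star", star_by_mid[mid],
                   np.maximum(profiles[mid] / 20.0, 20.0), mirna=mid)
    if len(ids) > 1:
        # dominant +1/+1 isomiR of the second miRNA
        pre = to_dna(precursors_rna[f"{ids[1]}-pre"])
        off = pre.find(mature_dna[ids[1]])
        variant = pre[off + 1:off + 1 + 21]
        add_source(f"var_{ids[1]}", "known_variant", variant,
                   profiles[ids[1]] * 1.5, mirna=ids[1])
    if len(ids) > 3:
        # two-mismatch junk near the fourth miRNA: must never be called
        m = mature_dna[ids[3]]
        junk = _mutate(rng, _mutate(rng, m, 5), 15)
        if not index.contains(junk):
            add_source("junk_2mm", "two_mismatch", junk,
                       np.full(4, 60.0), mirna=ids[3])

    novel_rows = []
    novel_mult = np.array([0.5, 1.0, 1.5, 1.0])
    for j, slot in enumerate(novel_slots):
        tag = slot["mature"]  # already the tag as sequenced
        add_source(f"mat_{slot['id']}", "novel_mature", tag,
                   400.0 * novel_mult)
        if j < 8:
            add_source(f"star_{slot['id']}", "novel_star", slot["star"],
                       np.full(4, 50.0))
        novel_rows.append({"id": slot["id"], "mature_seq": to_rna(tag),
                           "chrom": chrom, "start": slot["start"],
                           "end": slot["start"] + slot["block_len"],
                           "strand": slot["strand"],
                           "star_supported": j < 8})

    for slot in decoy_slots:
        kind = slot["kind"]
        tpm = np.full(4, 2.5) if kind == "low_reads" else np.full(4, 400.0)
        add_source(f"mat_{slot['id']}", f"decoy_{kind}", slot["mature"], tpm)
        if kind == "both_strand":
            g = genome[chrom]
            m_start = slot["start"] + slot["m_off"]
            anti = revcomp_dna(g[m_start - 2:m_start + 20])
            add_source(f"anti_{slot['id']}", "decoy_antisense", anti,
                       np.full(4, 100.0))

    # contaminant fragment sources
    lens = {"rRNA": LEN_PMF_MID, "tRNA": LEN_PMF_MID, "snRNA": LEN_PMF_MID,
            "snoRNA": LEN_PMF_MID, "repeat": LEN_PMF_SHARP,
            "exon_sense": LEN_PMF_MID, "exon_antisense": LEN_PMF_MID,
            "intron_sense": LEN_PMF_MID, "intron_antisense": LEN_PMF_MID}
    span_map = {"rRNA": "rRNA", "tRNA": "tRNA", "snRNA": "snRNA",
                "snoRNA": "snoRNA", "repeat": "repeat",
                "exon_sense": "exon", "exon_antisense": "exon",
                "intron_sense": "intron", "intron_antisense": "intron"}
    for cls, n_src in CLASS_SOURCES.items():
        if cls in ("siRNA", "unmapped"):
            continue
        spans = contaminant_spans.get(span_map[cls], [])
        if not spans:
            continue
        weights = rng.lognormal(0.0, 1.2, n_src)
        weights = weights / weights.sum() * CLASS_MASS[cls]
        for si in range(n_src):
            lo, hi, strand = spans[int(rng.integers(0, len(spans)))]
            ln = min(_sample_len(rng, lens[cls]), hi - lo)
            off = int(rng.integers(lo, hi - ln + 1))
            frag = g[off:off + ln]
            sense_seq = frag if strand == "+" else revcomp_dna(frag)
            seq = (revcomp_dna(sense_seq) if cls.endswith("antisense")
                   else sense_seq)
            add_source(f"{cls}_{si}", cls, seq, np.full(4, weights[si]))

    # siRNA duplex fragments: sense/antisense pairs with a 2-nt offset
    w = rng.lognormal(0.0, 1.0, CLASS_SOURCES["siRNA"])
    w = w / w.sum() * CLASS_MASS["siRNA"]
    for si in range(0, CLASS_SOURCES["siRNA"], 2):
        lo, hi = sirna_spans[int(rng.integers(0, len(sirna_spans)))]
        ln = _sample_len(rng, LEN_PMF_SIRNA)
        off = int(rng.integers(lo, hi - ln - 2))
        add_source(f"sirna_{si}", "siRNA", g[off:off + ln],
                   np.full(4, w[si]))
        add_source(f"sirna_{si + 1}", "siRNA",
                   revcomp_dna(g[off + 2:off + 2 + ln]),
                   np.full(4, w[si + 1]))

    # unmappable reads (unassembled-genome stand-ins)
    w = rng.lognormal(0.0, 1.0, CLASS_SOURCES["unmapped"])
    w = w / w.sum() * CLASS_MASS["unmapped"]
    for si in range(CLASS_SOURCES["unmapped"]):
        for attempt in range(20):
            seq = _rand_dna(rng, _sample_len(rng, LEN_PMF_SHARP))
            if not index.contains(seq):
                break
        add_source(f"unm_{si}", "unmapped", seq, np.full(4, w[si]))

    # intergenic background fills each stage's remaining mass exactly
    fixed = np.zeros(4)
    for row in sources:
        fixed += np.array([row[f"tpm_{s}"] for s in STAGES])
    remainder = 1e6 - fixed
    if np.any(remainder <= 0):
        raise GenerationError("expected TPM mass exceeds 1e6; lower the "
                              "planted profiles or contaminant masses")
    n_bg = config.n_background_sources
    wmat = np.zeros((n_bg, 4))
    base_w = rng.lognormal(0.0, 1.0, n_bg)
    for si in range(n_bg):
        if si % 3 == 0:
            wmat[si, :] = base_w[si]          # shared across stages
        else:
            wmat[si, si % 4] = base_w[si]     # stage-exclusive
    wmat = wmat / wmat.sum(axis=0, keepdims=True) * remainder
    for si in range(n_bg):
        lo, hi = background_spans[int(rng.integers(0,
                                                   len(background_spans)))]
        ln = _sample_len(rng, LEN_PMF_SHARP)
        off = int(rng.integers(lo, hi - ln + 1))
        add_source(f"bg_{si}", "background", g[off:off + ln], wmat[si])

    source_frame = pd.DataFrame(sources)
    mass = source_frame[[f"tpm_{s}" for s in STAGES]].sum()
    assert np.allclose(mass, 1e6), "per-stage TPM mass must be exactly 1e6"

    de_rows = [{"miRNA": mid, "transition": f"{STAGES[t]}->{STAGES[t + 1]}",
                "log2fc": fc, "direction": "up" if fc > 0 else "down"}
               for mid, t, fc in de_plan if mid in profiles]
    truth = SyntheticTruth(
        stages=STAGES,
        locus_table=pd.DataFrame(locus_rows),
        expression=pd.DataFrame({mid: profiles[mid] for mid in ids},
                                index=list(STAGES)).T,
        mature_expected=pd.DataFrame(mature_expected_rows,
                                     index=list(STAGES)).T,
        de_truth=pd.DataFrame(de_rows),
        editing_truth=pd.DataFrame(editing_rows),
        novel_truth=pd.DataFrame(novel_rows),
        decoy_truth=pd.DataFrame(decoy_rows),
        sources=source_frame,
    )
    return genome, FeatureSet(features), mature_rna, precursors_rna, truth


def _other_nt(rng, ref: str) -> str:
    choices = [c for c in "ACGU" if c != ref]
    return choices[int(rng.integers(0, 3))]


def _mutate(rng, dna: str, pos0: int) -> str:
    choices = [c for c in "ACGT" if c != dna[pos0]]
    return dna[:pos0] + choices[int(rng.integers(0, 3))] + dna[pos0 + 1:]


def emit_libraries(truth: SyntheticTruth, config: SyntheticConfig, outdir):
    """Emit one FASTQ per stage plus a per-source provenance table.

    Per-stage counts are one multinomial draw of the configured depth over
    the expected-TPM vector; planted editing sites split their parent's
    draw binomially at the planted rate.  Every read carries the full 3'
    adapter and constant Q40 qualities.  Returns ``(paths, provenance)``.
    """
    import os
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng([config.seed, 1])
    src = truth.sources
    seqs = src["seq"].tolist()
    edit_rates = src["edit_rate"].to_numpy()
    edited_seqs = src["edited_seq"].tolist()
    paths = {}
    prov_rows = []
    for s, stage in enumerate(truth.stages):
        depth = int(config.library_depths[s])
        if depth <= 0:
            raise ValueError(f"depth for stage {stage} must be positive")
        tpms = src[f"tpm_{stage}"].to_numpy(dtype=float)
        counts = rng.multinomial(depth, tpms / tpms.sum())
        path = os.path.join(outdir, f"{stage}.fastq")
        with open(path, "w") as out:
            for si in range(len(src)):
                n = int(counts[si])
                if n == 0:
                    continue
                n_edit = 0
                if edit_rates[si] > 0:
                    n_edit = int(rng.binomial(n, edit_rates[si]))
                sid = src.at[si, "source_id"]
                _write_reads(out, sid, seqs[si], n - n_edit,
                             config.adapter3, rng, config.sequencing_error)
                if n_edit:
                    _write_reads(out, sid + ".ed", edited_seqs[si], n_edit,
                                 config.adapter3, rng,
                                 config.sequencing_error)
                prov_rows.append({"source_id": sid, "stage": stage,
                                  "reads": n, "edited_reads": n_edit})
        paths[stage] = path
    provenance = pd.DataFrame(prov_rows)
    return paths, provenance


def _write_reads(out, sid, insert_dna, n, adapter3, rng, err_rate):
    read = insert_dna + adapter3
    qual = "I" * len(read)
    if err_rate <= 0:
        for i in range(n):
            out.write(f"@{sid}:{i}\n{read}\n+\n{qual}\n")
        return
    for i in range(n):
        seq = read
        n_err = rng.binomial(len(seq), err_rate)
        for _ in range(int(n_err)):
            p = int(rng.integers(0, len(seq)))
            seq = _mutate(rng, seq, p)
        out.write(f"@{sid}:{i}\n{seq}\n+\n{qual}\n")
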