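"""Known-miRNA profiling: exact mature matching, isomiRs and miRNA* stacks.

A miRNA is "detected" in a library when its mature sequence is sequenced
at least once there.  Reads landing elsewhere on the precursor build a
:class:`PrecursorStack`, from which +/-2 nt isomiR variants and the
star-arm species (located via the 2-nt 3' overhang duplex geometry) are
profiled.  Mature entries sharing an identical sequence are collapsed to
one family identifier, so a read is never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fold import fold, pair_table
from .seqio import TagTable, to_rna


@dataclass(frozen=True)
class MiRNARecord:
    mature_id: str
    mature_seq: str  # RNA
    precursor_id: str
    precursor_seq: str  # RNA
    mature_offset: int  # 0-based on precursor
    arm: str  # 5p / 3p

    def __post_init__(self):
        end = self.mature_offset + len(self.mature_seq)
        if self.precursor_seq[self.mature_offset:end] != self.mature_seq:
            raise ValueError(
                f"{self.mature_id}: mature not at stated precursor offset")


@dataclass
class PrecursorStack:
    """All tags mapping (as exact substrings) onto one precursor."""

    precursor_id: str
    entries: list = field(default_factory=list)  # (tag, offset, counts_vec)

    def total_mass(self) -> int:
        return int(sum(vec.sum() for _, _, vec in self.entries))


def read_fasta(path) -> dict:
    """id -> RNA-alphabet sequence."""
    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n{seq}\n")


def build_records(mature: dict, precursors: dict) -> list[MiRNARecord]:
    """Pair mature sequences with their precursors (miRBase-style FASTA).

    A mature id of the form ``<precursor_id>-5p/-3p`` (or equal to the
    precursor id) is matched by name; otherwise the first precursor that
    contains the mature sequence is used.  Duplicate mature ids are an
    error.
    """
    if len(set(mature)) != len(mature):
        raise ValueError("duplicate mature ids")
    records = []
    for mid, mseq in mature.items():
        stem = mid.rsplit("-5p", 1)[0].rsplit("-3p", 1)[0]
        candidates = [pid for pid in precursors
                      if pid == stem or pid.startswith(stem)]
        pid = None
        for cand in candidates + sorted(precursors):
            if mseq in precursors[cand]:
                pid = cand
                break
        if pid is None:
            raise ValueError(f"no precursor contains mature {mid}")
        off = precursors[pid].find(mseq)
        arm = "5p" if off < (len(precursors[pid]) - off - len(mseq)) else "3p"
        records.append(MiRNARecord(mid, mseq, pid, precursors[pid], off, arm))
    return records


def collapse_families(records: list[MiRNARecord]) -> dict:
    """Map mature sequence -> collapsed id (ids of identical matures joined)."""
    by_seq: dict[str, list[str]] = {}
    for rec in records:
        by_seq.setdefault(rec.mature_seq, []).append(rec.mature_id)
    return {seq: "/".join(sorted(set(ids))) for seq, ids in by_seq.items()}


def known_match_set(table: TagTable, records: list[MiRNARecord]) -> set:
    """Tags matching a mature sequence or any precursor substring exactly."""
    matures = {rec.mature_seq for rec in records}
    precursors = {rec.precursor_seq for rec in records}
    matched = set()
    for seq in table.counts:
        if seq in matures or any(seq in p for p in precursors):
            matched.add(seq)
    return matched


def match_known(table: TagTable, records: list[MiRNARecord]):
    """Exact-match mature counts per library.

    Returns ``(count_frame, detected)``: a DataFrame indexed by collapsed
    miRNA id with one raw-count column per library, and the per-library
    sets of detected ids (count > 0).
    """
    if not records:
        raise ValueError("empty reference set")
    families = collapse_families(records)
    rows = {}
    for seq, fam_id in sorted(families.items(), key=lambda kv: kv[1]):
        vec = table.counts.get(seq)
        rows[fam_id] = (vec if vec is not None
                        else np.zeros(len(table.libraries), dtype=np.int64))
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=table.libraries, dtype=np.int64)
    frame.index.name = "miRNA"
    detected = {lib: set(frame.index[frame[lib] > 0])
                for lib in table.libraries}
    return frame, detected


def shared_fraction(detected: dict) -> tuple[int, int, float]:
    """(shared, union, percentage) of ids detected in every library."""
    sets = list(detected.values())
    shared = set.intersection(*sets)
    union = set.union(*sets)
    pct = 100 * len(shared) / len(union) if union else 0.0
    return len(shared), len(union), pct


def build_stacks(table: TagTable, records: list[MiRNARecord]) -> dict:
    """PrecursorStack per precursor id from exact substring placements."""
    stacks = {}
    precursors = {}
    for rec in records:
        precursors[rec.precursor_id] = rec.precursor_seq
        stacks.setdefault(rec.precursor_id,
                          PrecursorStack(rec.precursor_id))
    for seq, vec in table.counts.items():
        for pid, pseq in precursors.items():
            off = pseq.find(seq)
            if off >= 0:
                stacks[pid].entries.append((seq, off, vec))
    for stack in stacks.values():
        stack.entries.sort(key=lambda e: (e[1], e[0]))
    return stacks


def detect_variants(stack: PrecursorStack, record: MiRNARecord,
                    max_shift: int = 2) -> pd.DataFrame:
    """IsomiRs: tags whose ends sit within +/-2 nt of the mature ends.

    Returns a frame with the 5'/3' shifts and read counts; rows where the
    variant out-masses the annotated mature are flagged ``variant_dominant``.
    """
    m_start = record.mature_offset
    m_end = m_start + len(record.mature_seq)  # half-open
    mature_mass = 0
    rows = []
    for tag, off, vec in stack.entries:
        if tag == record.mature_seq and off == m_start:
            mature_mass = int(vec.sum())
    for tag, off, vec in stack.entries:
        shift5 = off - m_start
        shift3 = (off + len(tag)) - m_end
        if (shift5, shift3) == (0, 0):
            continue
        if abs(shift5) <= max_shift and abs(shift3) <= max_shift:
            rows.append({"tag": tag, "shift5": shift5, "shift3": shift3,
                         "reads": int(vec.sum()),
                         "variant_dominant": int(vec.sum()) > mature_mass})
    return pd.DataFrame(rows, columns=["tag", "shift5", "shift3", "reads",
                                       "variant_dominant"])


def star_region(record: MiRNARecord, structure: str | None = None,
                overhang: int = 2) -> tuple[int, int]:
    """Star-arm interval (0-based half-open) on the precursor.

    Computed from the folded precursor assuming the canonical Dicer duplex
    with 2-nt 3' overhangs: the star spans the partner of (mature 3' end -
    2) through the partner of the mature 5' end + 2.  Raises ``ValueError``
    when the mature arm is unpaired or the star falls off the precursor.
    """
    if structure is None:
        structure, _ = fold(record.precursor_seq)
    pt = pair_table(structure)
    i = record.mature_offset
    j = i + len(record.mature_seq) - 1

    def partner_near(pos, lo, hi):
        for delta in range(0, hi - lo + 1):
            for cand in (pos + delta, pos - delta):
                if lo <= cand <= hi and cand in pt:
                    return pt[cand]
        return None

    p_end = partner_near(j - overhang, i, j)
    p_start = partner_near(i, i, j)
    if p_end is None or p_start is None:
        raise ValueError(f"{record.mature_id}: mature arm is unpaired")
    lo, hi = sorted((p_end, p_start + overhang))
    if lo < 0 or hi + 1 > len(record.precursor_seq):
        raise ValueError(f"{record.mature_id}: star region outside precursor")
    return lo, hi + 1


def star_ratio(stack: PrecursorStack, record: MiRNARecord,
               structure: str | None = None, slack: int = 2):
    """(mature mass, star mass, star_dominant flag, star/mature ratio).

    Star mass counts reads whose placement falls within the star interval
    extended by ``slack`` nt on both sides.
    """
    s_lo, s_hi = star_region(record, structure)
    m_start = record.mature_offset
    m_end = m_start + len(record.mature_seq)
    mature_mass = star_mass = 0
    for tag, off, vec in stack.entries:
        end = off + len(tag)
        if off == m_start and tag == record.mature_seq:
            mature_mass += int(vec.sum())
        elif off >= s_lo - slack and end <= s_hi + slack:
            star_mass += int(vec.sum())
    ratio = star_mass / mature_mass if mature_mass else float("inf")
    return mature_mass, star_mass, star_mass > mature_mass, ratio
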