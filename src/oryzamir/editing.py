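"""miRNA editing detection by one-mismatch alignment to mature references.

An editing event is a population of reads identical in length to a mature
miRNA but differing from it at exactly one position (Hamming distance 1).
Reads identical to the mature feed the reference (unedited) count; reads
at distance >= 2 are ignored.  Events are summarized into a 12-type
substitution x position tally, their cross-library rate consistency is
tested by one-way ANOVA on per-read outcomes, and edited sequences that
map perfectly elsewhere in the genome are flagged as possible paralogs or
SNPs rather than editing (mirroring a genomic-DNA control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

NUCLEOTIDES = "ACGU"
#: the 12 ordered substitution types, A->C first
SUBSTITUTION_TYPES = [f"{a}->{b}" for a, b in permutations(NUCLEOTIDES, 2)]


@dataclass
class EditingEvent:
    mirna: str
    position: int  # 1-based from the mature 5' end
    ref: str
    alt: str
    edited: np.ndarray  # per-library edited read counts
    reference: np.ndarray  # per-library unedited read counts
    genomic_flag: bool = False
    tags: list = field(default_factory=list)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a substitution")

    @property
    def subtype(self) -> str:
        return f"{self.ref}->{self.alt}"

    def rates(self) -> np.ndarray:
        denom = self.edited + self.reference
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, self.edited / denom, np.nan)

    def pooled_rate(self) -> float:
        denom = int(self.edited.sum() + self.reference.sum())
        return float(self.edited.sum()) / denom if denom else float("nan")

    def edited_sequence(self, mature_seq: str) -> str:
        pos = self.position - 1
        return mature_seq[:pos] + self.alt + mature_seq[pos + 1:]


def _single_mismatch(tag: str, ref: str):
    """(position 1-based, ref nt, alt nt) if Hamming distance is exactly 1."""
    if len(tag) != len(ref):
        return None
    found = None
    for i, (a, b) in enumerate(zip(ref, tag)):
        if a != b:
            if found is not None:
                return None
            found = (i + 1, a, b)
    return found


def scan_editing(unannotated_counts: dict, mature: dict,
                 mature_counts: pd.DataFrame | None, libraries: list,
                 min_reads: int = 5) -> list[EditingEvent]:
    """One-mismatch scan of unannotated tags against mature references.

    ``unannotated_counts`` maps tag sequence -> per-library count vector;
    ``mature_counts`` (rows indexed by miRNA id) supplies the reference
    (unedited) counts.  An event is kept when its total edited count over
    all libraries reaches ``min_reads``.
    """
    nlib = len(libraries)
    by_len: dict[int, list] = {}
    for mid in sorted(mature):
        by_len.setdefault(len(mature[mid]), []).append(mid)
    accum: dict = {}
    for tag in sorted(unannotated_counts):
        vec = np.asarray(unannotated_counts[tag], dtype=np.int64)
        for mid in by_len.get(len(tag), ()):
            hit = _single_mismatch(tag, mature[mid])
            if hit is None:
                continue
            key = (mid, *hit)
            entry = accum.setdefault(key, [np.zeros(nlib, np.int64), []])
            entry[0] += vec
            entry[1].append(tag)
    events = []
    for (mid, pos, ref, alt), (edited, tags) in sorted(accum.items()):
        if int(edited.sum()) < min_reads:
            continue
        if mature_counts is not None and mid in mature_counts.index:
            reference = mature_counts.loc[mid].to_numpy(dtype=np.int64)
        else:
            reference = np.zeros(nlib, np.int64)
        events.append(EditingEvent(mid, pos, ref, alt, edited, reference,
                                   tags=tags))
    return events


def tally(events: list[EditingEvent], libraries: list,
          max_position: int = 30):
    """Substitution-type and position tallies of edited reads.

    Returns ``(type_frame, position_frame, fractions)``: per-library read
    counts by substitution type, per-library read counts by position, and
    the per-library fraction of edited reads carried by each type
    (columns sum to 1 where any events exist).
    """
    type_frame = pd.DataFrame(0, index=SUBSTITUTION_TYPES, columns=libraries,
                              dtype=np.int64)
    pos_frame = pd.DataFrame(0, index=range(1, max_position + 1),
                             columns=libraries, dtype=np.int64)
    for ev in events:
        type_frame.loc[ev.subtype] += ev.edited
        pos_frame.loc[ev.position] += ev.edited
    sums = type_frame.sum(axis=0)
    fractions = type_frame / sums.replace(0, np.nan)
    return type_frame, pos_frame, fractions


def dominant_type(type_frame: pd.DataFrame) -> dict:
    """Per-library dominant substitution type and its read fraction."""
    out = {}
    for lib in type_frame.columns:
        col = type_frame[lib]
        total = int(col.sum())
        if total == 0:
            out[lib] = (None, 0.0)
        else:
            top = col.idxmax()
            out[lib] = (top, col[top] / total)
    return out


def consistency_anova(event: EditingEvent, min_depth: int = 2) -> float:
    """One-way ANOVA p-value on per-read edited/unedited outcomes.

    Each library is one group of Bernoulli observations (1 = edited).
    Libraries with fewer than ``min_depth`` reads are excluded; fewer than
    two usable groups is an error.
    """
    groups = []
    for e, r in zip(event.edited.tolist(), event.reference.tolist()):
        if e + r >= min_depth:
            groups.append(np.concatenate([np.ones(e), np.zeros(r)]))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two libraries with reads")
    stat, pval = stats.f_oneway(*groups)
    if np.isnan(pval):  # zero within-group variance and equal means
        return 1.0
    return float(pval)


def edited_variant_guard(events: list[EditingEvent], mature: dict,
                         genome_index) -> None:
    """Flag events whose edited sequence maps perfectly to the genome.

    A perfect genomic locus for the edited form suggests a paralog or SNP
    rather than post-transcriptional editing; events are flagged in place,
    not removed.
    """
    for ev in events:
        edited_seq = ev.edited_sequence(mature[ev.mirna])
        ev.genomic_flag = genome_index.contains(edited_seq)


def events_frame(events: list[EditingEvent], libraries: list,
                 anova: bool = True) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {"miRNA": ev.mirna, "position": ev.position, "ref": ev.ref,
               "alt": ev.alt, "genomic_flag": ev.genomic_flag,
               "pooled_rate": ev.pooled_rate()}
        for li, lib in enumerate(libraries):
            row[f"edited_{lib}"] = int(ev.edited[li])
            row[f"reference_{lib}"] = int(ev.reference[li])
            rates = ev.rates()
            row[f"rate_{lib}"] = float(rates[li])
        if anova:
            try:
                row["anova_p"] = consistency_anova(ev)
            except ValueError:
                row["anova_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
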