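"""Reading, trimming and collapsing of small-RNA sequencing libraries.

Reads come in as adapter-ligated FASTQ (DNA, Phred+33).  After 3' adapter
removal, quality and length filtering (18-30 nt), every surviving insert is
normalized to the RNA alphabet (T -> U) and collapsed to unique tags with
one read count per library.  The :class:`TagTable` is the container every
downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

_RC = str.maketrans("ACGTUN", "TGCAAN")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


@dataclass
class TrimStats:
    """Per-reason tallies of reads discarded during cleaning."""

    total_reads: int = 0
    clean: int = 0
    low_quality: int = 0
    no_adapter: int = 0
    too_short: int = 0
    too_long: int = 0
    ambiguous: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def load_fastq(path, adapter3: str, min_len: int = MIN_TAG_LEN,
               max_len: int = MAX_TAG_LEN, min_qual: int = 20):
    """Trim the 3' adapter and filter reads from one FASTQ library.

    The adapter is located by an exact search for its first 8 nt anywhere in
    the read; adapter-free reads are kept only when they already sit inside
    the length window.  Reads with any base below ``min_qual`` are dropped
    as low quality, and inserts containing N are dropped as ambiguous.

    Returns ``(clean_tags, stats)`` where ``clean_tags`` is a list of
    RNA-alphabet insert sequences (one entry per read).
    """
    adapter3 = to_dna(adapter3)
    if len(adapter3) < 6:
        raise ValueError("3' adapter must be at least 6 nt")
    seed = adapter3[:8]
    stats = TrimStats()
    clean: list[str] = []
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                stats.total_reads += 1
                seq = seq.upper()
                if any(ord(q) - 33 < min_qual for q in qual):
                    stats.low_quality += 1
                    continue
                pos = seq.find(seed)
                if pos >= 0:
                    insert = seq[:pos]
                elif min_len <= len(seq) <= max_len:
                    insert = seq
                else:
                    stats.no_adapter += 1
                    continue
                if "N" in insert:
                    stats.ambiguous += 1
                elif len(insert) < min_len:
                    stats.too_short += 1
                elif len(insert) > max_len:
                    stats.too_long += 1
                else:
                    clean.append(to_rna(insert))
                    stats.clean += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record near read {stats.total_reads + 1} "
                f"in {path}: {exc}") from exc
    return clean, stats


@dataclass
class TagTable:
    """Unique small-RNA tags with per-library read counts.

    ``counts`` maps RNA-alphabet sequence -> integer count vector ordered
    like ``libraries``; ``totals`` holds the clean-read count per library
    (always the column sums of ``counts``).
    """

    libraries: list[str]
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        for seq in self.counts:
            if not MIN_TAG_LEN <= len(seq) <= MAX_TAG_LEN:
                raise ValueError(f"tag length out of window: {seq}")

    @property
    def totals(self) -> dict:
        sums = np.zeros(len(self.libraries), dtype=np.int64)
        for vec in self.counts.values():
            sums += vec
        return dict(zip(self.libraries, sums.tolist()))

    def count(self, seq: str, library: str) -> int:
        idx = self.libraries.index(library)
        vec = self.counts.get(seq)
        return 0 if vec is None else int(vec[idx])

    def total_reads(self, seq: str) -> int:
        vec = self.counts.get(seq)
        return 0 if vec is None else int(vec.sum())

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            {s: v for s, v in self.counts.items()}, orient="index",
            columns=self.libraries, dtype=np.int64)
        df.index.name = "sequence"
        df.insert(0, "length", [len(s) for s in df.index])
        return df.sort_index()

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "TagTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        libs = [c for c in df.columns if c != "length"]
        counts = {seq: row[libs].to_numpy(dtype=np.int64)
                  for seq, row in df.iterrows()}
        return cls(libraries=libs, counts=counts)

    def write_fasta(self, path) -> None:
        """Export unique tags with count-annotated headers (tagN_xTOTAL)."""
        with open(path, "w") as out:
            for i, seq in enumerate(sorted(self.counts), start=1):
                out.write(f">tag{i}_x{self.total_reads(seq)}\n{seq}\n")


def collapse(clean_per_library: dict) -> TagTable:
    """Collapse per-library clean-read lists into a sparse-union TagTable."""
    libraries = list(clean_per_library)
    counts: dict = {}
    for idx, lib in enumerate(libraries):
        for seq in clean_per_library[lib]:
            vec = counts.get(seq)
            if vec is None:
                vec = counts[seq] = np.zeros(len(libraries), dtype=np.int64)
            vec[idx] += 1
    return TagTable(libraries=libraries, counts=counts)


def length_distribution(table: TagTable) -> pd.DataFrame:
    """Total-read counts per (length, library); rows sum to library totals."""
    lengths = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    mat = pd.DataFrame(0, index=list(lengths), columns=table.libraries,
                       dtype=np.int64)
    mat.index.name = "length"
    for seq, vec in table.counts.items():
        mat.loc[len(seq)] += vec
    return mat


@dataclass
class OverlapSummary:
    """Common/specific unique-tag and total-read tallies for a library pair."""

    lib_a: str
    lib_b: str
    common_unique: int
    specific_a_unique: int
    specific_b_unique: int
    common_reads: int
    specific_a_reads: int
    specific_b_reads: int


def library_overlap(table: TagTable, lib_a: str, lib_b: str) -> OverlapSummary:
    for lib in (lib_a, lib_b):
        if lib not in table.libraries:
            raise KeyError(f"unknown library id {lib!r}")
    ia, ib = table.libraries.index(lib_a), table.libraries.index(lib_b)
    cu = sa = sb = cr = ra = rb = 0
    for vec in table.counts.values():
        a, b = int(vec[ia]), int(vec[ib])
        if a and b:
            cu += 1
            cr += a + b
        elif a:
            sa += 1
            ra += a
        elif b:
            sb += 1
            rb += b
    return OverlapSummary(lib_a, lib_b, cu, sa, sb, cr, ra, rb)
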