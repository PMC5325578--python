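"""Raw degradome read preprocessing.

Degradome (PARE) libraries are single-end reads whose 5' ends mark uncapped
mRNA 5' termini. This module turns raw reads into collapsed, abundance-
normalized clean tags and keeps the library-level accounting (raw tags,
N-filtered, low-quality-filtered, clean tags) that a sequencing summary
table reports.

Abundances are normalized to TP100M, tags per 100 million:
``raw_count / clean_total * 1e8``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

from Bio import SeqIO

TAG_LENGTH_MIN = 20
TAG_LENGTH_MAX = 21

#: a read is low quality when at least this many bases fall below the Phred floor
LOW_QUALITY_MIN_BASES = 3
LOW_QUALITY_PHRED = 20

#: strict threshold for the polyN rule: flagged when the most frequent single
#: base makes up more than this fraction of the sequence
POLYN_FRACTION = 0.70


@dataclass(frozen=True)
class Tag:
    """A collapsed degradome tag: unique sequence, raw count, TP100M."""

    sequence: str
    raw_count: int
    tp100m: float


@dataclass
class LibraryAccounting:
    """Per-library read accounting.

    Invariant: ``filtered_n + filtered_low_quality + clean_tags == raw_tags``.
    Adapter trimming alone never removes a read; trimmed reads whose length
    falls outside [20, 21] nt are counted under ``filtered_low_quality``.
    polyN tags survive filtering (they are a classification label, not a
    filter) and are tallied separately.
    """

    raw_tags: int
    filtered_n: int
    filtered_low_quality: int
    clean_tags: int
    clean_fraction: float
    polyn_count: int = 0
    unique_tag_count: int = 0
    class_counts: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, raw_tags: int, filtered_n: int,
                    filtered_low_quality: int) -> "LibraryAccounting":
        clean = raw_tags - filtered_n - filtered_low_quality
        frac = clean / raw_tags if raw_tags else 0.0
        return cls(raw_tags=raw_tags, filtered_n=filtered_n,
                   filtered_low_quality=filtered_low_quality,
                   clean_tags=clean, clean_fraction=frac)


def clip_adapter(sequence: str, adapter: str) -> str:
    """Trim a 3' adapter from a read.

    The read is truncated at the first exact occurrence of the adapter's
    first 8 nt (a short seed is robust to adapter run-through at the read
    end). Reads without the seed are returned unchanged.
    """
    if len(adapter) < 8:
        raise ValueError(f"adapter must be >= 8 nt, got {len(adapter)}")
    seed = adapter[:8]
    idx = sequence.find(seed)
    return sequence if idx < 0 else sequence[:idx]


def detect_polyN(sequence: str) -> bool:
    """True when a single base makes up strictly more than 70% of the read."""
    if not sequence:
        raise ValueError("empty sequence")
    most = Counter(sequence).most_common(1)[0][1]
    return most / len(sequence) > POLYN_FRACTION


def _is_low_quality(qualities: Optional[Sequence[int]]) -> bool:
    if qualities is None:  # FASTA input: no quality information
        return False
    low = sum(1 for q in qualities if q < LOW_QUALITY_PHRED)
    return low >= LOW_QUALITY_MIN_BASES


def filter_reads(reads: Iterable[Tuple[str, Optional[Sequence[int]]]],
                 length_min: int = TAG_LENGTH_MIN,
                 length_max: int = TAG_LENGTH_MAX,
                 ) -> Tuple[list, LibraryAccounting]:
    """Filter adapter-trimmed reads into clean tags with accounting.

    ``reads`` yields ``(sequence, qualities)`` where qualities is a Phred
    score list or None (FASTA). Reads containing N are counted under
    ``filtered_n``; low-quality reads and reads whose trimmed length is
    outside ``[length_min, length_max]`` under ``filtered_low_quality``.
    """
    clean: list[str] = []
    raw = n_filtered = lowq = polyn = 0
    for seq, quals in reads:
        raw += 1
        seq = seq.upper()
        if "N" in seq:
            n_filtered += 1
            continue
        if _is_low_quality(quals) or not length_min <= len(seq) <= length_max:
            lowq += 1
            continue
        if detect_polyN(seq):
            polyn += 1
        clean.append(seq)
    acc = LibraryAccounting.from_counts(raw, n_filtered, lowq)
    acc.polyn_count = polyn
    return clean, acc


def collapse_tags(sequences: Iterable[str]) -> "dict[str, int]":
    """Collapse a clean tag stream to unique sequences with raw counts.

    Insertion (first-seen) order is preserved so downstream output is
    deterministic.
    """
    counts: dict[str, int] = {}
    for s in sequences:
        counts[s] = counts.get(s, 0) + 1
    return counts


def tp100m(raw_count: int, clean_total: int) -> float:
    """Tags per 100 million: ``raw_count / clean_total * 1e8``."""
    if clean_total < 1:
        raise ValueError("clean_total must be >= 1")
    return raw_count / clean_total * 1e8


def make_tags(counts: "dict[str, int]", clean_total: int) -> list:
    """Attach TP100M normalization to collapsed counts."""
    return [Tag(seq, c, tp100m(c, clean_total)) for seq, c in counts.items()]


def read_fastq(path) -> Iterator[Tuple[str, Optional[Sequence[int]]]]:
    """Yield ``(sequence, phred_qualities)`` from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq), rec.letter_annotations["phred_quality"]


def read_fasta_reads(path) -> Iterator[Tuple[str, None]]:
    """Yield ``(sequence, None)`` from a FASTA file (no qualities)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield str(rec.seq), None


def preprocess_reads(reads, adapter: str,
                     length_min: int = TAG_LENGTH_MIN,
                     length_max: int = TAG_LENGTH_MAX):
    """Full preprocessing: clip adapters, filter, collapse, normalize.

    Returns ``(tags, accounting)`` where tags is a list of :class:`Tag`.
    """
    trimmed = ((clip_adapter(seq, adapter), qual) for seq, qual in reads)
    clean, acc = filter_reads(trimmed, length_min, length_max)
    counts = collapse_tags(clean)
    acc.unique_tag_count = len(counts)
    tags = make_tags(counts, acc.clean_tags) if counts else []
    return tags, acc


def write_collapsed_fasta(tags: Sequence[Tag], path) -> None:
    """Write collapsed tags as FASTA with ``>seq_i_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">seq_{i}_x{t.raw_count}\n{t.sequence}\n")
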