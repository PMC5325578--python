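"""Tag classification against reference sets and transcript mapping.

Clean tags are labeled by the first matching tier of a priority rule —
Rfam-like structural ncRNA first, then GenBank-like ncRNA, then the polyN
composition rule, then transcript (cDNA) matches — so a tag that is both
an rRNA fragment and a transcript substring counts as rRNA. Matching is
exact (tags are only 20-21 nt, so substring search is both correct and
fast); ncRNA matching checks both strands, while transcript mapping is
sense-only because degradome tags derive from the 5' ends of mRNA
cleavage fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .preprocess import Tag, detect_polyN

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LABELS = ("rRNA", "tRNA", "snRNA", "snoRNA", "polyN",
          "cDNA_sense", "cDNA_antisense", "other")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SubstringIndex:
    """Exact-substring lookup over a set of labeled reference sequences.

    Indexes every k-mer (for the tag lengths in use) of every reference
    once; queries are O(1) dictionary hits.
    """

    def __init__(self, references: Mapping[str, str],
                 kmer_lengths: Sequence[int] = (20, 21)):
        self._kmers: Dict[str, List[Tuple[str, int]]] = {}
        self._lengths = tuple(kmer_lengths)
        for ref_id, seq in references.items():
            seq = seq.upper().replace("U", "T")
            for k in self._lengths:
                for i in range(len(seq) - k + 1):
                    self._kmers.setdefault(seq[i:i + k], []).append(
                        (ref_id, i + 1))

    def occurrences(self, tag: str) -> List[Tuple[str, int]]:
        """All (reference_id, 1-based position) exact sense occurrences."""
        return self._kmers.get(tag.upper(), [])

    def contains(self, tag: str) -> bool:
        return tag.upper() in self._kmers


@dataclass
class ReferenceTiers:
    """ncRNA reference sets by tier: tier1 maps class name -> {id: seq}
    (rRNA/tRNA/snRNA/snoRNA), tier2 likewise (typically rRNA/tRNA)."""

    tier1: Mapping[str, Mapping[str, str]]
    tier2: Mapping[str, Mapping[str, str]]

    def __post_init__(self):
        self._indexes = []
        for tier in (self.tier1, self.tier2):
            self._indexes.append(
                {cls: SubstringIndex(refs) for cls, refs in tier.items()})

    def match_class(self, tag: str) -> Optional[str]:
        """First tier/class with an exact match on either strand, or None."""
        rc = reverse_complement(tag)
        for tier_index in self._indexes:
            for cls, index in tier_index.items():
                if index.contains(tag) or index.contains(rc):
                    return cls
        return None


def classify_tag(tag: str, tiers: ReferenceTiers,
                 transcript_index: SubstringIndex) -> str:
    """Label one tag by the priority rule (ncRNA > polyN > cDNA > other)."""
    cls = tiers.match_class(tag)
    if cls is not None:
        return cls
    if detect_polyN(tag):
        return "polyN"
    if transcript_index.contains(tag):
        return "cDNA_sense"
    if transcript_index.contains(reverse_complement(tag)):
        return "cDNA_antisense"
    return "other"


def classify_tags(tags: Iterable[Tag], tiers: ReferenceTiers,
                  transcript_index: SubstringIndex) -> Dict[str, str]:
    """Label every unique tag; returns {sequence: label}."""
    return {t.sequence: classify_tag(t.sequence, tiers, transcript_index)
            for t in tags}


def class_counts(labels: Mapping[str, str],
                 tags: Iterable[Tag]) -> pd.DataFrame:
    """Per-class totals (read-weighted) and unique-tag counts."""
    rows = {lab: {"total": 0, "unique": 0} for lab in LABELS}
    for t in tags:
        lab = labels[t.sequence]
        rows[lab]["total"] += t.raw_count
        rows[lab]["unique"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class"
    return df


def map_tags_to_transcripts(tags: Iterable[Tag],
                            transcript_index: SubstringIndex,
                            ) -> List[Tuple[str, str, int, int]]:
    """All exact sense-strand occurrences of each tag on the transcripts.

    Returns ``(tag_sequence, transcript_id, position, raw_count)`` tuples,
    one per occurrence; multi-mapping tags are reported at every
    occurrence, not resolved.
    """
    hits = []
    for t in tags:
        for tid, pos in transcript_index.occurrences(t.sequence):
            hits.append((t.sequence, tid, pos, t.raw_count))
    return hits


def genome_strand_report(tags: Iterable[Tag],
                         genome: Optional[Mapping[str, str]],
                         ) -> Optional[pd.DataFrame]:
    """Per-chromosome sense/antisense exact-match tag counts.

    Counts are read-weighted (a tag's raw count adds to every chromosome
    it matches). Returns None with no genome.
    """
    if not genome:
        return None
    index = SubstringIndex(genome)
    counts = {chrom: {"sense": 0, "antisense": 0} for chrom in genome}
    for t in tags:
        for chrom in {c for c, _ in index.occurrences(t.sequence)}:
            counts[chrom]["sense"] += t.raw_count
        rc = reverse_complement(t.sequence)
        for chrom in {c for c, _ in index.occurrences(rc)}:
            counts[chrom]["antisense"] += t.raw_count
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "chromosome"
    return df
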