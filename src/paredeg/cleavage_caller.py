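"""Cleavage-site calling from degradome profiles and duplex candidates.

A degradome profile is the per-transcript vector of raw tag counts keyed
by the 5'-end position of each tag. A candidate duplex becomes a called
target when at least one degradome tag starts exactly at its predicted
cleavage site. Each call carries a peak-shape category:

* category 0 — >1 raw tags at the site, site abundance equals the
  transcript maximum, and that maximum is unique;
* category 1 — >1 raw tags, equal to the maximum, but the maximum is
  attained at more than one position;
* category 2 — >1 raw tags, below the maximum but above the median;
* category 3 — >1 raw tags, at or below the median;
* category 4 — exactly 1 raw tag at the site.

The maximum and median are taken over occupied positions only (positions
with at least one tag); including the zero positions would drive the
median to 0 on nearly every transcript and empty category 3.

Significance is an empirical permutation p-value: the miRNA is shuffled
preserving nucleotide composition, each shuffle is re-searched against the
whole transcript set, and a shuffle counts as a success when it yields a
supported call at least as good (score <= observed, category <= observed)
anywhere. With k successes in R shuffles, p = (1 + k) / (1 + R). The null
search considers gapless duplexes only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .target_scoring import DuplexAlignment, scan_best_hits


@dataclass
class DegradomeProfile:
    """Per-transcript 5'-end tag counts and the library size for TP100M."""

    transcript_id: str
    counts: Dict[int, int] = field(default_factory=dict)
    clean_total: int = 0


@dataclass
class TargetRecord:
    """One called miRNA-mRNA pair (one row of a target table)."""

    mirna_id: str
    transcript_id: str
    site: int                  # 1-based position from the cDNA 5' end
    location: str              # CDS / 5UTR / 3UTR
    score: float
    category: int
    tp100m: float
    p_value: Optional[float] = None


def build_profile(hits: Iterable[Tuple[str, int, int]],
                  transcript_id: str, clean_total: int) -> DegradomeProfile:
    """Profile for one transcript from ``(tag_sequence?, position, raw_count)``
    hits; only ``(position, raw_count)`` are used."""
    prof = DegradomeProfile(transcript_id, {}, clean_total)
    for _seq, pos, count in hits:
        prof.counts[pos] = prof.counts.get(pos, 0) + count
    return prof


def build_profiles(mapped: Iterable[Tuple[str, str, int, int]],
                   clean_total: int) -> Dict[str, DegradomeProfile]:
    """Profiles for all transcripts from ``(tag_seq, transcript_id, pos,
    raw_count)`` mapping hits."""
    profs: Dict[str, DegradomeProfile] = {}
    for seq, tid, pos, count in mapped:
        prof = profs.setdefault(tid, DegradomeProfile(tid, {}, clean_total))
        prof.counts[pos] = prof.counts.get(pos, 0) + count
    return profs


def categorize(profile: DegradomeProfile, site: int) -> int:
    """Peak-shape category (0-4) of a supported site; see module docstring."""
    counts = profile.counts
    if site not in counts:
        raise ValueError(
            f"no degradome evidence at {profile.transcript_id}:{site}")
    c = counts[site]
    if c == 1:
        return 4
    values = list(counts.values())
    peak = max(values)
    if c == peak:
        n_max = sum(1 for v in values if v == peak)
        return 0 if n_max == 1 else 1
    return 2 if c > median(values) else 3


def site_location(site: int,
                  cds: Optional[Tuple[int, int]]) -> str:
    """CDS/UTR placement of a site given a (cds_start, cds_end) interval.

    Without an annotation the whole transcript is treated as coding.
    """
    if cds is None:
        return "CDS"
    start, end = cds
    if site < start:
        return "5UTR"
    if site > end:
        return "3UTR"
    return "CDS"


def call_targets(candidates: Iterable[DuplexAlignment],
                 profiles: Mapping[str, DegradomeProfile],
                 cds_annotations: Optional[Mapping[str, Tuple[int, int]]] = None,
                 ) -> list:
    """Turn duplex candidates with degradome support into target records.

    Candidates without a tag starting exactly at the predicted site are
    dropped. When several alignments predict the same (miRNA, transcript,
    site) — e.g. a gapped variant of the same window — the best (lowest)
    score is kept.
    """
    cds_annotations = cds_annotations or {}
    best: Dict[Tuple[str, str, int], DuplexAlignment] = {}
    for cand in candidates:
        key = (cand.mirna_id, cand.transcript_id, cand.site)
        if key not in best or cand.score < best[key].score:
            best[key] = cand
    records = []
    for (mirna_id, tid, site), cand in sorted(best.items()):
        prof = profiles.get(tid)
        if prof is None or site not in prof.counts:
            continue
        count = prof.counts[site]
        records.append(TargetRecord(
            mirna_id=mirna_id, transcript_id=tid, site=site,
            location=site_location(site, cds_annotations.get(tid)),
            score=cand.score,
            category=categorize(prof, site),
            tp100m=count / prof.clean_total * 1e8 if prof.clean_total else 0.0,
        ))
    return records


def _shuffle_preserving_composition(seq: str, rng: random.Random) -> str:
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def pvalue_from_counts(k: int, R: int) -> float:
    """Add-one permutation p-value estimator, p = (1 + k) / (1 + R)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return (1 + k) / (1 + R)


def empirical_pvalue(record: TargetRecord, mirna_seq: str,
                     transcripts: Mapping[str, str],
                     profiles: Mapping[str, DegradomeProfile],
                     shuffles: int = 100, seed: int = 0) -> float:
    """Permutation p-value of one called target.

    Each of ``shuffles`` composition-preserving shuffles of the miRNA is
    scanned (gapless) against every transcript; a shuffle succeeds when it
    attains, at any tag-supported site, a score <= the record's score with
    a category <= the record's category.
    """
    rng = random.Random(seed)
    k = 0
    for _ in range(shuffles):
        shuffled = _shuffle_preserving_composition(mirna_seq, rng)
        if _null_hit(shuffled, transcripts, profiles,
                     record.score, record.category):
            k += 1
    return pvalue_from_counts(k, shuffles)


def _null_hit(mirna_seq: str, transcripts: Mapping[str, str],
              profiles: Mapping[str, DegradomeProfile],
              max_score: float, max_category: int) -> bool:
    for tid, seq in transcripts.items():
        prof = profiles.get(tid)
        if prof is None or not prof.counts:
            continue
        for site, _score in scan_best_hits(mirna_seq, seq, max_score).items():
            if site in prof.counts and categorize(prof, site) <= max_category:
                return True
    return False


def attach_pvalues(records: Sequence[TargetRecord],
                   mirnas: Mapping[str, str],
                   transcripts: Mapping[str, str],
                   profiles: Mapping[str, DegradomeProfile],
                   shuffles: int = 100, seed: int = 0) -> None:
    """Attach permutation p-values to records in place (seeded per record)."""
    for i, rec in enumerate(records):
        rec.p_value = empirical_pvalue(
            rec, mirnas[rec.mirna_id], transcripts, profiles,
            shuffles=shuffles, seed=seed + i)
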