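"""End-to-end degradome analysis: raw reads to called targets.

Chains the stage modules: adapter clipping and quality filtering, tag
collapsing and TP100M normalization, priority-rule classification against
ncRNA references, exact sense mapping to the transcriptome, duplex
candidate search, cleavage calling with peak categories, and optional
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from . import annotate_filter, cleavage_caller, preprocess, target_scoring
from .annotate_filter import ReferenceTiers, SubstringIndex
from .cleavage_caller import DegradomeProfile, TargetRecord
from .preprocess import LibraryAccounting, Tag


@dataclass
class PipelineResult:
    tags: List[Tag]
    accounting: LibraryAccounting
    labels: Dict[str, str]
    profiles: Dict[str, DegradomeProfile]
    records: List[TargetRecord]
    n_candidates: int = 0
    n_unsupported: int = 0
    class_table: Optional[object] = None


def run_pipeline(reads,
                 transcripts: Mapping[str, str],
                 mirnas: Mapping[str, str],
                 adapter: str,
                 ncrna_tier1: Optional[Mapping[str, Mapping[str, str]]] = None,
                 ncrna_tier2: Optional[Mapping[str, Mapping[str, str]]] = None,
                 cds: Optional[Mapping[str, Tuple[int, int]]] = None,
                 max_score: float = target_scoring.DEFAULT_MAX_SCORE,
                 allow_gaps: bool = True,
                 shuffles: int = 0,
                 pval_threshold: Optional[float] = None,
                 seed: int = 0) -> PipelineResult:
    """Run the full analysis on one library.

    ``reads`` yields (sequence, qualities-or-None). With ``shuffles`` > 0,
    permutation p-values are attached and records filtered at
    ``pval_threshold`` when given.
    """
    tags, acc = preprocess.preprocess_reads(reads, adapter)
    transcripts = {tid: seq.upper().replace("U", "T")
                   for tid, seq in transcripts.items()}
    tiers = ReferenceTiers(tier1=ncrna_tier1 or {}, tier2=ncrna_tier2 or {})
    tx_index = SubstringIndex(transcripts)
    labels = annotate_filter.classify_tags(tags, tiers, tx_index)
    class_table = annotate_filter.class_counts(labels, tags)

    # only unannotated, non-polyN, sense-matching tags feed target calling
    mrna_tags = [t for t in tags if labels[t.sequence] == "cDNA_sense"]
    mapped = annotate_filter.map_tags_to_transcripts(mrna_tags, tx_index)
    profiles = cleavage_caller.build_profiles(mapped, acc.clean_tags)

    candidates = []
    for mirna_id, mirna_seq in mirnas.items():
        for tid, seq in transcripts.items():
            candidates.extend(target_scoring.find_candidates(
                mirna_id, mirna_seq, tid, seq,
                max_score=max_score, allow_gaps=allow_gaps))
    records = cleavage_caller.call_targets(candidates, profiles, cds)
    n_unsupported = len({(c.mirna_id, c.transcript_id, c.site)
                         for c in candidates}) - len(records)

    if shuffles > 0:
        cleavage_caller.attach_pvalues(records, dict(mirnas), transcripts,
                                       profiles, shuffles=shuffles, seed=seed)
        if pval_threshold is not None:
            records = [r for r in records if r.p_value <= pval_threshold]

    return PipelineResult(tags=tags, accounting=acc, labels=labels,
                          profiles=profiles, records=records,
                          n_candidates=len(candidates),
                          n_unsupported=n_unsupported,
                          class_table=class_table)
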