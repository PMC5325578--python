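"""Plant miRNA:target duplex scoring and candidate-site search.

Scoring follows the standard plant-pairing penalty scheme: each mismatched
position costs 1, each G:U wobble 0.5, each gapped or bulged position 1,
and every penalty is doubled when the miRNA position falls in the core
region (positions 2-13, counted from the miRNA 5' end). A perfect
Watson-Crick duplex scores 0. Candidate target sites must score at or
below a cutoff (default 7.0) and must be perfectly Watson-Crick paired at
miRNA positions 10 and 11 — the slicing site, since AGO-mediated cleavage
occurs on the target between the bases paired to miRNA nt 10 and 11.

The duplex is antiparallel: miRNA position 1 (5' end) pairs the 3'-most
base of the target window on the transcript's sense strand. The cleavage
site reported for an alignment is the 1-based transcript position of the
base paired to miRNA position 10.

At most one single-nucleotide gap (a target base missing opposite a miRNA
base) or bulge (an extra, unpaired target base) is allowed per duplex.

The search scans every window of the transcript at every gap/bulge
placement; scoring is vectorized with numpy so whole-transcriptome scans
and shuffled-miRNA null scans stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

# pair states, per miRNA position
WC = "WC"
GU = "GU"
MISMATCH = "mismatch"
GAP_TARGET = "gap_target"      # target base missing opposite this miRNA position

CORE_START, CORE_END = 2, 13   # doubled-penalty region, 1-based miRNA coords
CLEAVAGE_POSITIONS = (10, 11)  # must be WC-paired
DEFAULT_MAX_SCORE = 7.0

_PENALTY = {WC: 0.0, GU: 0.5, MISMATCH: 1.0, GAP_TARGET: 1.0}
_BULGE_PENALTY = 1.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# base penalty matrix indexed [mirna_code, target_code]; target is the
# sense-strand DNA of the mRNA (T stands for U)
_PEN = np.ones((4, 4))
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
    _PEN[_m, _t] = 0.0
_PEN[2, 3] = 0.5  # miRNA G : target U
_PEN[3, 2] = 0.5  # miRNA U : target G


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT/U sequence as an int8 array (U mapped to T)."""
    try:
        return np.fromiter((_CODE[c] for c in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGTU character in sequence: {exc}") from exc


def _weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[CORE_START - 1:CORE_END] = 2.0
    return w


def position_weight(position: int) -> float:
    """Penalty multiplier for a 1-based miRNA position."""
    return 2.0 if CORE_START <= position <= CORE_END else 1.0


def pair_state(mirna_base: str, target_base: str) -> str:
    """Pair state of one miRNA base against one sense-strand target base."""
    p = _PEN[_CODE[mirna_base.upper()], _CODE[target_base.upper()]]
    return WC if p == 0 else (GU if p == 0.5 else MISMATCH)


def score_duplex(states: Sequence[str], bulges: Iterable[int] = ()) -> float:
    """Score a duplex from per-position pair states.

    ``states[i]`` is the state of miRNA position ``i + 1``; ``bulges``
    lists the 1-based miRNA positions each extra target base is charged to
    (the position 5' of the insertion point on the miRNA).
    """
    total = 0.0
    for i, st in enumerate(states):
        try:
            pen = _PENALTY[st]
        except KeyError:
            raise ValueError(f"unknown pair state: {st!r}") from None
        total += pen * position_weight(i + 1)
    for pos in bulges:
        total += _BULGE_PENALTY * position_weight(pos)
    return total


@dataclass(frozen=True)
class DuplexAlignment:
    """One scored miRNA:target-site pairing.

    ``start``/``end`` delimit the target window (1-based, inclusive, sense
    strand); ``site`` is the transcript base paired with miRNA position 10.
    """

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    start: int
    end: int
    pair_states: Tuple[str, ...]
    bulges: Tuple[int, ...]
    score: float
    site: int


def _alignment_offsets(L: int, gap_at: Optional[int], bulge_after: Optional[int]):
    """Window offsets paired to each miRNA position for one gap placement.

    Returns ``(window_length, offsets)`` where ``offsets[i]`` is the 0-based
    offset within the window of the target base paired with miRNA position
    ``i + 1``, or None for a gapped position. miRNA position 1 pairs the
    window's 3'-most base (antiparallel duplex).
    """
    if gap_at is not None:
        Lw = L - 1
        offsets = [None if i == gap_at else
                   (Lw - i if i < gap_at else Lw - i + 1)
                   for i in range(1, L + 1)]
    elif bulge_after is not None:
        Lw = L + 1
        offsets = [Lw - i if i <= bulge_after else Lw - i - 1
                   for i in range(1, L + 1)]
    else:
        Lw = L
        offsets = [Lw - i for i in range(1, L + 1)]
    return Lw, offsets


def _families(L: int, allow_gaps: bool):
    """Enumerate gap placements: (gap_at, bulge_after, extra_penalty)."""
    yield None, None, 0.0
    if not allow_gaps:
        return
    for j in range(1, L + 1):
        if j in CLEAVAGE_POSITIONS:
            continue  # a gap at the slicing site is never a candidate
        yield j, None, _PENALTY[GAP_TARGET] * position_weight(j)
    for j in range(1, L):
        if j == CLEAVAGE_POSITIONS[0]:
            continue  # bulge between positions 10 and 11 disrupts slicing
        yield None, j, _BULGE_PENALTY * position_weight(j)


def _scan_family(m: np.ndarray, t: np.ndarray, offsets, extra: float,
                 weights: np.ndarray):
    """Vectorized scores for all windows of one gap placement.

    Returns ``(scores, wc_ok, site_offset)``: per-window total penalty, a
    mask that positions 10 and 11 are Watson-Crick, and the within-window
    offset of the cleavage site.
    """
    Lw = max(o for o in offsets if o is not None) + 1
    n_win = len(t) - Lw + 1
    if n_win <= 0:
        return None
    scores = np.full(n_win, extra)
    wc_ok = np.ones(n_win, dtype=bool)
    for i, off in enumerate(offsets):
        if off is None:
            continue
        pen = _PEN[m[i], t[off:off + n_win]]
        scores += weights[i] * pen
        if (i + 1) in CLEAVAGE_POSITIONS:
            wc_ok &= pen == 0.0
    return scores, wc_ok, offsets[CLEAVAGE_POSITIONS[0] - 1]


def _reconstruct(mirna: str, target: str, start0: int, offsets,
                 bulge_after: Optional[int]):
    """Pair states (and bulge charges) of a window alignment, in python."""
    states = []
    for i, off in enumerate(offsets):
        if off is None:
            states.append(GAP_TARGET)
        else:
            states.append(pair_state(mirna[i], target[start0 + off]))
    bulges = (bulge_after,) if bulge_after is not None else ()
    return tuple(states), bulges


def find_candidates(mirna_id: str, mirna_seq: str, transcript_id: str,
                    transcript_seq: str,
                    max_score: float = DEFAULT_MAX_SCORE,
                    allow_gaps: bool = True) -> list:
    """All candidate target sites of one miRNA on one transcript.

    Every window (at every single-gap/bulge placement when ``allow_gaps``)
    scoring at or below ``max_score`` with Watson-Crick pairs at miRNA
    positions 10 and 11 is returned; gaps or bulges at the slicing site are
    excluded outright.
    """
    mirna_seq = mirna_seq.upper().replace("U", "T")
    L = len(mirna_seq)
    if L < 11:
        raise ValueError("miRNA shorter than 11 nt: cleavage-site rule undefined")
    t_seq = transcript_seq.upper().replace("U", "T")
    m = encode(mirna_seq)
    t = encode(t_seq)
    weights = _weights(L)
    out = []
    for gap_at, bulge_after, extra in _families(L, allow_gaps):
        Lw, offsets = _alignment_offsets(L, gap_at, bulge_after)
        scanned = _scan_family(m, t, offsets, extra, weights)
        if scanned is None:
            continue
        scores, wc_ok, site_off = scanned
        for s0 in np.nonzero((scores <= max_score) & wc_ok)[0]:
            s0 = int(s0)
            states, bulges = _reconstruct(mirna_seq, t_seq, s0, offsets,
                                          bulge_after)
            out.append(DuplexAlignment(
                mirna_id=mirna_id, mirna_seq=mirna_seq,
                transcript_id=transcript_id,
                start=s0 + 1, end=s0 + Lw,
                pair_states=states, bulges=bulges,
                score=float(scores[s0]), site=s0 + site_off + 1))
    out.sort(key=lambda a: (a.site, a.score, a.start, a.end))
    return out


def scan_best_hits(mirna_seq: str, transcript_seq: str,
                   max_score: float) -> "dict[int, float]":
    """Fast gapless scan: best score per cleavage site at or below cutoff.

    Used by the shuffled-miRNA null model, which considers ungapped
    duplexes only. Returns ``{site: min_score}`` for windows passing the
    score cutoff and the Watson-Crick slicing-site rule.
    """
    mirna_seq = mirna_seq.upper().replace("U", "T")
    L = len(mirna_seq)
    m = encode(mirna_seq)
    t = encode(transcript_seq.upper().replace("U", "T"))
    scanned = _scan_family(m, t, _alignment_offsets(L, None, None)[1], 0.0,
                           _weights(L))
    if scanned is None:
        return {}
    scores, wc_ok, site_off = scanned
    hits: dict[int, float] = {}
    for s0 in np.nonzero((scores <= max_score) & wc_ok)[0]:
        site = int(s0) + site_off + 1
        sc = float(scores[s0])
        if site not in hits or sc < hits[site]:
            hits[site] = sc
    return hits


def format_duplex(aln: DuplexAlignment, target_window: str) -> str:
    """Render a duplex in the dot/colon notation of degradome T-plot legends.

    Two dots mark a Watson-Crick pair, one dot a G:U wobble, a space any
    other state. Target is printed 5'->3' on top, miRNA 3'->5' below.
    """
    # walk miRNA 3'->5' alongside the target 5'->3'
    top, mid, bot = [], [], []
    tw = target_window.upper().replace("U", "T")
    ti = 0
    entries = []  # (target_base or '-', mirna_base or '-', state)
    L = len(aln.pair_states)
    for pos in range(L, 0, -1):
        st = aln.pair_states[pos - 1]
        if st == GAP_TARGET:
            entries.append(("-", aln.mirna_seq[pos - 1], st))
        else:
            entries.append((tw[ti], aln.mirna_seq[pos - 1], st))
            ti += 1
        if (pos - 1) in aln.bulges:
            entries.append((tw[ti], "-", "bulge"))
            ti += 1
    for tb, mb, st in entries:
        top.append(tb)
        bot.append(mb)
        mid.append(":" if st == WC else ("." if st == GU else " "))
    return "5' {} 3'\n   {}\n3' {} 5'".format(
        "".join(top), "".join(mid), "".join(bot))
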