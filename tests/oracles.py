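"""Brute-force reference implementations used as independent oracles.

Each oracle is a direct, unoptimized transcription of the scoring rules /
category ladder / alignment-space definition, kept separate from the
package code paths it checks.
"""

from statistics import median

_PENALTY = {"WC": 0.0, "GU": 0.5, "mismatch": 1.0, "gap_target": 1.0}
_WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU_PAIRS = {("G", "T"), ("T", "G")}
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_weight(pos):
    return 2.0 if 2 <= pos <= 13 else 1.0


def oracle_score(states, bulges=()):
    """Penalty-table sum over pair states (positions 1..L) plus bulges."""
    total = 0.0
    for pos, st in enumerate(states, start=1):
        total += _PENALTY[st] * oracle_weight(pos)
    for pos in bulges:
        total += 1.0 * oracle_weight(pos)
    return total


def oracle_pair_state(m_base, t_base):
    if (m_base, t_base) in _WC_PAIRS:
        return "WC"
    if (m_base, t_base) in _GU_PAIRS:
        return "GU"
    return "mismatch"


def oracle_candidates(mirna, transcript, max_score=7.0, allow_gaps=True):
    """Exhaustive enumeration of the single-gap duplex alignment space.

    Returns a set of (start, end, site, score, states, bulges) with
    1-based inclusive windows, antiparallel pairing (miRNA position 1
    pairs the window's 3' end), score <= max_score and Watson-Crick
    pairs at miRNA positions 10 and 11.
    """
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    L = len(mirna)
    placements = [("none", None)]
    if allow_gaps:
        placements += [("gap", j) for j in range(1, L + 1)
                       if j not in (10, 11)]
        placements += [("bulge", j) for j in range(1, L) if j != 10]
    out = set()
    for kind, j in placements:
        Lw = L + {"none": 0, "gap": -1, "bulge": 1}[kind]
        for start in range(1, len(transcript) - Lw + 2):
            window = transcript[start - 1: start - 1 + Lw]
            rev = window[::-1]  # walk target 3'->5' alongside miRNA 5'->3'
            states, bulges, ti = [], [], 0
            for pos in range(1, L + 1):
                if kind == "gap" and pos == j:
                    states.append("gap_target")
                    continue
                states.append(oracle_pair_state(mirna[pos - 1], rev[ti]))
                ti += 1
                if kind == "bulge" and pos == j:
                    bulges.append(j)
                    ti += 1  # skip the bulged target base
            score = oracle_score(states, bulges)
            if score > max_score:
                continue
            if states[9] != "WC" or states[10] != "WC":
                continue
            # transcript position paired with miRNA position 10
            consumed_before = 9 if (kind != "gap" or j > 10) else 8
            if kind == "bulge" and j < 10:
                consumed_before += 1
            site = start + Lw - 1 - consumed_before
            out.add((start, start + Lw - 1, site, score,
                     tuple(states), tuple(bulges)))
    return out


def oracle_categorize(counts, site):
    """The printed five-class ladder, evaluated directly."""
    c = counts[site]
    if c == 1:
        return 4
    occupied = list(counts.values())
    peak = max(occupied)
    med = median(occupied)
    if c == peak and occupied.count(peak) == 1:
        return 0
    if c == peak:
        return 1
    if c > med:
        return 2
    return 3


def oracle_revcomp(seq):
    return "".join(_RC[b] for b in reversed(seq))
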