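"""Ground-truthed synthetic degradome libraries.

Generates a transcriptome, a mature miRNA set, ncRNA contaminant
references, and a raw degradome FASTQ in which miRNA-guided cleavage
events are planted at known positions: each planted site hosts a target
window that is the reverse complement of its miRNA (with configurable
mismatch / G:U / bulge edits), and the simulated signal reads are 20-21 nt
fragments whose 5' end sits exactly at the transcript base paired with
miRNA position 10 — the product expected from AGO slicing followed by
MmeI-truncated library construction.

Besides the signal, the simulator emits uniform background decay tags,
ncRNA contaminant fragments, polyN reads (>70% single base), single-N
reads, and low-quality reads, each suffixed with the 3' sequencing
adapter. Every read class gives the preprocessing and classification
filters deterministic work, and a truth table records the planted site,
its duplex score (computed by the scoring code, never hand-entered), the
expected peak category, and the planted read count for end-to-end
round-trip tests.

Background placements that would tie or exceed any planted site's count
on the same transcript are re-rolled, so the expected categories stay
exact under noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .annotate_filter import reverse_complement
from .target_scoring import (GU, MISMATCH, WC, pair_state, score_duplex)

_BASES = "ACGT"

#: defaults for the study conditions the simulator emulates
DEFAULT_CONTAMINANTS = {
    "rRNA": 0.06, "tRNA": 0.002, "snRNA": 0.002, "snoRNA": 0.002,
    "polyN": 0.005, "N_read": 0.002, "low_quality": 0.005,
}
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter

_NCRNA_LENGTHS = {"rRNA": 1600, "tRNA": 76, "snRNA": 160, "snoRNA": 110}


@dataclass
class SyntheticConfig:
    """Parameters of one simulated degradome experiment."""

    n_transcripts: int = 20
    transcript_length_range: Tuple[int, int] = (600, 1200)
    cds_fraction: float = 1.0
    n_mirnas: int = 5
    mirna_length: int = 21
    sites_per_mirna: int = 2
    #: edits applied to every planted target window: (1-based miRNA
    #: position, one of "mismatch" | "GU" | "bulge")
    duplex_edits: List[Tuple[int, str]] = field(default_factory=list)
    signal_depth_range: Tuple[int, int] = (5, 30)
    #: expected background tags per transcript nucleotide
    noise_rate: float = 0.0
    contaminant_fractions: Dict[str, float] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.transcript_length_range
        if lo > hi or lo < 50:
            raise ValueError("transcript_length_range must be sane (lo>=50)")
        if not 0.0 <= self.cds_fraction <= 1.0:
            raise ValueError("cds_fraction must be in [0,1]")
        for f in self.contaminant_fractions.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("contaminant fractions must be in [0,1]")
        if sum(self.contaminant_fractions.values()) >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        if self.mirna_length < 12:
            raise ValueError("mirna_length must be >= 12")
        for pos, kind in self.duplex_edits:
            if kind not in ("mismatch", "GU", "bulge"):
                raise ValueError(f"unknown edit kind {kind!r}")
            if kind == "bulge":
                if not 1 <= pos <= self.mirna_length - 1 or pos == 10:
                    raise ValueError(
                        "bulge position must be in [1, L-1] and not 10")
            else:
                if not 1 <= pos <= self.mirna_length or pos in (10, 11):
                    raise ValueError(
                        "edit position must avoid the slicing site (10/11)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "duplex_edits" in raw:
            raw["duplex_edits"] = [tuple(e) for e in raw["duplex_edits"]]
        for key in ("transcript_length_range", "signal_depth_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted cleavage event."""

    mirna_id: str
    transcript_id: str
    site: int            # 1-based transcript position paired with miRNA nt 10
    expected_score: float
    expected_category: int
    raw_count: int


@dataclass
class References:
    """Synthetic reference set plus the internal site plan."""

    transcripts: Dict[str, str]
    cds: Dict[str, Tuple[int, int]]
    mirnas: Dict[str, str]
    ncrna: Dict[str, Dict[str, str]]
    config: SyntheticConfig
    # site plan: (mirna_id, transcript_id, site, window_start, score)
    _sites: List[Tuple[str, str, int, int, float]] = field(default_factory=list)


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _mismatch_base(m_base: str, rng: random.Random) -> str:
    """A target base that neither WC-pairs nor wobbles with the miRNA base."""
    choices = [b for b in _BASES if pair_state(m_base, b) == MISMATCH]
    return rng.choice(choices)


def _wc_base(m_base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[m_base]


def build_site_window(mirna: str, edits: Sequence[Tuple[int, str]],
                      rng: random.Random) -> Tuple[str, int, float]:
    """Target window (5'->3' sense), site offset within it, and duplex score.

    The window is the reverse complement of the miRNA with the edits
    applied; the returned offset is 0-based within the window and marks
    the base paired with miRNA position 10.
    """
    L = len(mirna)
    by_pos = {pos: kind for pos, kind in edits if kind != "bulge"}
    bulge_after = sorted(pos for pos, kind in edits if kind == "bulge")
    states: List[str] = []
    emitted: List[Tuple[int, str]] = []  # (mirna position or 0, target base)
    for i in range(1, L + 1):
        m_base = mirna[i - 1]
        kind = by_pos.get(i)
        if kind == "mismatch":
            base = _mismatch_base(m_base, rng)
        elif kind == "GU":
            # miRNA base is forced to G upstream, so target U (=T) wobbles
            base = "T" if m_base == "G" else "G"
        else:
            base = _wc_base(m_base)
        states.append(pair_state(m_base, base))
        emitted.append((i, base))
        if i in bulge_after:
            emitted.append((0, rng.choice(_BASES)))  # the bulged target base
    # emitted walks the target 3'->5'; reverse it for the sense window
    window = "".join(base for _pos, base in reversed(emitted))
    rev = list(reversed(emitted))
    site_offset = next(idx for idx, (pos, _b) in enumerate(rev) if pos == 10)
    score = score_duplex(states, tuple(bulge_after))
    return window, site_offset, score


def _prepare_mirna(rng: random.Random, length: int,
                   edits: Sequence[Tuple[int, str]]) -> str:
    """Random miRNA with bases forced where edits require them (G:U needs
    a G on the miRNA side)."""
    seq = list(_random_seq(rng, length))
    for pos, kind in edits:
        if kind == "GU":
            seq[pos - 1] = "G"
    return "".join(seq)


def generate_references(config: SyntheticConfig) -> References:
    """Transcriptome, miRNA set, ncRNA references, with planted sites."""
    rng = random.Random(config.seed)
    L = config.mirna_length
    mirnas = {f"syn-miR{i + 1:02d}": _prepare_mirna(rng, L, config.duplex_edits)
              for i in range(config.n_mirnas)}
    lo, hi = config.transcript_length_range
    transcripts = {f"TX{i + 1:04d}": _random_seq(rng, rng.randint(lo, hi))
                   for i in range(config.n_transcripts)}
    tids = list(transcripts)

    refs = References(transcripts=transcripts, cds={}, mirnas=mirnas,
                      ncrna={}, config=config)
    occupied: Dict[str, List[Tuple[int, int]]] = {t: [] for t in tids}
    site_no = 0
    for mirna_id, mirna_seq in mirnas.items():
        for _k in range(config.sites_per_mirna):
            tid = tids[site_no % len(tids)]
            site_no += 1
            window, site_off, score = build_site_window(
                mirna_seq, config.duplex_edits, rng)
            Lw = len(window)
            seq = transcripts[tid]
            # the signal tag extends 21 nt 3'-ward from the site
            max_start = len(seq) - (site_off + 21)
            if max_start < 1:
                raise ValueError(
                    f"transcript {tid} too short to host a planted site")
            for _try in range(200):
                start0 = rng.randint(0, max_start - 1)
                span = (start0, start0 + Lw)
                if all(span[1] <= s or span[0] >= e
                       for s, e in occupied[tid]):
                    break
            else:
                raise ValueError(
                    f"could not place a site on {tid} without overlap")
            occupied[tid].append(span)
            seq = seq[:start0] + window + seq[start0 + Lw:]
            transcripts[tid] = seq
            site = start0 + site_off + 1  # 1-based
            refs._sites.append((mirna_id, tid, site, start0 + 1, score))

    for tid, seq in transcripts.items():
        n = len(seq)
        cds_len = max(1, round(n * config.cds_fraction))
        start = (n - cds_len) // 2 + 1
        refs.cds[tid] = (start, start + cds_len - 1)
        if config.cds_fraction == 1.0:
            refs.cds[tid] = (1, n)

    refs.ncrna = {cls: {f"{cls}_1": _random_seq(rng, length)}
                  for cls, length in _NCRNA_LENGTHS.items()}
    return refs


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: List[int]


def _read_length(rng: random.Random) -> int:
    return 20 if rng.random() < 0.5 else 21


def _expected_category(counts: Mapping[int, int], site: int) -> int:
    """The peak category the planted structure implies (generator-side
    bookkeeping mirroring the printed five-class ladder)."""
    c = counts[site]
    if c == 1:
        return 4
    values = list(counts.values())
    peak = max(values)
    if c == peak:
        return 0 if sum(1 for v in values if v == peak) == 1 else 1
    return 2 if c > median(values) else 3


def simulate_degradome(config: SyntheticConfig, refs: References,
                       ) -> Tuple[List[SimulatedRead], List[TruthRecord]]:
    """Raw degradome reads plus the ground-truth table.

    Deterministic for a fixed config seed: the same config and references
    give byte-identical FASTQ output.
    """
    rng = random.Random(config.seed + 1)
    adapter = config.adapter
    reads: List[SimulatedRead] = []
    counter = 0

    def emit(seq: str, quals: Optional[List[int]] = None, tag: str = "read"):
        nonlocal counter
        counter += 1
        full = seq + adapter
        q = (quals or [40] * len(seq)) + [40] * len(adapter)
        reads.append(SimulatedRead(f"{tag}_{counter:06d}", full, q))

    # --- planted signal ---------------------------------------------------
    lo_d, hi_d = config.signal_depth_range
    planted_counts: Dict[str, Dict[int, int]] = {}
    plans = []
    for mirna_id, tid, site, _wstart, score in refs._sites:
        depth = rng.randint(lo_d, hi_d)
        planted_counts.setdefault(tid, {})
        planted_counts[tid][site] = planted_counts[tid].get(site, 0) + depth
        plans.append((mirna_id, tid, site, score, depth))

    position_counts: Dict[str, Dict[int, int]] = {
        tid: dict(sites) for tid, sites in planted_counts.items()}

    for mirna_id, tid, site, score, depth in plans:
        seq = refs.transcripts[tid]
        for _ in range(depth):
            length = _read_length(rng)
            frag = seq[site - 1: site - 1 + length]
            if len(frag) < 20:
                continue  # fragment runs off the transcript end
            emit(frag, tag="signal")

    # --- background decay tags -------------------------------------------
    n_background = 0
    for tid, seq in refs.transcripts.items():
        n_bg = int(round(config.noise_rate * len(seq)))
        counts = position_counts.setdefault(tid, {})
        min_planted = min(planted_counts.get(tid, {}).values(), default=None)
        for _ in range(n_bg):
            for _try in range(100):
                pos = rng.randint(1, len(seq) - 20)
                if pos in planted_counts.get(tid, {}):
                    continue  # never inflate a planted peak
                new_count = counts.get(pos, 0) + 1
                if min_planted is not None and new_count >= min_planted:
                    continue  # keep background below every planted count
                counts[pos] = new_count
                length = _read_length(rng)
                frag = seq[pos - 1: pos - 1 + length]
                if len(frag) < 20:
                    continue
                emit(frag, tag="background")
                n_background += 1
                break

    # --- contaminants ------------------------------------------------------
    n_core = sum(d for *_rest, d in plans) + n_background
    fractions = config.contaminant_fractions
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        n_cls = int(round(fractions.get(cls, 0.0) * n_core))
        pool = list(refs.ncrna.get(cls, {}).values())
        for _ in range(n_cls):
            src = rng.choice(pool)
            length = _read_length(rng)
            start = rng.randint(0, len(src) - length)
            emit(src[start:start + length], tag=cls)
    for _ in range(int(round(fractions.get("polyN", 0.0) * n_core))):
        length = _read_length(rng)
        base = rng.choice(_BASES)
        n_major = int(length * 0.75) + 1  # strictly more than 70%
        seq = [base] * n_major + [rng.choice(_BASES.replace(base, ""))
                                  for _ in range(length - n_major)]
        rng.shuffle(seq)
        emit("".join(seq), tag="polyn")
    for _ in range(int(round(fractions.get("N_read", 0.0) * n_core))):
        length = _read_length(rng)
        seq = list(_random_seq(rng, length))
        seq[rng.randint(0, length - 1)] = "N"
        emit("".join(seq), tag="nread")
    for _ in range(int(round(fractions.get("low_quality", 0.0) * n_core))):
        length = _read_length(rng)
        quals = [40] * length
        for i in rng.sample(range(length), 3):
            quals[i] = 2
        emit(_random_seq(rng, length), quals=quals, tag="lowq")

    truth = [TruthRecord(mirna_id, tid, site, score,
                         _expected_category(position_counts[tid], site), depth)
             for mirna_id, tid, site, score, depth in plans]
    return reads, truth


# --- serialization ---------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\tsite\texpected_score\t"
                 "expected_category\traw_count\n")
        for t in truth:
            fh.write(f"{t.mirna_id}\t{t.transcript_id}\t{t.site}\t"
                     f"{t.expected_score}\t{t.expected_category}\t"
                     f"{t.raw_count}\n")


def write_cds_table(cds: Mapping[str, Tuple[int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for tid, (s, e) in cds.items():
            fh.write(f"{tid}\t{s}\t{e}\n")


def read_cds_table(path) -> Dict[str, Tuple[int, int]]:
    cds = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            tid, s, e = line.rstrip("\n").split("\t")
            cds[tid] = (int(s), int(e))
    return cds
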