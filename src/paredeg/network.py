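"""Two-library target comparison and miRNA-mRNA network decomposition.

Targets found in a control and a treatment library are compared at two
levels: target-gene sets (a Venn summary with percentages of the union)
and (miRNA, target) pair records. Pair records are kept as lists, not
sets: one library may record the same (miRNA, target) pair at several
cleavage sites, so each library's overlap with the other is counted
against its own records and the two overlap counts need not be equal.
The overlapped/independent partition and its percentages are therefore
reported per library.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx

Pair = Tuple[str, str]  # (mirna_id, target_id)


def _pct(numerator: int, denominator: int) -> float:
    """Percentage with half-up rounding to 2 decimals (0.0 on empty)."""
    if denominator == 0:
        return 0.0
    val = Decimal(numerator) * 100 / Decimal(denominator)
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class VennSummary:
    a_only: int
    shared: int
    b_only: int
    union: int
    a_only_pct: float
    shared_pct: float
    b_only_pct: float


def venn_targets(targets_a: Iterable[str],
                 targets_b: Iterable[str]) -> VennSummary:
    """Set overlap of target genes between two libraries."""
    a, b = set(targets_a), set(targets_b)
    shared = a & b
    union = a | b
    return VennSummary(
        a_only=len(a - b), shared=len(shared), b_only=len(b - a),
        union=len(union),
        a_only_pct=_pct(len(a - b), len(union)),
        shared_pct=_pct(len(shared), len(union)),
        b_only_pct=_pct(len(b - a), len(union)))


@dataclass
class NetworkPartition:
    """Overlapped/independent decomposition of two libraries' pair records."""

    overlapped_a: List[Pair]
    overlapped_b: List[Pair]
    independent_a: List[Pair]
    independent_b: List[Pair]
    independent_a_pct: float
    independent_b_pct: float


def split_networks(pairs_a: Sequence[Pair],
                   pairs_b: Sequence[Pair]) -> NetworkPartition:
    """Partition each library's pair records by presence in the other.

    A record of library X is *overlapped* when its (miRNA, target) key
    occurs anywhere in library Y, *independent* otherwise; duplicate
    records count individually, so ``|overlapped_a|`` and
    ``|overlapped_b|`` may differ.
    """
    keys_a: Set[Pair] = set(pairs_a)
    keys_b: Set[Pair] = set(pairs_b)
    ov_a = [p for p in pairs_a if p in keys_b]
    ov_b = [p for p in pairs_b if p in keys_a]
    ind_a = [p for p in pairs_a if p not in keys_b]
    ind_b = [p for p in pairs_b if p not in keys_a]
    return NetworkPartition(
        overlapped_a=ov_a, overlapped_b=ov_b,
        independent_a=ind_a, independent_b=ind_b,
        independent_a_pct=_pct(len(ind_a), len(pairs_a)),
        independent_b_pct=_pct(len(ind_b), len(pairs_b)))


def build_graph(pairs: Iterable[Pair]) -> nx.Graph:
    """Bipartite miRNA-target graph (duplicate pairs collapse to one edge)."""
    g = nx.Graph()
    for mirna, target in pairs:
        g.add_node(mirna, kind="miRNA")
        g.add_node(target, kind="gene")
        g.add_edge(mirna, target)
    return g


def export_network(pairs: Iterable[Pair], sif_path, tsv_path,
                   node_path=None) -> nx.Graph:
    """Write a bipartite edge list as SIF and TSV, plus a node-type table."""
    g = build_graph(pairs)
    # orient every edge miRNA -> target regardless of insertion order
    oriented = sorted(
        (u, v) if g.nodes[u]["kind"] == "miRNA" else (v, u)
        for u, v in g.edges)
    with open(sif_path, "w") as fh:
        for mirna, target in oriented:
            fh.write(f"{mirna}\ttargets\t{target}\n")
    with open(tsv_path, "w") as fh:
        fh.write("mirna\ttarget\n")
        for mirna, target in oriented:
            fh.write(f"{mirna}\t{target}\n")
    if node_path is not None:
        with open(node_path, "w") as fh:
            fh.write("node\ttype\n")
            for node in sorted(g.nodes):
                fh.write(f"{node}\t{g.nodes[node]['kind']}\n")
    return g


def hub_mirnas(pairs: Iterable[Pair], top_n: int = 10) -> List[Tuple[str, int]]:
    """Top miRNAs by number of distinct targets."""
    g = build_graph(pairs)
    degs = [(n, g.degree(n)) for n in g.nodes if g.nodes[n]["kind"] == "miRNA"]
    degs.sort(key=lambda x: (-x[1], x[0]))
    return degs[:top_n]


@dataclass
class TagSetComparison:
    common_unique: int
    common_total: int
    specific_a_unique: int
    specific_a_total: int
    specific_b_unique: int
    specific_b_total: int


def compare_tag_sets(tags_a: Mapping[str, int],
                     tags_b: Mapping[str, int]) -> TagSetComparison:
    """Sequence-level common/specific tag accounting between two libraries.

    Inputs map tag sequence -> raw count. Common totals sum both
    libraries' counts over the shared sequences.
    """
    shared = set(tags_a) & set(tags_b)
    only_a = set(tags_a) - shared
    only_b = set(tags_b) - shared
    return TagSetComparison(
        common_unique=len(shared),
        common_total=sum(tags_a[s] + tags_b[s] for s in shared),
        specific_a_unique=len(only_a),
        specific_a_total=sum(tags_a[s] for s in only_a),
        specific_b_unique=len(only_b),
        specific_b_total=sum(tags_b[s] for s in only_b))
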