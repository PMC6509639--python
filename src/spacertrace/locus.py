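"""Population-level CRISPR locus reconstruction from reads.

Reads carrying the direct repeat are recruited and oriented, split into
spacers at repeat boundaries, and assembled into a directed spacer graph
whose edges point from the leader toward the locus-distal end.  The
consensus locus order is the maximum-support path through the (cycle-
collapsed) graph; low-frequency leader-end additions are reported as recent
spacers and unit losses as skip fractions.

Two levels of spacer extraction exist: :func:`split_read_into_spacers`
applies the strict rule that a spacer must be flanked by full repeat
matches on both sides (this is what graph edges are built from), while
:func:`extract_spacer_observations` additionally admits spacers bounded by
one full repeat and an unambiguous terminal partial repeat, which is how
read-level CRISPR tools recover rare leader spacers from short reads.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .seq import encode, hamming, revcomp
from .types import LocusReconstruction, SpacerGraph

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# read recruitment and splitting


def _repeat_match_positions(read: str, repeat: str, max_mismatch: int) -> list[int]:
    """Start positions of full-length repeat matches (<= max_mismatch subs)."""
    m, n = len(repeat), len(read)
    if n < m:
        return []
    r = encode(read)
    q = encode(repeat)
    windows = np.lib.stride_tricks.sliding_window_view(r, m)
    mism = (windows != q).sum(axis=1)
    return [int(i) for i in np.nonzero(mism <= max_mismatch)[0]]


def best_repeat_mismatch(read: str, repeat: str) -> int:
    """Minimum mismatch count of the repeat over all full-length windows."""
    m, n = len(repeat), len(read)
    if n < m:
        return m + 1
    r = encode(read)
    q = encode(repeat)
    windows = np.lib.stride_tricks.sliding_window_view(r, m)
    return int((windows != q).sum(axis=1).min())


def recruit_repeat_reads(
    reads: Iterable[str], repeat_consensus: str, max_mismatch: int = 2
) -> list[str]:
    """Keep reads containing >= 1 full repeat match on either strand.

    Returned reads are oriented to the array (forward) strand: a read whose
    best match lies on the reverse complement is flipped.  Ties go to the
    forward orientation.
    """
    out = []
    for read in reads:
        fwd = best_repeat_mismatch(read, repeat_consensus)
        rc_read = revcomp(read)
        rev = best_repeat_mismatch(rc_read, repeat_consensus)
        if min(fwd, rev) > max_mismatch:
            continue
        out.append(read if fwd <= rev else rc_read)
    return out


def _greedy_nonoverlapping(positions: list[int], width: int) -> list[int]:
    chosen: list[int] = []
    for p in positions:
        if not chosen or p >= chosen[-1] + width:
            chosen.append(p)
    return chosen


def split_read_into_spacers(
    read: str, repeat_consensus: str, max_mismatch: int = 2
) -> list[str]:
    """Spacers of an oriented read, strict both-flank rule.

    Only substrings flanked on BOTH sides by full-length repeat matches are
    returned, in read order; partial terminal repeats yield no spacer on
    that side.
    """
    width = len(repeat_consensus)
    positions = _greedy_nonoverlapping(
        _repeat_match_positions(read, repeat_consensus, max_mismatch), width
    )
    spacers = []
    for a, b in zip(positions, positions[1:]):
        gap = read[a + width : b]
        if gap:
            spacers.append(gap)
    return spacers


def extract_spacer_observations(
    read: str,
    repeat_consensus: str,
    max_mismatch: int = 2,
    spacer_len: tuple[int, int] = (18, 72),
    min_partial_repeat: int = 8,
) -> list[str]:
    """Spacer observations including terminal-partial-repeat evidence.

    In addition to strict both-flank spacers, a substring bounded by a full
    repeat on one side and a read-terminal partial repeat (>= ``min_partial
    _repeat`` matching bases, <= 1 mismatch) on the other is reported when
    its placement is unambiguous within the spacer-length bounds.
    """
    width = len(repeat_consensus)
    positions = _greedy_nonoverlapping(
        _repeat_match_positions(read, repeat_consensus, max_mismatch), width
    )
    if not positions:
        return []
    spacers = []
    lo, hi = spacer_len
    # leading partial: read starts inside a repeat -> suffix of the repeat
    first = positions[0]
    if first >= lo + min_partial_repeat:
        # partial repeat must be a suffix of the repeat ending where a
        # spacer of admissible length begins
        cands = []
        for g in range(lo, min(hi, first - min_partial_repeat) + 1):
            part = read[: first - g]
            if len(part) < min_partial_repeat or len(part) >= width:
                continue
            if hamming(part, repeat_consensus[-len(part):], limit=1) <= 1:
                cands.append(read[first - g : first])
        if len(cands) == 1:
            spacers.append(cands[0])
    # strict middle spacers
    for a, b in zip(positions, positions[1:]):
        gap = read[a + width : b]
        if gap:
            spacers.append(gap)
    # trailing partial: read ends inside the next repeat
    last_end = positions[-1] + width
    tail = len(read) - last_end
    if tail >= lo + min_partial_repeat:
        cands = []
        for g in range(lo, min(hi, tail - min_partial_repeat) + 1):
            part = read[last_end + g :]
            if len(part) < min_partial_repeat or len(part) >= width:
                continue
            if hamming(part, repeat_consensus[: len(part)], limit=1) <= 1:
                cands.append(read[last_end : last_end + g])
        if len(cands) == 1:
            spacers.append(cands[0])
    return spacers


# ---------------------------------------------------------------------------
# graph construction and consensus


def build_spacer_graph(spacer_lists: Iterable[Sequence[str]]) -> SpacerGraph:
    """Count node support and adjacent co-occurrence over per-read lists.

    Lists must be ordered leader -> distal consistently.  Node support is
    the number of reads containing the spacer; edge weight the number of
    reads where the second spacer immediately follows the first.
    """
    g = SpacerGraph()
    for spacers in spacer_lists:
        for s in set(spacers):
            g.support[s] = g.support.get(s, 0) + 1
        for u, v in zip(spacers, spacers[1:]):
            if u == v:
                log.warning("duplicated spacer sequence collapses to one node: %s", u)
                continue
            g.edges[(u, v)] = g.edges.get((u, v), 0) + 1
    return g


def _collapse_cycles(G: nx.DiGraph) -> None:
    """Drop minimum-weight edges until the graph is acyclic."""
    while True:
        try:
            cycle = nx.find_cycle(G)
        except nx.NetworkXNoCycle:
            return
        u, v = min(cycle, key=lambda e: (G.edges[e]["weight"], e))[:2]
        log.warning("dropping back edge %s->%s to break a cycle", u, v)
        G.remove_edge(u, v)


def _max_weight_path(G: nx.DiGraph) -> list[str]:
    """Maximum total-edge-weight path; ties prefer smaller sequences."""
    order = list(nx.topological_sort(G))
    best: dict[str, float] = {v: 0.0 for v in order}
    pred: dict[str, Optional[str]] = {v: None for v in order}
    for v in order:
        for u in G.predecessors(v):
            cand = best[u] + G.edges[u, v]["weight"]
            if cand > best[v] or (cand == best[v] and pred[v] is not None and u < pred[v]):
                best[v] = cand
                pred[v] = u
    end = min((v for v in order), key=lambda v: (-best[v], v))
    path = [end]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path[::-1]


def consensus_locus_order(
    graph: SpacerGraph,
    min_branch_support: int = 1,
    trim_support_fraction: float = 0.5,
) -> LocusReconstruction:
    """Consensus spacer order with diversification/loss annotations.

    The consensus is the maximum-support path through the DAG obtained by
    dropping minimum-weight back edges; terminal path nodes whose support
    falls below ``trim_support_fraction`` x the median path support are
    trimmed (they represent subpopulation leader additions, not the shared
    locus).  Off-consensus spacers whose edges all touch the leader-end
    node -- or that have no edges at all -- are flagged recent; edges that
    skip a consensus spacer are reported as unit losses with the fraction
    of reads taking the skip.
    """
    if not graph.support:
        raise ValueError("empty spacer graph")

    warnings: list[str] = []
    G = nx.DiGraph()
    for v in graph.support:
        G.add_node(v)
    for (u, v), w in graph.edges.items():
        G.add_edge(u, v, weight=w)

    components = list(nx.weakly_connected_components(G))
    orphans: list[str] = []
    if len(components) > 1:
        components.sort(key=lambda c: (-sum(graph.support[v] for v in c), min(c)))
        for comp in components[1:]:
            if len(comp) == 1:
                orphans.extend(comp)
            else:
                orphans.extend(sorted(comp))
                warnings.append(
                    f"disconnected component of {len(comp)} spacers not placed"
                )
        if orphans:
            warnings.append(f"{len(orphans)} spacer(s) outside the main component")
        G = G.subgraph(components[0]).copy()

    _collapse_cycles(G)
    path = _max_weight_path(G)

    # trim low-support termini (subpopulation leader additions)
    supports = [graph.support[v] for v in path]
    med = float(np.median(supports)) if supports else 0.0
    trimmed: list[str] = []
    while len(path) > 2 and graph.support[path[0]] < trim_support_fraction * med:
        trimmed.append(path.pop(0))
    while len(path) > 2 and graph.support[path[-1]] < trim_support_fraction * med:
        trimmed.append(path.pop())

    on_path = set(path)
    leader = path[0]
    recent: list[str] = []
    branches: list[tuple[int, str]] = []
    pos = {v: i for i, v in enumerate(path)}
    for v in sorted(G.nodes()):
        if v in on_path:
            continue
        touched = {u for u, _ in G.in_edges(v)} | {w for _, w in G.out_edges(v)}
        if not touched or touched <= {leader} | set(trimmed):
            recent.append(v)
        else:
            support = graph.support[v]
            if support >= min_branch_support:
                anchors = [pos[t] for t in touched if t in pos]
                branches.append((min(anchors) if anchors else 0, v))
    for v in trimmed:
        if v not in recent:
            recent.append(v)
    for v in orphans:
        # an isolated observation cannot be placed; report it as recent
        # (leader-proximal additions are the expected source) with a warning
        if v not in recent:
            recent.append(v)

    lost: list[tuple[str, float]] = []
    for i, u in enumerate(path):
        for _, w in G.out_edges(u):
            if w in pos and pos[w] > i + 1:
                skip_w = G.edges[u, w]["weight"]
                through = G.edges[u, path[i + 1]]["weight"] if G.has_edge(u, path[i + 1]) else 0
                frac = skip_w / (skip_w + through) if skip_w + through else 0.0
                for v in path[i + 1 : pos[w]]:
                    lost.append((v, frac))

    recent.sort()
    return LocusReconstruction(
        consensus_order=path,
        branches=sorted(branches),
        lost_units=lost,
        recent_spacers=recent,
        orphans=sorted(orphans),
        warnings=warnings,
    )
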