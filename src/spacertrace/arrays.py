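"""De novo CRISPR array detection and leader-end orientation.

The detector is a k-mer-seeded periodic repeat finder in the spirit of CRT:
an exact k-mer recurring at an admissible period (repeat + spacer length)
seeds a chain of candidate repeat instances, which is then extended outward
column-by-column under a per-instance mismatch budget.  Candidates must
reach the minimum repeat length and unit count to be reported, which keeps
the false-positive rate on random sequence effectively zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .seq import hamming, revcomp
from .types import CrisprArray, Region, Spacer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArrayParams:
    """Detector bounds.  Defaults follow common array statistics."""

    k: int = 8
    repeat_len: tuple[int, int] = (21, 48)
    spacer_len: tuple[int, int] = (18, 72)
    min_units: int = 3
    max_repeat_mismatch: int = 2
    # a terminal instance matching at least this fraction of the consensus
    # is accepted as the (often degenerate) closing repeat
    terminal_identity: float = 0.6


def find_arrays(scaffold: str, params: ArrayParams = ArrayParams(),
                scaffold_id: str = "scaffold") -> list[CrisprArray]:
    """Detect repeat-spacer arrays on one scaffold.

    Returns arrays satisfying the CrisprArray invariants; overlapping
    candidates are resolved in favour of more units, then longer span.
    Returns an empty list when nothing is found.
    """
    p = params
    n = len(scaffold)
    if n < 2 * p.repeat_len[0] + p.spacer_len[0]:
        return []

    min_period = p.repeat_len[0] + p.spacer_len[0]
    max_period = p.repeat_len[1] + p.spacer_len[1]

    # k-mer -> sorted occurrence positions
    index: dict[str, list[int]] = {}
    for i in range(n - p.k + 1):
        index.setdefault(scaffold[i : i + p.k], []).append(i)

    candidates: list[CrisprArray] = []
    seen_chains: set[tuple[int, ...]] = set()
    for kmer, positions in index.items():
        if len(positions) < p.min_units:
            continue
        used: set[int] = set()
        for start_idx in range(len(positions)):
            if positions[start_idx] in used:
                continue
            chain = _grow_chain(positions, start_idx, min_period, max_period)
            if len(chain) < p.min_units:
                continue
            used.update(chain)
            key = tuple(chain)
            if key in seen_chains:
                continue
            seen_chains.add(key)
            arr = _expand_chain(scaffold, chain, p, scaffold_id)
            if arr is not None:
                candidates.append(arr)

    return _dedupe(candidates)


def _grow_chain(positions: list[int], start_idx: int, lo: int, hi: int) -> list[int]:
    """Greedy chain of same-k-mer anchors at admissible periodic gaps."""
    chain = [positions[start_idx]]
    j = start_idx
    while True:
        last = chain[-1]
        nxt = None
        for k in range(j + 1, len(positions)):
            gap = positions[k] - last
            if gap < lo:
                continue
            if gap > hi:
                break
            nxt = k
            break  # closest admissible occurrence
        if nxt is None:
            return chain
        chain.append(positions[nxt])
        j = nxt


def _expand_chain(scaffold: str, anchors: list[int], p: ArrayParams,
                  scaffold_id: str) -> Optional[CrisprArray]:
    """Extend anchor k-mers outward into full repeat instances."""
    n = len(scaffold)
    n_inst = len(anchors)
    # unanimity for small instance counts, allow one deviant beyond 10
    def column_ok(offsets_base):
        col = [scaffold[a + off] for a, off in offsets_base]
        best = max(set(col), key=col.count)
        agree = col.count(best)
        need = n_inst if n_inst <= 10 else n_inst - 1
        return agree >= need

    left = 0
    while True:
        off = -(left + 1)
        if anchors[0] + off < 0:
            break
        if not column_ok([(a, off) for a in anchors]):
            break
        left += 1
        if p.k + left > p.repeat_len[1]:
            break
    right = 0
    while True:
        off = p.k + right
        if anchors[-1] + off >= n:
            break
        if not column_ok([(a, off) for a in anchors]):
            break
        right += 1
        if p.k + left + right > p.repeat_len[1]:
            break

    rep_len = p.k + left + right
    if rep_len < p.repeat_len[0]:
        return None

    starts = [a - left for a in anchors]
    # column-wise majority consensus over aligned instances
    consensus = "".join(
        max(cols := [scaffold[s + j] for s in starts], key=cols.count)
        for j in range(rep_len)
    )

    # drop instances that blow the mismatch budget (keep degenerate ends)
    kept = []
    for idx, s in enumerate(starts):
        mm = hamming(scaffold[s : s + rep_len], consensus)
        if mm <= p.max_repeat_mismatch:
            kept.append(s)
        elif idx in (0, len(starts) - 1) and mm <= rep_len * (1 - p.terminal_identity):
            kept.append(s)
    if len(kept) < p.min_units:
        return None

    # enforce spacer-length bounds between consecutive instances; keep the
    # longest valid run
    runs, run = [], [kept[0]]
    for s in kept[1:]:
        gap = s - (run[-1] + rep_len)
        if p.spacer_len[0] <= gap <= p.spacer_len[1]:
            run.append(s)
        else:
            runs.append(run)
            run = [s]
    runs.append(run)
    best = max(runs, key=len)
    if len(best) < p.min_units:
        return None

    repeats = [Region(s, s + rep_len) for s in best]
    spacers = [
        Spacer(sequence=scaffold[a.end : b.start], array_id=scaffold_id)
        for a, b in zip(repeats, repeats[1:])
    ]
    return CrisprArray(
        scaffold_id=scaffold_id,
        repeat_consensus=consensus,
        repeat_instances=repeats,
        spacers=spacers,
    )


def _dedupe(candidates: list[CrisprArray]) -> list[CrisprArray]:
    """Greedy non-overlap selection: more units first, then longer span."""
    ranked = sorted(
        candidates, key=lambda a: (-a.n_units, -(len(a.span)), a.span.start)
    )
    accepted: list[CrisprArray] = []
    for arr in ranked:
        if any(arr.span.overlaps(other.span) for other in accepted):
            continue
        accepted.append(arr)
    accepted.sort(key=lambda a: a.span.start)
    for i, arr in enumerate(accepted):
        arr.array_id = f"{arr.scaffold_id}_array{i + 1}"
        for sp in arr.spacers:
            sp.array_id = arr.array_id
    return accepted


def orient_array(
    array: CrisprArray,
    read_support: Optional[Sequence[int]] = None,
    cas_gene_hint: Optional[int] = None,
) -> CrisprArray:
    """Call the leader end of an array.

    With per-spacer read support, the leader is the end enriched for
    singleton (support == 1) spacers; otherwise the end nearer the supplied
    cas gene coordinate; otherwise unknown.  When both lines of evidence
    exist and disagree, read support wins and the conflict is logged.
    """
    support_side = None
    if read_support is not None:
        if len(read_support) != len(array.spacers):
            raise ValueError("read_support length must match spacer count")
        half = max(1, len(read_support) // 2)
        left_single = sum(1 for c in read_support[:half] if c == 1)
        right_single = sum(1 for c in read_support[-half:] if c == 1)
        if left_single > right_single:
            support_side = "left"
        elif right_single > left_single:
            support_side = "right"
        for sp, c in zip(array.spacers, read_support):
            sp.support_count = c
            sp.singleton = c == 1

    hint_side = None
    if cas_gene_hint is not None:
        array.cas_gene_hint = cas_gene_hint
        span = array.span
        d_left = abs(cas_gene_hint - span.start)
        d_right = abs(cas_gene_hint - span.end)
        hint_side = "left" if d_left <= d_right else "right"

    if support_side and hint_side and support_side != hint_side:
        log.warning(
            "leader evidence conflict on %s: read support says %s, cas hint says %s",
            array.array_id, support_side, hint_side,
        )
    side = support_side or hint_side or "unknown"
    array.leader_side = side
    if side != "unknown":
        n = len(array.spacers)
        for i, sp in enumerate(array.spacers):
            sp.index_from_leader = i if side == "left" else n - 1 - i
    return array


def mirror_array(array: CrisprArray, scaffold_len: int) -> CrisprArray:
    """The same array expressed on the reverse complement of its scaffold."""
    repeats = [
        Region(scaffold_len - r.end, scaffold_len - r.start)
        for r in reversed(array.repeat_instances)
    ]
    spacers = [
        Spacer(sequence=revcomp(sp.sequence), array_id=sp.array_id)
        for sp in reversed(array.spacers)
    ]
    side = {"left": "right", "right": "left", "unknown": "unknown"}[array.leader_side]
    return CrisprArray(
        scaffold_id=array.scaffold_id,
        repeat_consensus=revcomp(array.repeat_consensus),
        repeat_instances=repeats,
        spacers=spacers,
        leader_side=side,
        array_id=array.array_id,
    )
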