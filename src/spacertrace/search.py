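"""Spacer dereplication, protospacer search, and target classification.

Matching implements the strict acceptance criterion of zero-mismatch (or a
configured substitution budget), full-length alignment on either strand.
The production scanner is a pigeonhole-chunk k-mer index: a spacer matched
with at most ``m`` substitutions must contain at least one of ``m+1`` equal
chunks exactly, so exact chunk lookups enumerate every candidate position,
which is then verified by direct comparison.  A naive sliding-window scan
(:func:`scan_bruteforce`) is kept as the independent reference
implementation; the two must agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq import encode, revcomp
from .types import CrisprArray, ProtospacerHit, TargetClassification

log = logging.getLogger(__name__)

# annotation keywords that mark a scaffold as phage-like
PHAGE_KEYWORDS = (
    "capsid", "phage", "virus", "prophage", "terminase", "prohead",
    "tape measure", "tail", "head", "portal", "dna packaging",
)


@dataclass
class SpacerCatalog:
    """Dereplicated spacers with multiplicities and reverse-complement links."""

    sequences: dict[str, str] = field(default_factory=dict)  # id -> sequence
    multiplicity: dict[str, int] = field(default_factory=dict)
    revcomp_pairs: list[tuple[str, str]] = field(default_factory=list)
    source_array: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def id_of(self, sequence: str) -> Optional[str]:
        for sid, s in self.sequences.items():
            if s == sequence:
                return sid
        return None


def dereplicate_spacers(
    spacers: Iterable, id_prefix: str = "sp"
) -> SpacerCatalog:
    """Collapse exact duplicates, keeping multiplicities.

    Accepts plain sequences or :class:`~spacertrace.types.Spacer` objects
    (whose ``array_id`` is propagated).  Reverse-complement pairs remain
    distinct entries but are cross-referenced so scaffold-level statistics
    can avoid double counting.
    """
    seqs: dict[str, int] = {}
    sources: dict[str, str] = {}
    for sp in spacers:
        seq = sp if isinstance(sp, str) else sp.sequence
        seqs[seq] = seqs.get(seq, 0) + 1
        if not isinstance(sp, str) and sp.array_id and seq not in sources:
            sources[seq] = sp.array_id
    catalog = SpacerCatalog()
    width = max(4, len(str(len(seqs))))
    by_seq: dict[str, str] = {}
    for i, (seq, count) in enumerate(seqs.items(), start=1):
        sid = f"{id_prefix}{i:0{width}d}"
        catalog.sequences[sid] = seq
        catalog.multiplicity[sid] = count
        by_seq[seq] = sid
        if seq in sources:
            catalog.source_array[sid] = sources[seq]
    for seq, sid in by_seq.items():
        rc = revcomp(seq)
        if rc in by_seq and seq < rc:
            catalog.revcomp_pairs.append((sid, by_seq[rc]))
    return catalog


# ---------------------------------------------------------------------------
# scanning


def scan_bruteforce(spacer: str, scaffold: str, max_mismatch: int = 0) -> list[tuple[int, str, int]]:
    """Reference scanner: every full-length placement on both strands.

    Returns (start, strand, mismatches) tuples in forward coordinates.
    This is the contract the indexed scanner must reproduce exactly.
    """
    m = len(spacer)
    n = len(scaffold)
    if n < m:
        return []
    enc = encode(scaffold)
    windows = np.lib.stride_tricks.sliding_window_view(enc, m)
    out = []
    for strand, pat in (("+", spacer), ("-", revcomp(spacer))):
        q = encode(pat)
        mism = (windows != q).sum(axis=1)
        for i in np.nonzero(mism <= max_mismatch)[0]:
            out.append((int(i), strand, int(mism[i])))
    out.sort()
    return out


class _ChunkIndex:
    """Exact-substring index of one scaffold for a fixed chunk length."""

    def __init__(self, scaffold: str, chunk_len: int):
        self.chunk_len = chunk_len
        self.positions: dict[str, list[int]] = {}
        for i in range(len(scaffold) - chunk_len + 1):
            self.positions.setdefault(scaffold[i : i + chunk_len], []).append(i)

    def lookup(self, chunk: str) -> list[int]:
        return self.positions.get(chunk, [])


def _mismatches_at(scaffold: str, pat: str, start: int, limit: int) -> Optional[int]:
    if start < 0 or start + len(pat) > len(scaffold):
        return None
    mm = 0
    for a, b in zip(pat, scaffold[start : start + len(pat)]):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def find_protospacer_hits(
    catalog: SpacerCatalog,
    scaffolds: dict[str, str],
    max_mismatch: int = 0,
) -> list[ProtospacerHit]:
    """Full-length matches of every catalog spacer on every scaffold.

    Both strands are searched; coverage is always 1.0 because only
    full-length placements count.  Spacers containing non-ACGT characters
    yield no hits at max_mismatch=0 (warned).
    """
    hits: list[ProtospacerHit] = []
    items = []
    for sid, seq in catalog.sequences.items():
        if len(seq) < 15:
            raise ValueError(f"spacer {sid} shorter than 15 nt")
        if set(seq) - set("ACGT"):
            log.warning("spacer %s contains non-ACGT characters; no exact hits", sid)
            if max_mismatch == 0:
                continue
        items.append((sid, seq))
    if not items:
        return []

    chunk_of = {sid: max(1, len(seq) // (max_mismatch + 1)) for sid, seq in items}
    for scaf_id, scaffold in scaffolds.items():
        indexes = {
            clen: _ChunkIndex(scaffold, clen) for clen in sorted(set(chunk_of.values()))
        }
        for sid, seq in items:
            clen = chunk_of[sid]
            index = indexes[clen]
            m = len(seq)
            found: dict[tuple[int, str], int] = {}
            for strand, pat in (("+", seq), ("-", revcomp(seq))):
                starts: set[int] = set()
                for c in range(max_mismatch + 1):
                    off = c * clen
                    for p in index.lookup(pat[off : off + clen]):
                        starts.add(p - off)
                for start in starts:
                    mm = _mismatches_at(scaffold, pat, start, max_mismatch)
                    if mm is not None:
                        found[(start, strand)] = mm
            for (start, strand), mm in sorted(found.items()):
                hits.append(
                    ProtospacerHit(
                        spacer_id=sid, target_scaffold=scaf_id,
                        start=start, end=start + m, strand=strand,
                        mismatches=mm, coverage=1.0,
                    )
                )
    hits.sort(key=lambda h: (h.target_scaffold, h.start, h.spacer_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# filtering and classification


def exclude_array_self_hits(
    hits: Sequence[ProtospacerHit], arrays: Sequence[CrisprArray]
) -> tuple[list[ProtospacerHit], list[ProtospacerHit]]:
    """Remove hits overlapping any repeat-spacer array span.

    A spacer trivially matches its own array; such matches must not count
    as targets.  Returns (kept, removed).
    """
    spans: dict[str, list] = {}
    for arr in arrays:
        spans.setdefault(arr.scaffold_id, []).append(arr.span)
    kept, removed = [], []
    for h in hits:
        overlapping = any(
            h.start < sp.end and sp.start < h.end
            for sp in spans.get(h.target_scaffold, [])
        )
        (removed if overlapping else kept).append(h)
    return kept, removed


def classify_target_scaffold(
    scaffold_id: str,
    hits: Sequence[ProtospacerHit],
    annotations=None,
    keywords: Sequence[str] = PHAGE_KEYWORDS,
    self_spacer_ids: Optional[set[str]] = None,
) -> TargetClassification:
    """Classify one targeted scaffold by annotation keywords.

    ``annotations`` is a DataFrame-like with scaffold/start/end/strand/
    product columns (may be None or empty).  A scaffold is phage_like iff
    at least one of its annotation products contains a keyword
    (case-insensitive substring); otherwise it is 'self' when all of its
    hits come from self-targeting spacers, else unclassified.
    """
    scaffold_hits = [h for h in hits if h.target_scaffold == scaffold_id]
    if not scaffold_hits:
        raise ValueError(f"no hits on scaffold {scaffold_id}")
    keyword_products: list[str] = []
    if annotations is not None and len(annotations):
        rows = annotations[annotations["scaffold"] == scaffold_id]
        for product in rows["product"]:
            lowered = str(product).lower()
            if any(k in lowered for k in keywords):
                keyword_products.append(str(product))
    distinct = len({h.spacer_id for h in scaffold_hits})
    if keyword_products:
        category = "phage_like"
    elif self_spacer_ids and all(h.spacer_id in self_spacer_ids for h in scaffold_hits):
        category = "self"
    else:
        category = "unclassified"
    return TargetClassification(
        scaffold_id=scaffold_id,
        n_hits=len(scaffold_hits),
        distinct_spacers=distinct,
        keyword_products=keyword_products,
        category=category,
    )


@dataclass
class SelfTargetRecord:
    spacer_id: str
    target_scaffold: str
    start: int
    end: int
    strand: str
    target_gene: Optional[str] = None
    intergenic: bool = False


def flag_self_targeting(
    hits: Sequence[ProtospacerHit],
    bin_membership: dict[str, str],
    arrays: Sequence[CrisprArray],
    spacer_source_array: dict[str, str],
    annotations=None,
) -> tuple[list[SelfTargetRecord], int]:
    """Spacers hitting their own genome (bin) outside any array.

    A spacer is self-targeting iff it has >= 1 array-excluded hit on a
    scaffold assigned to the same bin as its source array's scaffold.  Hits
    on unbinned scaffolds are not counted but tallied as unresolved.
    Returns (records, n_unresolved).
    """
    kept, _ = exclude_array_self_hits(hits, arrays)
    array_bins: dict[str, Optional[str]] = {}
    for arr in arrays:
        array_bins[arr.array_id] = bin_membership.get(arr.scaffold_id)

    records: list[SelfTargetRecord] = []
    unresolved = 0
    for h in kept:
        source = spacer_source_array.get(h.spacer_id)
        if source is None:
            continue
        source_bin = array_bins.get(source, bin_membership.get(source))
        target_bin = bin_membership.get(h.target_scaffold)
        if target_bin is None:
            unresolved += 1
            continue
        if source_bin is None or target_bin != source_bin:
            continue
        gene = None
        if annotations is not None and len(annotations):
            rows = annotations[
                (annotations["scaffold"] == h.target_scaffold)
                & (annotations["start"] < h.end)
                & (annotations["end"] > h.start)
            ]
            if len(rows):
                gene = str(rows.iloc[0]["product"])
        records.append(
            SelfTargetRecord(
                spacer_id=h.spacer_id, target_scaffold=h.target_scaffold,
                start=h.start, end=h.end, strand=h.strand,
                target_gene=gene, intergenic=gene is None,
            )
        )
    return records, unresolved
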