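"""Shared domain types.

All coordinates are 0-based half-open on the forward strand of the named
scaffold; strand is '+'/'-'. These containers are plain dataclasses so that
every result can be serialized to JSON/TSV without custom machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class Region:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Spacer:
    """One spacer of a CRISPR array or read-recovered catalog."""

    sequence: str
    array_id: str = ""
    index_from_leader: Optional[int] = None
    support_count: int = 0
    singleton: bool = False

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"bad spacer sequence {self.sequence!r}")


@dataclass
class CrisprArray:
    """A detected (or planted) repeat-spacer locus on one scaffold.

    ``repeat_instances`` has exactly one more element than ``spacers``; the
    i-th spacer lies between repeat instances i and i+1.
    """

    scaffold_id: str
    repeat_consensus: str
    repeat_instances: list[Region]
    spacers: list[Spacer]
    leader_side: str = "unknown"  # left | right | unknown
    cas_gene_hint: Optional[int] = None
    array_id: str = ""

    def __post_init__(self) -> None:
        if len(self.repeat_instances) != len(self.spacers) + 1:
            raise ValueError(
                "repeat instance count must be spacer count + 1 "
                f"({len(self.repeat_instances)} vs {len(self.spacers)})"
            )
        prev_end = -1
        for r in self.repeat_instances:
            if r.start < prev_end:
                raise ValueError("repeat instances must be increasing and non-overlapping")
            prev_end = r.end
        if self.leader_side not in ("left", "right", "unknown"):
            raise ValueError(f"bad leader_side {self.leader_side!r}")

    @property
    def span(self) -> Region:
        return Region(self.repeat_instances[0].start, self.repeat_instances[-1].end)

    @property
    def n_units(self) -> int:
        return len(self.repeat_instances)


@dataclass(frozen=True)
class ProtospacerHit:
    """One full-length spacer match on a scaffold."""

    spacer_id: str
    target_scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def location(self) -> tuple:
        """Unique target location key (spacer identity ignored)."""
        return (self.target_scaffold, self.start, self.end, self.strand)


@dataclass
class TargetClassification:
    scaffold_id: str
    n_hits: int
    distinct_spacers: int
    keyword_products: list[str] = field(default_factory=list)
    category: str = "unclassified"  # phage_like | self | unclassified


@dataclass
class PamObservation:
    """5-bp flanks of one protospacer hit, read on the targeted strand."""

    hit: ProtospacerHit
    upstream5: str
    downstream5: str
    complete: bool


@dataclass
class SpacerGraph:
    """Directed adjacency of spacers co-occurring on reads.

    Edges point leader -> distal; weight counts reads where the second
    spacer immediately follows the first.
    """

    support: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def nodes(self) -> list[str]:
        return list(self.support)


@dataclass
class LocusReconstruction:
    consensus_order: list[str]
    branches: list[tuple[int, str]] = field(default_factory=list)
    lost_units: list[tuple[str, float]] = field(default_factory=list)
    recent_spacers: list[str] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class CoverageProfile:
    scaffold_id: str
    depth: "object"  # numpy int array, len == scaffold length
    mapped_pairs: int = 0

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


@dataclass
class ProphageCall:
    region: Region
    region_mean_depth: float
    flank_mean_depth: float
    ratio: Optional[float]
    circular_support: int
    state: str  # integrated_only | active_particles


@dataclass
class VariantCall:
    scaffold_id: str
    position: int
    ref: str
    alt: str
    alt_fraction: float
    consequence: str  # nonsense | frameshift_stop | other
    stop_offset_codons: Optional[int] = None
    depth: int = 0


@dataclass
class FragmentationCall:
    gene_region: Region
    fragment_orfs: list[Region]
    tiling_coverage_of_reference: float
    variants: list[VariantCall] = field(default_factory=list)


def to_plain(obj) -> object:
    """Recursively convert dataclasses to JSON-friendly structures."""
    import numpy as _np

    if hasattr(obj, "__dataclass_fields__"):
        return {k: to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain(v) for v in obj]
    if isinstance(obj, _np.ndarray):
        return obj.tolist()
    if isinstance(obj, (_np.integer,)):
        return int(obj)
    if isinstance(obj, (_np.floating,)):
        return float(obj)
    return obj
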