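"""Protospacer-adjacent motif (PAM) inference from hit flanks.

For every protospacer hit the 5 bp upstream and 5 bp downstream of the
targeted strand are extracted; observations are deduplicated to unique
target locations, aggregated into dinucleotide motif counts (upstream
positions -2,-1), a 4x5 position frequency matrix over the upstream flank,
and per-position information content in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seq import DNA_ALPHABET, revcomp
from .types import PamObservation, ProtospacerHit

BASES = tuple(DNA_ALPHABET)


def extract_pam_observation(
    hit: ProtospacerHit, scaffold: str, flank: int = 5
) -> PamObservation:
    """Flanks of one hit, read 5'->3' on the targeted (protospacer) strand.

    For a '+' hit the upstream flank is ``scaffold[start-flank:start]``; for
    a '-' hit it is the reverse complement of ``scaffold[end:end+flank]``.
    Hits closer than ``flank`` to a scaffold end are flagged incomplete.
    """
    if hit.start < 0 or hit.end > len(scaffold):
        raise ValueError("hit coordinates outside scaffold")
    up_plus = scaffold[max(0, hit.start - flank) : hit.start]
    down_plus = scaffold[hit.end : hit.end + flank]
    if hit.strand == "+":
        upstream, downstream = up_plus, down_plus
    else:
        upstream, downstream = revcomp(down_plus), revcomp(up_plus)
    complete = len(upstream) == flank and len(downstream) == flank
    return PamObservation(
        hit=hit, upstream5=upstream, downstream5=downstream, complete=complete
    )


@dataclass
class PamSummary:
    """Aggregated PAM evidence over unique target locations."""

    n_locations: int
    n_complete: int
    motif_counts: dict[str, int]
    pfm: "np.ndarray"  # 4 x flank, columns sum to 1 (complete obs only)
    info_content: list[float]  # bits per upstream position
    flank: int = 5
    motif_len: int = 2
    incomplete: list[PamObservation] = field(default_factory=list)

    def pfm_frame(self) -> pd.DataFrame:
        cols = [str(i - self.flank) for i in range(self.flank)]
        return pd.DataFrame(self.pfm, index=list(BASES), columns=cols)


def build_pam_summary(
    observations: Sequence[PamObservation], flank: int = 5, motif_len: int = 2
) -> PamSummary:
    """Deduplicate to unique target locations and aggregate motifs.

    Multiple spacers hitting the identical (scaffold, start, end, strand)
    location count once.  Counts and the PFM cover complete observations
    only; incomplete ones are carried along for reporting.  Information
    content per upstream position j is 2 + sum_b f_bj log2 f_bj.
    """
    unique: dict[tuple, PamObservation] = {}
    for obs in observations:
        unique.setdefault(obs.hit.location, obs)
    deduped = list(unique.values())
    complete = [o for o in deduped if o.complete]
    incomplete = [o for o in deduped if not o.complete]

    counts: dict[str, int] = {}
    matrix = np.zeros((4, flank))
    for obs in complete:
        motif = obs.upstream5[-motif_len:]
        counts[motif] = counts.get(motif, 0) + 1
        for j, b in enumerate(obs.upstream5):
            if b in BASES:
                matrix[BASES.index(b), j] += 1

    if complete:
        pfm = matrix / matrix.sum(axis=0, keepdims=True)
    else:
        pfm = np.full((4, flank), 0.25)
    info = []
    for j in range(flank):
        h = sum(
            pfm[b, j] * math.log2(pfm[b, j]) for b in range(4) if pfm[b, j] > 0
        )
        info.append(2.0 + h if complete else 0.0)

    return PamSummary(
        n_locations=len(deduped),
        n_complete=len(complete),
        motif_counts=dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))),
        pfm=pfm,
        info_content=info,
        flank=flank,
        motif_len=motif_len,
        incomplete=incomplete,
    )


def call_pam_motifs(summary: PamSummary, min_fraction: float = 0.2) -> list[str]:
    """Motifs reaching ``min_fraction`` of complete locations.

    Sorted by count descending, ties broken lexicographically.  Raises when
    there are no observations at all.
    """
    if summary.n_locations == 0:
        raise ValueError("no observations")
    if summary.n_complete == 0:
        return []
    return [
        motif
        for motif, count in sorted(
            summary.motif_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        if count / summary.n_complete >= min_fraction
    ]


def write_pfm(summary: PamSummary, path) -> None:
    """PFM as a TSV matrix (rows A/C/G/T, columns -5..-1)."""
    summary.pfm_frame().to_csv(path, sep="\t", float_format="%.6f")


def plot_pam_logo(summary: PamSummary, path=None, ax=None):
    """Sequence-logo-style plot of the upstream flank (needs matplotlib).

    Letter heights are the per-base contributions to the information
    content at each position, the standard logo scaling.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 2.5))
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    for j in range(summary.flank):
        heights = [
            (BASES[b], summary.pfm[b, j] * summary.info_content[j]) for b in range(4)
        ]
        y = 0.0
        for base, h in sorted(heights, key=lambda t: t[1]):
            if h <= 0:
                continue
            ax.text(
                j + 0.5, y + h / 2, base, ha="center", va="center",
                fontsize=8 + 16 * h, color=colors[base], fontweight="bold",
            )
            y += h
    ax.set_xlim(0, summary.flank)
    ax.set_ylim(0, 2)
    ax.set_xticks([i + 0.5 for i in range(summary.flank)])
    ax.set_xticklabels([str(i - summary.flank) for i in range(summary.flank)])
    ax.set_ylabel("bits")
    ax.set_xlabel("position relative to protospacer 5' end")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
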