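"""End-to-end orchestration: simulate -> detect -> reconstruct -> search ->
PAM -> evidence, with a consolidated, deterministic report.

The pipeline is a thin composition of the library stages.  A run is
described by a :class:`RunConfig` (unknown keys are rejected up front);
every stage parameter is echoed into the report for provenance.  Stage
regions that cannot be inferred at desk scale (prophage boundaries, the
assayed gene) are supplied by configuration or scenario truth.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import arrays as arrays_mod
from . import evidence as ev
from . import io as io_mod
from . import locus as locus_mod
from . import pam as pam_mod
from . import search as search_mod
from .scenarios import SCENARIOS, Scenario
from .types import Region, to_plain

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # input: either a named scenario or file paths
    scenario: Optional[str] = None
    scaffolds_fasta: Optional[str] = None
    reads_r1: Optional[str] = None
    reads_r2: Optional[str] = None
    annotations_tsv: Optional[str] = None
    bins_tsv: Optional[str] = None
    # stage toggles
    run_detect: bool = True
    run_reconstruct: bool = True
    run_search: bool = True
    run_pam: bool = True
    run_evidence: bool = True
    # stage parameters
    array_k: int = 8
    repeat_len: tuple[int, int] = (21, 48)
    spacer_len: tuple[int, int] = (18, 72)
    min_units: int = 3
    max_repeat_mismatch: int = 2
    read_repeat_mismatch: int = 2
    min_branch_support: int = 1
    max_mismatch: int = 0
    pam_flank: int = 5
    pam_motif_len: int = 2
    pam_min_fraction: float = 0.2
    max_pair_mismatch: int = 1
    prophage_ratio_threshold: float = 3.0
    min_circular_pairs: int = 3
    end_window: int = 500
    min_depth: int = 10
    cas_gene_hint: Optional[int] = None
    prophage_region: Optional[tuple[str, int, int]] = None
    gene_region: Optional[tuple[str, int, int]] = None
    circularity_scaffolds: tuple[str, ...] = ()
    # run control
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.scenario is not None and cfg.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        if cfg.scenario is None and cfg.scaffolds_fasta is None:
            raise ValueError("need a scenario or scaffolds_fasta")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("repeat_len", "spacer_len", "prophage_region", "gene_region",
                    "circularity_scaffolds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls.from_dict(data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report dict (also written to ``out_dir`` when set, along
    with per-stage artifacts).  The report is deterministic for a given
    (config, seed); wall-clock timings are kept out of it.
    """
    echoed = dataclasses.asdict(config)
    echoed.pop("out_dir")  # environment detail; keeps reruns byte-identical
    report: dict = {"config": to_plain(echoed), "stages": {}}
    timings: dict[str, float] = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    scenario: Optional[Scenario] = None
    if config.scenario is not None:
        scenario = SCENARIOS[config.scenario](config.seed)
        scaffolds = scenario.scaffolds
        reads = scenario.reads
        annotations = scenario.annotations
        bins = scenario.bins
        cas_hint = scenario.cas_gene_hint
        if out:
            io_mod.write_scenario(scenario, out / "simulated")
        report["stages"]["simulate"] = {
            "scenario": scenario.name,
            "n_scaffolds": len(scaffolds),
            "n_read_pairs": len(reads),
        }
    else:
        scaffolds = io_mod.read_fasta(config.scaffolds_fasta)
        reads = (
            io_mod.read_fastq_pairs(config.reads_r1, config.reads_r2)
            if config.reads_r1 and config.reads_r2
            else []
        )
        annotations = (
            io_mod.read_annotations(config.annotations_tsv)
            if config.annotations_tsv
            else None
        )
        bins = io_mod.read_bins(config.bins_tsv) if config.bins_tsv else {}
        cas_hint = config.cas_gene_hint
    timings["input"] = time.perf_counter() - t0

    params = arrays_mod.ArrayParams(
        k=config.array_k, repeat_len=tuple(config.repeat_len),
        spacer_len=tuple(config.spacer_len), min_units=config.min_units,
        max_repeat_mismatch=config.max_repeat_mismatch,
    )

    detected: list = []
    if config.run_detect:
        t0 = time.perf_counter()
        for name in sorted(scaffolds):
            found = arrays_mod.find_arrays(scaffolds[name], params, scaffold_id=name)
            for arr in found:
                arrays_mod.orient_array(arr, cas_gene_hint=cas_hint)
            detected.extend(found)
        report["stages"]["detect"] = {
            "n_arrays": len(detected),
            "arrays": [
                {"array_id": a.array_id, "scaffold": a.scaffold_id,
                 "start": a.span.start, "end": a.span.end,
                 "n_units": a.n_units, "consensus": a.repeat_consensus,
                 "leader_side": a.leader_side}
                for a in detected
            ],
        }
        timings["detect"] = time.perf_counter() - t0

    reconstruction = None
    graph = None
    read_spacers: list[str] = []
    primary_array = None
    if config.run_reconstruct and detected and reads:
        t0 = time.perf_counter()
        primary_array = max(detected, key=lambda a: a.n_units)
        repeat = primary_array.repeat_consensus
        all_reads = [r for p in reads for r in (p.r1, p.r2)]
        recruited = locus_mod.recruit_repeat_reads(
            all_reads, repeat, config.read_repeat_mismatch
        )
        leader_right = primary_array.leader_side == "right"
        strict_lists = []
        for read in recruited:
            spl = locus_mod.split_read_into_spacers(
                read, repeat, config.read_repeat_mismatch
            )
            if leader_right:
                spl = spl[::-1]
            strict_lists.append(spl)
        graph = locus_mod.build_spacer_graph(strict_lists)
        # terminal-partial observations (one full + one partial flanking
        # repeat) refine support counts and recover rare leader spacers the
        # strict both-flank rule missed
        obs_support: dict[str, int] = {}
        for read in recruited:
            obs = locus_mod.extract_spacer_observations(
                read, repeat, config.read_repeat_mismatch,
                spacer_len=tuple(config.spacer_len),
            )
            read_spacers.extend(obs)
            for s in set(obs):
                obs_support[s] = obs_support.get(s, 0) + 1
        for s, n in obs_support.items():
            graph.support[s] = max(graph.support.get(s, 0), n)
        reconstruction = locus_mod.consensus_locus_order(
            graph, min_branch_support=config.min_branch_support
        )
        report["stages"]["reconstruct"] = {
            "array_id": primary_array.array_id,
            "n_recruited_reads": len(recruited),
            "n_nodes": len(graph.support),
            "n_edges": len(graph.edges),
            "consensus_length": len(reconstruction.consensus_order),
            "n_recent": len(reconstruction.recent_spacers),
            "n_lost_units": len(set(s for s, _ in reconstruction.lost_units)),
            "warnings": reconstruction.warnings,
        }
        timings["reconstruct"] = time.perf_counter() - t0

    catalog = None
    hits = kept_hits = None
    self_records: list = []
    classifications = []
    if config.run_search:
        t0 = time.perf_counter()
        from .types import Spacer

        pool: list = []
        seen_seq: set[str] = set()
        if graph is not None and primary_array is not None:
            for s in sorted(graph.support):
                pool.append(Spacer(sequence=s, array_id=primary_array.array_id))
                seen_seq.add(s)
        for arr in detected:
            for sp in arr.spacers:
                if sp.sequence not in seen_seq:
                    pool.append(sp)
                    seen_seq.add(sp.sequence)
        if not pool and scenario is not None:
            pool = [Spacer(sequence=s) for s in scenario.truth.spacer_catalog.values()]
        catalog = search_mod.dereplicate_spacers(pool)
        hits = search_mod.find_protospacer_hits(
            catalog, scaffolds, max_mismatch=config.max_mismatch
        )
        kept_hits, excluded = search_mod.exclude_array_self_hits(hits, detected)
        spacer_sources = dict(catalog.source_array)
        self_records, unresolved = search_mod.flag_self_targeting(
            kept_hits, bins, detected, spacer_sources, annotations
        )
        self_ids = {r.spacer_id for r in self_records}
        for scaf in sorted({h.target_scaffold for h in kept_hits}):
            classifications.append(
                search_mod.classify_target_scaffold(
                    scaf, kept_hits, annotations, self_spacer_ids=self_ids
                )
            )
        report["stages"]["search"] = {
            "n_unique_spacers": len(catalog),
            "n_hits": len(kept_hits),
            "n_array_excluded": len(excluded),
            "n_self_targeting_spacers": len(self_ids),
            "n_unresolved": unresolved,
            "targets": [to_plain(c) for c in classifications],
        }
        timings["search"] = time.perf_counter() - t0

    if config.run_pam and kept_hits:
        t0 = time.perf_counter()
        observations = [
            pam_mod.extract_pam_observation(h, scaffolds[h.target_scaffold],
                                            flank=config.pam_flank)
            for h in kept_hits
        ]
        summary = pam_mod.build_pam_summary(
            observations, flank=config.pam_flank, motif_len=config.pam_motif_len
        )
        motifs = pam_mod.call_pam_motifs(summary, config.pam_min_fraction)
        self_ids = {r.spacer_id for r in self_records}
        self_obs = [o for o in observations if o.hit.spacer_id in self_ids]
        pam_stage = {
            "n_locations": summary.n_locations,
            "motif_counts": summary.motif_counts,
            "motifs": motifs,
            "info_content": [round(x, 6) for x in summary.info_content],
        }
        if self_obs:
            self_summary = pam_mod.build_pam_summary(
                self_obs, flank=config.pam_flank, motif_len=config.pam_motif_len
            )
            pam_stage["self_targets"] = {
                "n_locations": self_summary.n_locations,
                "motif_counts": self_summary.motif_counts,
                "motifs": pam_mod.call_pam_motifs(self_summary, config.pam_min_fraction),
            }
        report["stages"]["pam"] = pam_stage
        if out:
            pam_mod.write_pfm(summary, out / "pam_pfm.tsv")
        timings["pam"] = time.perf_counter() - t0

    if config.run_evidence and reads:
        t0 = time.perf_counter()
        mapping = ev.map_reads(
            reads, scaffolds, max_pair_mismatch=config.max_pair_mismatch
        )
        stage: dict = {
            "n_pairs_input": mapping.n_input_pairs,
            "n_pairs_retained": len(mapping.pairs),
            "n_pairs_filtered": mapping.n_discarded_filter,
            "n_pairs_unmapped": mapping.n_unmapped,
            "mean_depth": {
                name: round(prof.mean_depth, 6)
                for name, prof in sorted(mapping.coverage.items())
            },
        }
        prophage_region = config.prophage_region
        if prophage_region is None and scenario is not None:
            prophage_region = scenario.truth.prophage_region
        if prophage_region is not None:
            scaf, start, end = prophage_region
            call = ev.prophage_activity_call(
                mapping.coverage[scaf], Region(start, end),
                ratio_threshold=config.prophage_ratio_threshold,
                min_circular_pairs=config.min_circular_pairs,
            )
            stage["prophage"] = to_plain(call)
        for scaf in config.circularity_scaffolds:
            support = ev.detect_circularity(
                mapping.pairs, scaf, len(scaffolds[scaf]),
                end_window=config.end_window,
                unmapped_reads=mapping.unmapped_reads,
                scaffold_seq=scaffolds[scaf],
            )
            stage.setdefault("circularity", {})[scaf] = support
        gene_region = config.gene_region
        if gene_region is None and scenario is not None:
            extras = scenario.truth.extras
            if "gene_region" in extras:
                gene_region = ("host1", *extras["gene_region"])
        if gene_region is not None:
            scaf, start, end = gene_region
            calls = ev.call_disrupting_variants(
                mapping.pairs, scaffolds[scaf], scaf, Region(start, end),
                min_depth=config.min_depth,
            )
            stage["variants"] = [to_plain(c) for c in calls]
        if scenario is not None and "fragment_orfs" in scenario.truth.extras:
            extras = scenario.truth.extras
            frag = ev.detect_fragmented_gene(
                [(Region(a, b), "+") for a, b in extras["fragment_orfs"]],
                extras["reference_protein"],
                extras["population_gene"],
            )
            stage["fragmentation"] = to_plain(frag) if frag else None
        report["stages"]["evidence"] = stage
        timings["evidence"] = time.perf_counter() - t0

    if out:
        write_reports(
            out, report,
            detected=detected, catalog=catalog, graph=graph,
            reconstruction=reconstruction, hits=kept_hits,
            self_records=self_records,
        )
        io_mod.write_json({"seconds": {k: round(v, 3) for k, v in timings.items()}},
                          out / "timings.json")
    return report


def write_reports(out_dir, report, detected=None, catalog=None, graph=None,
                  reconstruction=None, hits=None, self_records=None) -> None:
    """Write stage artifacts with stable column orders."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_json(report, out / "report.json")

    if detected is not None:
        rows = [
            {"scaffold": a.scaffold_id, "start": a.span.start, "end": a.span.end,
             "n_units": a.n_units, "consensus": a.repeat_consensus,
             "leader_side": a.leader_side}
            for a in detected
        ]
        pd.DataFrame(
            rows, columns=["scaffold", "start", "end", "n_units", "consensus",
                           "leader_side"]
        ).to_csv(out / "arrays.tsv", sep="\t", index=False)
    if catalog is not None:
        io_mod.write_fasta(
            {f"{sid}_x{catalog.multiplicity[sid]}": seq
             for sid, seq in catalog.sequences.items()},
            out / "spacers.fasta",
        )
    if graph is not None:
        pd.DataFrame(
            [{"from": u, "to": v, "weight": w} for (u, v), w in sorted(graph.edges.items())],
            columns=["from", "to", "weight"],
        ).to_csv(out / "spacer_graph.tsv", sep="\t", index=False)
    if reconstruction is not None:
        io_mod.write_json(reconstruction, out / "reconstruction.json")
    if hits is not None:
        io_mod.write_hits(hits, out / "hits.tsv", out / "hits.bed")
    if self_records is not None:
        pd.DataFrame(
            [to_plain(r) for r in self_records],
            columns=["spacer_id", "target_scaffold", "start", "end", "strand",
                     "target_gene", "intergenic"],
        ).to_csv(out / "self_targets.tsv", sep="\t", index=False)

    with open(out / "report.txt", "w") as fh:
        fh.write(render_text_report(report, reconstruction))


def render_text_report(report: dict, reconstruction=None) -> str:
    lines = ["spacertrace run report", "=" * 22, ""]
    for stage, data in report.get("stages", {}).items():
        lines.append(f"[{stage}]")
        for key, value in data.items():
            if isinstance(value, (int, float, str)):
                lines.append(f"  {key}: {value}")
            elif isinstance(value, list) and key in ("motifs", "warnings"):
                lines.append(f"  {key}: {', '.join(map(str, value)) or '-'}")
        lines.append("")
    if reconstruction is not None and reconstruction.consensus_order:
        lines.append("locus diagram (leader -> distal):")
        cells = []
        recent = set(reconstruction.recent_spacers)
        for s in reconstruction.consensus_order:
            cells.append(f"[{s[:6]}..]")
        diagram = "R-" + "-R-".join(cells) + "-R"
        lines.append("  " + diagram)
        if recent:
            lines.append(
                "  recent (leader-end, subpopulation): "
                + ", ".join(f"{s[:6]}.." for s in sorted(recent))
            )
        lines.append("")
    return "\n".join(lines)
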