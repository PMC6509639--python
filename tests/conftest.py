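"""Shared fixtures: generated scenarios and end-to-end pipeline runs.

Everything is generated programmatically at test time; session scope keeps
the expensive end-to-end run to a single execution.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import spacertrace as st
from spacertrace.pipeline import RunConfig, run_pipeline
from spacertrace.scenarios import scenario_fcasy

FCASY_SEED = 1


@dataclass
class FcasyRun:
    scenario: "st.scenarios.Scenario"
    report: dict
    reconstruction: st.LocusReconstruction
    graph: st.SpacerGraph
    array: st.CrisprArray


@pytest.fixture(scope="session")
def fcasy_scenario():
    return scenario_fcasy(FCASY_SEED)


@pytest.fixture(scope="session")
def fcasy_run(fcasy_scenario) -> FcasyRun:
    """End-to-end pipeline run plus the intermediate locus objects."""
    report = run_pipeline(RunConfig.from_dict({"scenario": "fcasy", "seed": FCASY_SEED}))

    sc = fcasy_scenario
    arrays = st.find_arrays(sc.scaffolds["host1"], scaffold_id="host1")
    assert len(arrays) == 1
    array = st.orient_array(arrays[0], cas_gene_hint=sc.cas_gene_hint)
    reads = [r for p in sc.reads for r in (p.r1, p.r2)]
    recruited = st.recruit_repeat_reads(reads, array.repeat_consensus, 2)
    strict = [st.split_read_into_spacers(r, array.repeat_consensus, 2) for r in recruited]
    graph = st.build_spacer_graph(strict)
    obs_support: dict[str, int] = {}
    for r in recruited:
        obs = st.extract_spacer_observations(
            r, array.repeat_consensus, 2, spacer_len=(18, 72)
        )
        for s in set(obs):
            obs_support[s] = obs_support.get(s, 0) + 1
    for s, n in obs_support.items():
        graph.support[s] = max(graph.support.get(s, 0), n)
    reconstruction = st.consensus_locus_order(graph)
    return FcasyRun(
        scenario=sc, report=report, reconstruction=reconstruction,
        graph=graph, array=array,
    )
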