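"""Target search: dereplication, scanning vs oracle, filtering, self-targets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import pandas as pd

from spacertrace.search import (
    SpacerCatalog,
    classify_target_scaffold,
    dereplicate_spacers,
    exclude_array_self_hits,
    find_protospacer_hits,
    flag_self_targeting,
    scan_bruteforce,
)
from spacertrace.seq import random_dna, revcomp
from spacertrace.types import CrisprArray, ProtospacerHit, Region, Spacer


class TestDereplication:
    def test_duplicates_collapse_with_multiplicity(self):
        s, t = "ACGT" * 5, "TTGC" * 5
        cat = dereplicate_spacers([s, s, t])
        assert len(cat) == 2
        assert sorted(cat.multiplicity.values()) == [1, 2]

    def test_idempotent(self):
        seqs = ["ACGT" * 5, "TTGC" * 5, "ACGT" * 5]
        once = dereplicate_spacers(seqs)
        twice = dereplicate_spacers(once.sequences.values())
        assert set(twice.sequences.values()) == set(once.sequences.values())
        assert all(m == 1 for m in twice.multiplicity.values())

    def test_revcomp_pair_kept_distinct_but_crosslinked(self):
        s = "AAACGTTGCAACGTTGCAAC"  # not its own reverse complement
        cat = dereplicate_spacers([s, revcomp(s)])
        assert len(cat) == 2
        assert len(cat.revcomp_pairs) == 1


class TestScanning:
    def test_planted_spacer_found_at_position(self):
        rng = np.random.default_rng(0)
        scaffold = random_dna(200, rng)
        spacer = scaffold[3:23]
        cat = dereplicate_spacers([spacer])
        hits = find_protospacer_hits(cat, {"sc": scaffold})
        assert any(h.start == 3 and h.end == 23 and h.strand == "+" for h in hits)

    def test_revcomp_planting_gives_minus_hit_same_interval(self):
        rng = np.random.default_rng(1)
        scaffold = random_dna(200, rng)
        spacer = revcomp(scaffold[50:80])
        hits = find_protospacer_hits(dereplicate_spacers([spacer]), {"sc": scaffold})
        assert any(h.start == 50 and h.end == 80 and h.strand == "-" for h in hits)

    def test_search_mirrors_under_scaffold_revcomp(self):
        rng = np.random.default_rng(2)
        scaffold = random_dna(400, rng)
        spacer = scaffold[100:130]
        cat = dereplicate_spacers([spacer])
        fwd = find_protospacer_hits(cat, {"sc": scaffold})
        rev = find_protospacer_hits(cat, {"sc": revcomp(scaffold)})
        mirrored = {
            (len(scaffold) - h.end, len(scaffold) - h.start,
             "+" if h.strand == "-" else "-")
            for h in rev
        }
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            find_protospacer_hits(dereplicate_spacers(["ACGTACGTAC"]), {"sc": "A" * 100})

    def test_ambiguous_base_spacer_warns_and_yields_nothing(self, caplog):
        import logging

        cat = dereplicate_spacers(["ACGTNACGTACGTACGTACG"])
        with caplog.at_level(logging.WARNING):
            hits = find_protospacer_hits(cat, {"sc": "ACGT" * 50})
        assert hits == []
        assert any("non-ACGT" in r.message for r in caplog.records)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    hst.integers(min_value=0, max_value=10_000),
    hst.integers(min_value=0, max_value=2),
)
def test_indexed_scan_equals_bruteforce_oracle(seed, max_mismatch):
    """The pigeonhole-index scanner must reproduce the sliding-window scan."""
    rng = np.random.default_rng(seed)
    scaffold = random_dna(2000, rng)
    spacers = {}
    for i in range(5):
        spacers[f"r{i}"] = random_dna(18 + int(rng.integers(0, 15)), rng)
    for i in range(5):
        pos = int(rng.integers(0, 1960))
        s = scaffold[pos : pos + 25]
        spacers[f"p{i}"] = s if rng.random() < 0.5 else revcomp(s)
    cat = SpacerCatalog(sequences=spacers, multiplicity={k: 1 for k in spacers})
    hits = find_protospacer_hits(cat, {"sc": scaffold}, max_mismatch=max_mismatch)
    got = {(h.spacer_id, h.start, h.strand, h.mismatches) for h in hits}
    expected = set()
    for sid, s in spacers.items():
        for start, strand, mm in scan_bruteforce(s, scaffold, max_mismatch):
            expected.add((sid, start, strand, mm))
    assert got == expected


def _array_on(scaffold_id, start, repeat_len=25, n_spacers=2, spacer_len=20):
    pos = start
    repeats, spacers = [], []
    for i in range(n_spacers + 1):
        repeats.append(Region(pos, pos + repeat_len))
        pos += repeat_len
        if i < n_spacers:
            spacers.append(Spacer(sequence="A" * spacer_len, array_id="arr1"))
            pos += spacer_len
    return CrisprArray(
        scaffold_id=scaffold_id, repeat_consensus="G" * repeat_len,
        repeat_instances=repeats, spacers=spacers, array_id="arr1",
    )


class TestExclusion:
    def test_hit_inside_array_span_removed(self):
        arr = _array_on("sc", 100)
        hit = ProtospacerHit("s1", "sc", 130, 150, "+")
        kept, removed = exclude_array_self_hits([hit], [arr])
        assert kept == [] and removed == [hit]

    def test_hit_adjacent_to_span_retained(self):
        arr = _array_on("sc", 100)  # span [100, 215)
        hit = ProtospacerHit("s1", "sc", 215, 235, "+")
        kept, removed = exclude_array_self_hits([hit], [arr])
        assert kept == [hit] and removed == []

    def test_no_arrays_is_identity(self):
        hit = ProtospacerHit("s1", "sc", 10, 30, "+")
        assert exclude_array_self_hits([hit], []) == ([hit], [])


class TestClassification:
    def _ann(self, product):
        return pd.DataFrame(
            [{"scaffold": "sc", "start": 0, "end": 300, "strand": "+",
              "product": product}]
        )

    def test_capsid_product_is_phage_like(self):
        hits = [ProtospacerHit(f"s{i}", "sc", 10 * i, 10 * i + 20, "+") for i in range(3)]
        c = classify_target_scaffold("sc", hits, self._ann("major capsid protein"))
        assert c.category == "phage_like"
        assert c.n_hits == 3

    def test_tail_fiber_matches_tail_keyword(self):
        hits = [ProtospacerHit("s1", "sc", 10, 30, "+")]
        c = classify_target_scaffold("sc", hits, self._ann("tail fiber protein"))
        assert c.category == "phage_like"

    def test_no_annotations_is_unclassified(self):
        hits = [ProtospacerHit("s1", "sc", 10, 30, "+")]
        c = classify_target_scaffold("sc", hits, None)
        assert c.category == "unclassified"
        assert c.distinct_spacers == 1


class TestSelfTargeting:
    def _setup(self):
        arr = _array_on("host_a", 100)
        bins = {"host_a": "bin1", "host_b": "bin1", "phage": "bin2"}
        sources = {"s1": "arr1", "s2": "arr1"}
        return arr, bins, sources

    def test_same_bin_hit_outside_array_is_self(self):
        arr, bins, sources = self._setup()
        hit = ProtospacerHit("s1", "host_b", 500, 520, "+")
        recs, unresolved = flag_self_targeting([hit], bins, [arr], sources)
        assert len(recs) == 1 and recs[0].spacer_id == "s1"
        assert recs[0].intergenic
        assert unresolved == 0

    def test_other_bin_hit_is_not_self(self):
        arr, bins, sources = self._setup()
        hit = ProtospacerHit("s1", "phage", 500, 520, "+")
        recs, _ = flag_self_targeting([hit], bins, [arr], sources)
        assert recs == []

    def test_unbinned_target_counted_unresolved(self):
        arr, bins, sources = self._setup()
        hit = ProtospacerHit("s1", "mystery", 500, 520, "+")
        recs, unresolved = flag_self_targeting([hit], bins, [arr], sources)
        assert recs == [] and unresolved == 1

    def test_target_gene_reported_when_annotated(self):
        arr, bins, sources = self._setup()
        ann = pd.DataFrame(
            [{"scaffold": "host_b", "start": 450, "end": 600, "strand": "+",
              "product": "PINc domain ribonuclease"}]
        )
        hit = ProtospacerHit("s1", "host_b", 500, 520, "+")
        recs, _ = flag_self_targeting([hit], bins, [arr], sources, annotations=ann)
        assert recs[0].target_gene == "PINc domain ribonuclease"
        assert not recs[0].intergenic
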