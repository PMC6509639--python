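# spacertrace

Spacer-centric CRISPR analyses for metagenomes: de novo repeat-spacer array
detection, read-level reconstruction of the population CRISPR locus, exact
protospacer search linking spacers to (pro)phage scaffolds, in-silico PAM
inference, self-targeting spacer detection, prophage activity and
circularization evidence, and fragmented-gene variant analysis — together
with a synthetic-data generator that plants all of the above with
machine-readable ground truth.

## Who this is for

Microbial ecologists and phage biologists working with assembled
metagenomes who want to exploit CRISPR immunological memory: which phage
infect which host population, whether a locus is actively diversifying,
whether a spacer set includes self-targets, and whether an integrated
prophage is producing free particles. The package targets the regime of
small host genomes (e.g. Candidate Phyla Radiation bacteria at ~31–33% GC)
with short-read population data, where the CRISPR locus visible on the
assembled scaffold is only the shared core of a diversifying population.

## The model in brief

A CRISPR locus is the alternation `R S₁ R S₂ … Sₙ R` of a conserved direct
repeat R (21–48 nt) and variable spacers Sᵢ (18–72 nt). New spacers are
acquired at the **leader end**, so sub-populations differ by leader-end
additions and occasional loss of whole repeat-spacer units.

* **Array detection** seeds on exact k-mers (k = 8) recurring at admissible
  periods (repeat + spacer length) and extends the aligned instances
  column-by-column under a per-instance mismatch budget (default ≤ 2), in
  the style of CRT-class repeat finders.
* **Locus reconstruction** recruits repeat-bearing reads, splits them into
  spacers at repeat boundaries, and builds a directed **spacer graph**:
  node support = reads containing the spacer, edge weight w(u→v) = reads
  where v immediately follows u (leader → distal). The consensus order is
  the maximum-support path after collapsing cycles; edges that skip a
  consensus spacer give per-unit loss fractions w_skip/(w_skip+w_through);
  low-support leader attachments are flagged **recent**.
* **Protospacer search** is full-length, both-strand matching at a
  configurable substitution budget (default 0 mismatches, 100% coverage),
  implemented as a pigeonhole-chunk k-mer index and verified against a
  naive sliding-window oracle. Hits inside any array span are excluded;
  hits on scaffolds of the spacer's own genome bin are **self-targeting**.
* **PAM inference** takes the 5 bp upstream/downstream of each hit on the
  targeted strand, deduplicates to unique target locations, and aggregates
  a position frequency matrix, per-position information content
  `2 + Σ_b f_b log₂ f_b` (bits), and 5′ dinucleotide motif counts.
* **Evidence layers** map pairs with an exact-31-mer-seeded ungapped
  mapper (short-deletion rescue via split seeds) and drop pairs with ≥ 2
  substitution mismatches combined across both mates. Retained alignments
  drive prophage region/flank coverage ratios, outward-pair and split-read
  circularity support, pileup variant calls with in-frame consequence
  annotation (nonsense / frameshift-stop, stop offset in codons), and
  split-ORF fragmented-gene calls by local protein alignment.

## Worked example

```python
from spacertrace.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig.from_dict({"scenario": "fcasy", "seed": 1}))
s = report["stages"]
print(s["search"]["n_unique_spacers"],
      s["reconstruct"]["n_recent"],
      s["search"]["n_self_targeting_spacers"],
      s["pam"]["self_targets"]["motif_counts"])
```

prints

```
22 6 12 {'TA': 7, 'TG': 4, 'AT': 1}
```

meaning: from 150-bp error-free pairs at 50× host coverage the pipeline
recovered all 22 unique spacers of the planted locus, flagged the 6
subpopulation-specific leader-end spacers as recent acquisitions,
identified the 12 spacers with targets in the host's own bin, and read the
planted 7×TA / 4×TG / 1×AT PAM mix off the self-target flanks (motif call
`[TA, TG]`). The same run's variant calls report the planted
gene-disrupting deletion at 100% of reads (stop 5 codons downstream) and
the nonsense substitution near its planted 82% population fraction.

The `examples/` directory holds one short script per capability
(simulation, array detection, locus reconstruction, target search + PAM,
prophage/variant evidence); each prints the numbers it computes and what
they mean. A thin CLI mirrors the library:

```bash
spacertrace simulate --scenario fcasy --seed 1 --out out/
spacertrace detect-arrays --scaffolds out/scaffolds.fasta --out out/arrays/
spacertrace run-all --scenario fcasy --seed 1 --out out/run/
```

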