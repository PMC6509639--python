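"""Generate a synthetic host population with a diversifying CRISPR locus.

Builds the fragmented-effector scenario: a host carrying a 16-spacer CRISPR
locus, six sub-populations that have each acquired one extra leader-end
spacer, a second host scaffold with self-targeted protospacers, a free
phage, and 150-bp paired reads at 50x host coverage.
"""

from spacertrace.scenarios import scenario_fcasy

sc = scenario_fcasy(seed=1)

print(f"scaffolds : {', '.join(f'{k} ({len(v):,} bp)' for k, v in sc.scaffolds.items())}")
print(f"read pairs: {len(sc.reads):,} (150 bp, error-free)")
print(f"planted   : {len(sc.truth.spacer_catalog)} unique spacers "
      f"({len(sc.truth.recent_spacers)} recent, leader end)")
print(f"            {len(sc.truth.self_targets)} self-targeting protospacers, "
      f"{len(sc.truth.protospacers)} phage protospacers")
print(f"            {len(sc.truth.variant_fractions)} gene-disrupting mutations "
      f"at fractions {[v['fraction'] for v in sc.truth.variant_fractions]}")

# The truth bundle is what recovery is tested against: every planted
# feature (locus orders, protospacer coordinates, PAMs, variant fractions)
# is recorded there, and io.write_scenario() serializes everything to
# FASTA/FASTQ/TSV/JSON.
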