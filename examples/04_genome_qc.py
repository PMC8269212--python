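"""Sequencing-QC statistics of sorted-cell genomes.

Summarizes the bundled mock-community benchmark table (per-species mapping
averages, success rates) and computes alignment-based completeness on a
synthetic single-cell assembly.
"""

from ramansort import data, seqqc
from ramansort import synthetic as syn

# --- benchmark table ------------------------------------------------------
summary = seqqc.batch_summary(data.mock_benchmark_records(), data.SORTED_COUNTS)
print(summary.per_group.to_string(index=False))
print("\nspecies-average mapping range:",
      summary.min_species_mapping, "-", summary.max_species_mapping, "%")

counts = data.success_counts()
print("morphology-sort success rate:",
      seqqc.success_rate(counts["mock_morphology"]["n_positive"],
                         counts["mock_morphology"]["n_sorted"], 1), "%")

# --- completeness of a partial assembly -----------------------------------
genome = syn.SyntheticGenome("cell", 100_000, 0.51, seed=5)
reference = genome.sequence()
contigs = syn.make_contigs(genome, 25, (1000, 4000), seed=6)
completeness = seqqc.completeness_by_aligned_bases(contigs, reference)
print(f"\nsynthetic assembly covers {completeness}% of its reference")

# The per-species means reproduce the benchmark's printed averages exactly
# (half-up rounding to two decimals); completeness counts every reference
# base covered by at least one contig alignment.
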