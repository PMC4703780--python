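"""Bin contigs by tetranucleotide signature, GC and coverage.

Fragments the synthetic genomes into contigs (standing in for assembly),
maps the reads to get per-contig coverage, clusters the contigs, and prints
the bin summary table plus recovery against the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from denitromics import abundance, binning, pipeline, synthetic

spec = pipeline.default_community_spec(seed=42, n_populations=5,
                                       genome_length=60_000,
                                       n_dna_reads=10_000)
community = synthetic.generate_community(spec)
contigs, contig_map = synthetic.fragment_genomes(community.genomes,
                                                 n50_target=10_000,
                                                 min_len=1_000, seed=42)
reads = synthetic.simulate_reads(community.genomes, community.abundances, spec)
assignments = abundance.assign_reads(reads, contigs)
lengths = {c: len(s) for c, s in contigs.items()}
coverage = abundance.contig_coverage(assignments, lengths)

bins = binning.cluster_contigs(contigs, coverage.to_dict())
stats = binning.bin_stats(bins, contigs, coverage.to_dict())
print(stats[["Bin", "Size (kb)", "Number of contigs (#)",
             "N50 contig length (kb)", "GC content (%)",
             "Mean coverage (x)"]].to_string(index=False))

truth = contig_map.set_index("contig")["population"].reindex(bins.index)
print(f"\nadjusted Rand index vs planted truth: "
      f"{adjusted_rand_score(truth, bins):.3f}")

ab = abundance.bin_abundance(coverage, bins, lengths)
print("\nestimated relative abundance per bin (assigned-base fractions):")
print(ab["abundance"].round(3).to_string())
print("\nAn ARI of 1.0 means every contig landed in the bin of its source")
print("population; abundances approximate the planted 0.516/0.258/... series.")
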