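"""Stage-exclusive markers, temporal clusters, and promoter extraction.

Calls markers with the exclusivity + upregulation rule, clusters temporal
profiles with k-means, and extracts strand-aware promoter windows around
the 16-cell-stage markers (the input one would hand to a motif-discovery
suite)."""

import tfekit as tk

bundle = tk.simulate_study(tk.SimConfig(seed=1, n_chromosomes=3,
                                        chromosome_length=500_000,
                                        n_coding_genes=250,
                                        n_noncoding_genes=60,
                                        n_markers_per_stage=5))
matrix, _ = tk.quantify(bundle.events, bundle.sheet)
factors = tk.spikein_size_factors(matrix)
values = tk.log2_normalize(matrix, factors)
de = tk.de_all_contrasts(matrix, factors, bundle.sheet)

medians = tk.stage_medians(values, bundle.sheet)
markers = tk.call_stage_markers(medians, de,
                                stage_order=tuple(bundle.sheet.stages_used()))
for stage in markers.stages:
    print(f"{stage}: {len(markers.for_stage(stage))} exclusive marker TFEs")

# k-means on row-scaled pseudocount values of all expressed TFEs
values_pc = tk.log2_normalize(matrix, factors, pseudocount=1.0)
expressed = values_pc.loc[(matrix.endogenous().sum(axis=1) > 0)
                          [lambda s: s].index]
scaled = tk.scale_rows(expressed)
clusters = tk.kmeans_profiles(scaled, k=6, restarts=100, seed=1)
print(f"\nk-means (k=6): WCSS {clusters.wcss:.1f}; cluster sizes "
      f"{clusters.labels.value_counts().sort_index().tolist()}")

# promoter windows for the 16c markers: 400 bp up / 100 bp down of summits
target = markers.for_stage("16c")
windows = tk.promoter_windows(matrix.regions.loc[target], up=400, down=100,
                              chrom_sizes=bundle.reference.chrom_sizes)
seqs = tk.extract_promoter_sequences(windows, bundle.reference.sequences)
name, seq = next(iter(seqs.items()))
print(f"\n{len(seqs)} promoter sequences; first: {name} ({len(seq)} bp)")
# Each sequence covers 400 bases 5' of the TFE summit and 100 from the
# summit 3'-ward, reverse-complemented on minus-strand TFEs.
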