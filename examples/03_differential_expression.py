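"""Consecutive-stage differential expression across the MZT.

Runs the negative-binomial Wald test for every later-vs-earlier stage pair
and prints up/down counts, which trace the two maternal degradation waves
and the zygotic activation burst."""

import tfekit as tk

bundle = tk.simulate_study(tk.SimConfig(seed=1, n_chromosomes=3,
                                        chromosome_length=500_000,
                                        n_coding_genes=250,
                                        n_noncoding_genes=60,
                                        n_markers_per_stage=5))
matrix, _ = tk.quantify(bundle.events, bundle.sheet)
factors = tk.spikein_size_factors(matrix)

print(f"{(~matrix.spike_mask).sum()} TFEs, "
      f"{len(bundle.sheet.sample_ids)} samples\n")
print(f"{'contrast':>12}  {'up':>5}  {'down':>5}")
for contrast, table in tk.de_all_contrasts(matrix, factors, bundle.sheet).items():
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    print(f"{contrast.label():>12}  {n_up:>5}  {n_down:>5}")
# Maternal degradation shows as downregulation entering 2c and, much more
# strongly, at 16c; the 16c transition also carries the largest
# upregulation burst (zygotic genome activation), with renewed synthesis
# at the blastocyst.  At this small example scale the 2c wave is mostly
# visible in fold changes rather than significant counts.
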