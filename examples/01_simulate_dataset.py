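"""Simulate a five-group allotetraploid RNA-seq experiment.

Two diploid progenitors (Cg2, Co2), two resynthesized allotetraploid
groups (Sd, Sh) and one natural allotetraploid group (Cbp), six lines
each; allotetraploid individuals carry homoeologous-exchange copy-number
blocks and ~50% of their reads can be phased to a subgenome.
"""

from homeobias import SimConfig, simulate_experiment

cfg = SimConfig(n_chromosomes=4, genes_per_chromosome=150, seed=1)
ds = simulate_experiment(cfg)

print(f"unphased counts: {ds.unphased.counts.shape[0]} genes x {ds.unphased.counts.shape[1]} samples")
print(f"allotetraploid individuals with phased counts: {len(ds.phased.individuals)}")

assigned = ds.phased.totals().sum().sum()
total = ds.phased.unphased().sum().sum()
print(f"phasing proportion: {assigned / total:.3f}  (fraction of reads assigned to a subgenome)")

unbal = ds.truth.unbalanced_fraction()
print(f"true unbalanced copy-number fraction: {unbal:.3f}  (gene-individual pairs not 2:2)")

counts = [len(b) for b in ds.truth.breakpoints.values()]
print(f"true breakpoints per chromosome quartet: {sum(counts) / len(counts):.3f}")
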