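"""Generate a small synthetic ribosome-profiling study and look at its parts.

Builds an annotation (with TOP-motif flags), per-replicate footprint and
mRNA-Seq reads, and gene x sample count tables for a control and an
exercise condition.
"""

from riboshift import (
    SimulationConfig,
    count_reads,
    make_count_table,
    simulate_abundances,
    simulate_annotation,
    simulate_rpf_reads,
)

cfg = SimulationConfig(seed=0, n_genes=200, depth_rpf=100_000, depth_mrna=100_000)
annotation = simulate_annotation(cfg)
print(f"{len(annotation)} genes, {len(annotation.top_gene_ids)} carry a TOP motif")

abundances = simulate_abundances(cfg, annotation, "control")
reads = simulate_rpf_reads(cfg, annotation, abundances, "control_rep1", "rep1")
print(f"{len(reads)} footprints drawn; first rows:")
print(reads.head(3).to_string(index=False))

counts = make_count_table(
    [count_reads(reads, annotation, "control_rep1")]
)
print("count table head:")
print(counts.head(3))
# Each footprint is ~30 nt with its 5' end biased to the main reading frame;
# counts per gene follow a multinomial over the genes' ribosome loading, so
# the column sum equals the sequencing depth exactly.
print("library size:", counts["control_rep1"].sum())
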