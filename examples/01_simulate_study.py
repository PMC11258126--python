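"""Generate a small synthetic multi-cohort methylation/expression study.

The generator plants a sparse regulatory network (edge probability decaying
with promoter distance, a core shared across cohorts plus cohort-specific
edges, five multi-target hub elements) and emits everything the pipeline
consumes: gene annotation, probe manifest, paired beta/expression matrices,
loops, clinical follow-up and a perturb-seq screen.
"""

from methlink import genome, simulate

cfg = simulate.SimConfig(seed=1, n_genes=20, n_clusters=300, genome_length=10_000_000,
                         n_cohorts=2, samples_per_cohort=120)
genes, probes = simulate.simulate_genome(cfg)
cluster_map = genome.cluster_probes(probes)
adjacency = genome.build_adjacency(genes, cluster_map)
datasets, truth = simulate.simulate_cohorts(cfg, cluster_map, adjacency)

print(f"genes: {len(genes)}, probes: {len(probes)}, CpG clusters: {cluster_map.n_clusters}")
print(f"candidate gene-cluster pairs within 1 Mb: {len(adjacency)}")
print(f"planted true edges: {len(truth.edges)} "
      f"({(truth.edges['scope'] == 'core').sum()} core, shared by all cohorts)")
print(f"planted hub elements: {truth.hub_ids}")
for ds in datasets:
    print(f"{ds.cancer_id}: {ds.expression.shape[0]} genes x {ds.n_samples} samples, "
          f"{(ds.sample_type == 'tumor').sum()} tumor / {(ds.sample_type == 'normal').sum()} normal")
# Each candidate pair links a gene promoter to a CpG cluster within 1 Mb;
# only the planted edges carry a real methylation -> expression effect.
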