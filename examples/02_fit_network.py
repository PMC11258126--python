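"""Fit the per-gene elastic-net association models for one cohort and
compare the recovered network against the planted truth.

Each gene's log expression is regressed on the beta values of every CpG
cluster within 1 Mb of its promoter, with unpenalized tumor/normal
intercepts and (lambda, alpha) tuned by 10-fold cross validation.
"""

import numpy as np

from methlink import expression, genome, simulate

cfg = simulate.SimConfig(seed=1, n_genes=15, n_clusters=200, genome_length=8_000_000,
                         n_cohorts=1, samples_per_cohort=120)
genes, probes = simulate.simulate_genome(cfg)
cluster_map = genome.cluster_probes(probes)
adjacency = genome.build_adjacency(genes, cluster_map)
datasets, truth = simulate.simulate_cohorts(cfg, cluster_map, adjacency)

net = expression.fit_cancer_network(datasets[0], adjacency, seed=1)
est = net.edges.set_index(["gene_id", "cluster_id"])["coefficient"]
active = truth.edges[truth.edges["scope"].isin(["core", "cohort0"])]
hits = sum(est.get((e["gene_id"], e["cluster_id"]), 0.0) != 0 for _, e in active.iterrows())

print(f"genes passing the sd >= 1 expression filter: {len(net.fits)}")
print(f"nonzero associations selected: {len(net.edges)}")
print(f"planted edges recovered: {hits}/{len(active)}")
print(f"mean cross-validated R^2: {np.mean([f.cv_r2 for f in net.fits]):.2f}")
# A negative coefficient means methylation gain at the element lowers the
# gene's expression (an activating element); positive means repressing.
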