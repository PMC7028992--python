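"""Build the bipartite eQTL network and detect its communities.

Edges are SNP-gene pairs significant at q < 0.2; analyses use the giant
connected component.  Community detection maximizes bipartite modularity;
per-SNP core scores measure each SNP's contribution to its community.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from eqtlnet import (PipelineConfig, build_network, core_scores,
                     detect_communities, giant_component, run_eqtl_scan)
from eqtlnet.simulate import SimulationDesign, simulate_dataset

design = SimulationDesign(n_samples=150, n_blocks=12, snps_per_block=4,
                          n_genes=45, n_communities=3, seed=7)
genotypes, expression, _, covariates, annotation, _, _, truth = simulate_dataset(design)

config = PipelineConfig()
table = run_eqtl_scan(genotypes, expression, covariates, config, gene_ann=annotation)
network = giant_component(build_network(table, config.fdr_threshold))
print(f"giant component: {len(network.snp_nodes)} SNPs, "
      f"{len(network.gene_nodes)} genes, {network.m} edges")

assignment = detect_communities(network, seed=config.rng_seed)
print(f"{assignment.n_communities} communities, modularity Q = {assignment.modularity:.3f}")

truth_map = pd.concat([truth.snp_community, truth.gene_community.dropna()])
nodes = [n for n in network.snp_nodes + network.gene_nodes if n in truth_map.index]
ari = adjusted_rand_score([truth_map[n] for n in nodes], list(assignment.labels(nodes)))
print(f"adjusted Rand index vs planted communities: {ari:.3f}")
# ARI = 1 means the detected partition matches the planted one exactly;
# Q near 0.6-0.7 reflects strong modular structure plus the noise edges
# admitted by the permissive FDR threshold.

scores = core_scores(network, assignment)
print("top community-core SNPs:")
print(scores.sort_values("core_score", ascending=False).head(5))
# High core scores mark local hubs: SNPs wired to many genes of their own
# community; the scores of all SNPs sum exactly to Q.
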