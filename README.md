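# eqtlnet

Systems-level analysis of how trait-associated (e.g. cancer-risk) germline
SNPs act through gene regulation.  The package maps expression quantitative
trait loci (eQTLs), represents them as a bipartite SNP–gene network,
decomposes the network into modularity-maximizing communities, and tests
where GWAS risk SNPs sit in that structure — which communities they
concentrate in, whether they are community "cores", and whether they
preferentially target a user-supplied list of cancer genes.

It is written for statistical geneticists and systems biologists who have
genotype, expression and covariate tables plus GWAS labels, and want the
network stage of the analysis as a tested, reusable library.  A
synthetic-data generator with planted structure supplies ground truth for
every stage, so the whole pipeline is verifiable end to end without any
controlled-access data.

## The model

**eQTL mapping.** Every SNP–gene pair is tested with an additive linear
model

```
Expression ~ Genotype + Age + Sex + EthnicBackground + PC1 + PC2 + PC3 + ε
```

with a two-sided t-test on the genotype coefficient.  A pair is *cis* when
the SNP lies within 1 Mb of the gene's transcription start site on the same
chromosome, otherwise *trans*; Benjamini–Hochberg correction is applied to
the cis and trans strata separately and pairs with q < 0.2 become network
edges (permissive on purpose: network centrality is hurt more by missing
edges than by spurious ones).

**Bipartite modularity (condor-style).** For the giant connected component
with m edges, binary biadjacency Ã, SNP degrees k_i, gene degrees d_j and
community labels C,

```
Q = (1/m) Σ_ij (Ã_ij − k_i d_j / m) δ(C_i, C_j)
```

is maximized by alternating closed-form reassignment sweeps over the two
node sides, seeded from a clustering of the weighted gene-space projection,
followed by an exact local search over gene-side partitions (single moves,
pair moves, swaps, merges).  Networks whose smaller side has ≤ 7 nodes are
solved exactly by enumeration.

**SNP core scores.** `Q_ih = (1/m) Σ_j (Ã_ij − k_i d_j/m) δ(C_i,h) δ(C_j,h)`
is SNP i's additive contribution to its community's modularity; core scores
sum exactly to Q and mark local community hubs.

**Risk statistics, in LD-block units.** Risk labels (GWAS p ≤ 5×10⁻⁸)
propagate to block-mates and to SNPs with r² > 0.8.  Communities are tested
for risk-block enrichment with one-sided Fisher tests (whole network as
background, called only with ≥ 4 risk blocks and BH q < 0.05); community
genes are tested against GMT gene sets by hypergeometric overrepresentation;
promoters ([TSS−750, TSS+250], strand-aware) are tested for risk-block
occupancy.  Two bespoke tests follow: a degree-matched resampling test on
each SNP's "cancer degree" (Mann–Whitney U against pseudo-risk sets drawn
within total-degree deciles) and a likelihood-ratio test of
`block-median Q_ih ~ risk status + community indicators` against the model
without risk status (χ², 1 df).

## Worked example

```bash
python examples/02_network_communities.py
```

prints (150 samples, 12 LD blocks, 45 genes, 3 planted communities):

```
giant component: 48 SNPs, 49 genes, 631 edges
3 communities, modularity Q = 0.568
adjusted Rand index vs planted communities: 1.000
```

All significant associations fall into one connected component; the
optimizer finds exactly three communities that match the planted partition
perfectly (ARI = 1), with Q well above 0 (a single community scores Q = 0
exactly).  `examples/03_risk_enrichment.py` continues on the default design
and prints the per-community Fisher table — exactly the two planted risk
communities are called enriched — and
`examples/04_risk_statistics.py` prints

```
cancer-degree resampling: U_obs = 344, null mean 258 +/- 23, empirical p = 0.001 ...
core-score LRT: statistic = 9.69 (df=1), p = 0.0019, risk coefficient = +0.0012 ...
```

meaning risk blocks target cancer genes beyond what their connectivity
predicts, and sit closer to their community cores than non-GWAS blocks.

The same pipeline is available from the shell:

```bash
eqtlnet simulate --out-dir data --seed 7
eqtlnet all --data-dir data --out-dir out --rng-seed 7
```

Each stage writes TSVs (`edges.tsv`, `network.tsv`, `communities.tsv`,
`core_scores.tsv`, `enrichment.tsv`, `risk_tests.tsv`) plus a log of every
configuration value; the same config and seed reproduce byte-identical
outputs.

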