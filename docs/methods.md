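# Methods

## Scope and data model

The package analyses one "tissue" at a time: a genotype matrix (samples ×
SNPs, additive 0/1/2 coding with explicit missing values), a normalized
expression matrix, a covariate table (age, sex, ethnic background, three
genotype principal components), gene annotation (chromosome, TSS, strand),
GWAS-catalog-like labels, a cancer-gene list and GMT gene sets.  All
genomic coordinates are 1-based internally; BED input is converted on read.
Sample sets are aligned by id intersection, kept in genotype order.

## eQTL mapping

Each SNP–gene pair is fit by OLS of expression on genotype dosage plus the
covariate design (intercept; categoricals dummy-coded against the first
level; categorical columns with fewer than two observed levels dropped).
The genotype coefficient's two-sided t-test gives the pair's p-value.
Missing genotypes are dropped pairwise — never imputed — and the
implementation residualizes expression and dosage against the covariates
once per missingness pattern (Frisch–Waugh–Lovell), which is algebraically
identical to the joint fit; an oracle test checks agreement with explicit
normal equations to 1e-10 on random designs.  Pairs whose genotype is
constant after dropping missing calls, or with fewer complete samples than
design columns + 2, are recorded as untestable and skipped.

Filters precede the scan: SNPs need call rate ≥ 0.9 and MAF ≥ 0.05
(removal is strict "under threshold", so the boundary survives); genes need
raw count ≥ 6 in ≥ 10 samples (skipped with a warning when no count matrix
is supplied).  A pair is cis iff same chromosome and |pos − TSS| ≤ 1 Mb —
the window boundary is inclusive, a choice the data model leaves open; it
is configurable.  BH adjustment runs within the cis stratum and the trans
stratum separately; edges are pairs with q < 0.2.  The threshold is
deliberately permissive: downstream network statistics degrade more under
false-negative edges than false-positive ones, and all block-level tests
absorb the extra noise.  It is a config value, not a constant.

## Network and communities

Significant pairs become unweighted edges of a bipartite SNP–gene graph
(effect sizes are kept only as edge annotation); community analyses use the
giant connected component, with ties between equal-size components broken
by edge count, then smallest member id — the tie rule is ours, chosen for
determinism.

Bipartite modularity of a labelled partition is

Q = (1/m) Σ_ij (Ã_ij − k_i d_j / m) δ(C_i, C_j),

computed per community as E_c − K_c·D_c/m (within-community edges minus the
degree-product null), which equals the double sum including all non-edges;
an exhaustive double-loop oracle verifies this to 1e-12.

Maximization exploits a structural fact: with the gene-side partition
fixed, each SNP's optimal community is the argmax of its own term
e_ic − k_i D_c / m (or a singleton scoring zero), independently of other
SNPs — so Q is effectively a function of the gene partition alone.  The
optimizer runs in three layers:

1. **Initialization**: greedy unipartite modularity clustering
   (networkx `greedy_modularity_communities`) of the weighted gene-space
   projection (genes linked by shared-SNP counts); each SNP adopts its gene
   neighbours' majority community.  Any reasonable initializer works; the
   contract is the bipartite phase.
2. **Alternating sweeps** (the condor/BRIM scheme): reassign every SNP,
   then every gene, to its term-maximizing community; each sweep maximizes
   Q given the other side, so Q is monotone non-decreasing.  Ties keep the
   current community to prevent oscillation.  A greedy community-merge step
   follows each round because single-node moves can neither split nor merge
   whole communities.
3. **Exact gene-space refinement**: local search over gene partitions with
   single-gene moves, coordinated pair moves (two SNP-sharing genes moved
   together), cross-community swaps and merges, each scored under the exact
   objective (SNPs implicitly re-optimized).  Several deterministic starts
   (projection, all-singleton, seeded random) and seeded
   perturb-and-redescend cycles guard against local optima.

Networks whose smaller side has ≤ 7 nodes skip the heuristic entirely: set
partitions of that side are enumerated (Bell(7) = 877 at most) and the
other side is assigned closed-form, which is provably optimal.  Tests
verify that the detector reaches the brute-force optimum on all graphs of
≤ 12 nodes in a fixed random family, and recovers planted partitions with
ARI ≥ 0.9 at pipeline scale.

Convergence tolerance is 1e-10 (configurable); at most 100 sweep rounds,
after which the best assignment so far is returned with a warning flag.

Core scores Q_ih are each SNP's term at its own community; their sum equals
Q exactly (floating tolerance 1e-12, tested).  No per-community
normalization is applied to Q_ih; instead community identity enters the
downstream regression as a covariate, which handles between-community
scale differences without distorting the scores themselves.

## LD blocks and risk mapping

r² is the squared Pearson correlation of additive codes on
pairwise-complete samples (composite LD — phase is not in the data model).
The built-in block builder is a left-to-right greedy scan: extend the block
while the candidate SNP has r² ≥ 0.8 with the block's first SNP and the
span stays ≤ 5 Mb.  It exists to serve synthetic data; haplotype-based
block definitions from upstream tooling can be supplied as a
(snp_id, block_id) TSV and take precedence, producing identical downstream
statistics for identical partitions.  A network SNP is risk-flagged iff it
is itself a labelled risk SNP (GWAS p ≤ 5×10⁻⁸), shares a block with one,
or has r² strictly above 0.8 with one; the input genotype panel is the r²
reference.

All enrichment and regression tests use LD blocks as the unit.  A block's
community is the most frequent community among its SNPs (ties → lowest
index); the collapsing rule is ours — some rule is needed once per-SNP
quantities are pooled per block, and the dominant community is the natural
representative.

## Enrichment tests

Fisher tests are one-sided ("greater") — every question posed is about
excess.  P-values are exact (scipy's hypergeometric implementation,
cross-checked against a from-scratch fixed-margin enumeration for all
tables with total ≤ 40); reported odds ratios are sample ORs with a 0.5
Haldane–Anscombe correction only when a zero cell occurs, affecting display
and never the p-value.  Community risk enrichment uses the whole network's
blocks as background, runs once with all risk labels pooled and once per
trait, applies BH across communities within each analysis, and calls a
community enriched only when it holds ≥ 4 risk blocks — small significant
clusters are deliberately not called.  Whether the correction should span
communities, traits or both is genuinely open; per-analysis BH is the
default and the scope is configurable.  Gene-set overrepresentation is a
one-sided hypergeometric test against the network's gene background with BH
across sets (q < 0.05).  Promoters are strand-aware closed intervals
[TSS−750, TSS+250] in the transcription direction (missing strand → "+"
with a warning); the promoter test contrasts cancer-gene promoters against
an all-genes version of the same test.  The cis/trans contrast is a Fisher
test of (risk vs non-risk edge) × (trans vs cis) over significant edges.

## Risk statistics

**Degree-matched resampling.**  Cancer degree is a SNP's edge count into
the cancer-gene list.  The observed Mann–Whitney U compares risk and
non-risk units (LD blocks when available — member degrees summed — else
SNPs).  The null redraws pseudo-risk unit sets of the risk set's size from
within total-degree bins (decile edges by default, configurable), so the
null preserves the risk set's degree profile; bins whose pool holds no
non-risk unit merge upward with a warning.  The empirical p is
(1 + #{U_null ≥ U_obs}) / (n_resamples + 1): an add-one-corrected one-sided
p, our operationalization of comparing observed against resampled U values.
If every unit is risk-flagged the test is degenerate and returns p = 1.
Calibration is tested (p uniform under random labels, KS at the 1% level)
along with power under planted wiring.

**Core-score LRT.**  Per block and status (risk / non-GWAS; SNPs labelled
for non-cancer traits excluded), the median core score is regressed on
community indicators (n−1 of them) without and with a risk indicator.  The
statistic is N·log(RSS₀/RSS₁) — the Gaussian profile-likelihood LRT —
against χ²(1); an exact F(1, N−p) variant is available behind a flag since
the large-sample reference is a choice, not a given.  Rank-deficient
designs are handled by least-squares with a warning.  Type-I error is
verified to sit in [0.03, 0.07] at α = 0.05 over 500 null replicates, with
≥ 90% power at p < 10⁻³ under a strong planted shift (1.6 residual SDs).

## Synthetic data

The generator plants every structure the pipeline is supposed to find.

*Genotypes*: one LD block per synthetic chromosome (so cross-block pairs
are trans by construction and blocks are separated by more than the cis
window), each block sharing a MAF drawn uniform on [0.1, 0.5].  Haplotypes
copy a block anchor haplotype entrywise with probability √r², else redraw
at the block MAF — this sets the expected pairwise genotype r² to the
target directly (r² = 1 ⇒ identical SNPs; r² = 0 ⇒ independence), which a
thresholded-Gaussian construction only achieves after calibration.  A small
missing-call rate (1%) exercises pairwise deletion.

*Expression*: each gene takes one cis driver (mid-block SNP of a block in
its community; TSS placed within the cis window, alternating strands) plus
two trans drivers from other blocks of the same community, covariate
effects, and Gaussian noise.  Defaults — 300 samples, 40 blocks × 5 SNPs at
r² 0.9, 150 genes in 5 communities, cis β = 1.0, trans β = 0.6, noise SD 1
— give per-test power high enough that planted pairs dominate the edge set
while the q < 0.2 threshold still admits a realistic false-edge share
(~20% of edges), which is exactly the regime the network stage must
tolerate.  One weak bridge edge per community (ring layout) keeps the
network connected without blurring the partition.  Five filler genes with
near-zero counts exercise the expression filter.

*Risk planting*: 30% of blocks are risk-labelled, concentrated in the
first two communities; cancer genes (20% of genes) concentrate there too.
Each risk block's lead SNP gains 3 extra trans edges to same-community
genes chosen with 5-fold weight toward cancer genes — raising risk SNPs'
cancer degree and core scores.  Cancer genes on risk blocks get
promoter-proximal TSSs (promoter covers the cis driver), with one
promoter-proximal control gene per non-risk block, so cancer-gene promoters
concentrate risk blocks while all-gene promoters do not — the intended
contrast of the promoter analysis.  GWAS labels cover risk-block lead SNPs
(trait named after the community) plus a few non-cancer-trait labels to
exercise the other-trait filter.

*What the generator does not emulate*: realistic recombination maps and LD
decay (blocks are exchangeable within and independent between), population
stratification beyond a PC-style confounding knob, expression count
distributions (counts exist only to drive the filter), polygenic trans
architecture, or any real GWAS effect-size spectrum.  Passing tests
therefore demonstrate the statistical machinery — regression correctness,
FDR behaviour, modularity optimization, calibration of the resampling and
LRT nulls, block-level counting — not biological realism of any particular
dataset.

## Numerical and testing choices

Determinism is a contract: a single seeded generator drives each
stochastic component, node orders are sorted, ties have fixed rules, and
the CLI reproduces byte-identical TSVs for identical config + seed.  Test
problem sizes (e.g. 18–36 blocks and 45–90 genes for recovery benchmarks,
199 resamples × 200 replicates for calibration) were chosen so planted
effects are unambiguous at desk scale while the whole suite stays fast;
recovery benchmarks use communities large enough (≈ 18 blocks' worth of
nodes each) that ARI is insensitive to a handful of noise-driven node
assignments.  The brute-force community oracle used in tests enumerates
set partitions of one node side only, which is exact for this objective
(the other side decomposes per node) and keeps exhaustive search feasible.

Known limitations: the trans scan is a dense O(S×G) loop over SNPs (no
matrix-tiling optimizations), fine for ~10⁵ pairs per run; the community
optimizer's optimality guarantee is exhaustive only when one side is ≤ 7
nodes, heuristic-with-restarts above; Fisher ORs are sample ORs, not
conditional MLEs; and the LRT's χ² reference is asymptotic — use the F
variant for very few blocks.
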