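"""Synthetic genotype/expression data with planted eQTL-community structure.

The generator emulates the statistical features the downstream pipeline
relies on, with known ground truth at every level:

* biallelic SNPs in LD blocks (one block per synthetic chromosome, so any
  cross-block association is trans by construction).  Within a block every
  SNP's haplotype copies a shared anchor haplotype with probability
  sqrt(within_block_r2), else is drawn fresh at the block MAF — this makes
  the expected pairwise r² equal the target directly, reduces to identical
  SNPs at r²=1 and to independence at r²=0;
* expression driven additively by one cis driver plus ``n_trans_per_gene``
  trans drivers from the gene's planted community, with covariate effects
  and Gaussian noise; each gene's TSS is placed within the cis window of its
  driver block;
* a planted community structure over blocks and genes, with one weak
  "bridge" trans edge per community (ring layout) so the significant-eQTL
  network has a single giant connected component spanning all communities;
* risk blocks concentrated in the first ``n_risk_communities`` communities,
  wired to ``core_shift`` extra trans targets each, preferring cancer genes
  with weight ``risk_target_bias`` — raising both the cancer degree and the
  core score of risk SNPs;
* GWAS-catalog-like labels for risk-block lead SNPs (plus some
  non-cancer-trait labels to exercise the other-trait filter), a cancer-gene
  list, and GMT gene sets matching the planted communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, recompute_snp_stats, write_genotypes_tsv, write_matrix, write_gmt, write_annotation


@dataclass
class SimulationDesign:
    """Parameters of the planted-structure generator.

    Defaults describe a desk-scale study: 300 samples, 40 LD blocks of 5
    SNPs (r² target 0.9), 150 genes in 5 communities, standardized cis and
    trans effects of 1.0 and 0.6 against unit noise, a quarter of the blocks
    risk-labelled inside 2 risk communities, cancer genes concentrated
    there, 5-fold risk->cancer-gene targeting bias and 3 extra trans edges
    per risk block.
    """

    n_samples: int = 300
    n_blocks: int = 40
    snps_per_block: int = 5
    within_block_r2: float = 0.9
    n_genes: int = 150
    n_communities: int = 5
    n_trans_per_gene: int = 2
    cis_effect_size: float = 1.0
    trans_effect_size: float = 0.6
    noise_sd: float = 1.0
    frac_risk_blocks: float = 0.3
    frac_cancer_genes: float = 0.2
    risk_target_bias: float = 5.0
    core_shift: int = 3
    n_risk_communities: int = 2
    n_low_genes: int = 5
    missing_rate: float = 0.01
    maf_low: float = 0.1
    maf_high: float = 0.5
    covariate_confounding: float = 0.0
    bridge_edges: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_blocks", "snps_per_block", "n_genes", "n_communities"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("within_block_r2", "frac_risk_blocks", "frac_cancer_genes", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_communities > self.n_blocks:
            raise ValueError("need at least one block per community")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")

    # planted layout helpers ------------------------------------------------

    def block_ids(self) -> list[str]:
        return [f"T{b + 1}" for b in range(self.n_blocks)]

    def block_community(self, b: int) -> int:
        return b % self.n_communities + 1

    def gene_community(self, g: int) -> int:
        return g % self.n_communities + 1

    def snp_id(self, b: int, s: int) -> str:
        return f"snp_b{b + 1}_{s + 1}"

    def block_chrom(self, b: int) -> str:
        return f"chr{b + 1}"

    def snp_pos(self, s: int) -> int:
        return 1_000_000 + s * 2_000


@dataclass
class GroundTruth:
    """Planted structure: true eQTL pairs, communities, blocks and labels."""

    true_pairs: pd.DataFrame            # snp_id, gene_id, beta, cis_flag
    snp_community: pd.Series            # snp_id -> planted community
    gene_community: pd.Series           # gene_id -> planted community (NaN for filler genes)
    blocks: pd.Series                   # snp_id -> planted block id
    risk_blocks: list[str]
    cancer_genes: list[str]
    risk_communities: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(design: SimulationDesign, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Correlated biallelic genotype blocks on separate synthetic chromosomes."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.n_samples
    copy_prob = np.sqrt(design.within_block_r2)
    cols, ids, chroms, poss = [], [], [], []
    for b in range(design.n_blocks):
        p = rng.uniform(design.maf_low, design.maf_high)
        anchors = rng.random((2, n)) < p  # two anchor haplotypes per sample
        for s in range(design.snps_per_block):
            if s == 0:
                haps = anchors
            else:
                keep = rng.random((2, n)) < copy_prob
                fresh = rng.random((2, n)) < p
                haps = np.where(keep, anchors, fresh)
            cols.append(haps.sum(axis=0).astype(float))
            ids.append(design.snp_id(b, s))
            chroms.append(design.block_chrom(b))
            poss.append(design.snp_pos(s))
    X = np.column_stack(cols)
    if design.missing_rate > 0:
        X[rng.random(X.shape) < design.missing_rate] = np.nan
    samples = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample")
    dosages = pd.DataFrame(X, index=samples, columns=pd.Index(ids, name="snp_id"))
    snps = pd.DataFrame({"chrom": chroms, "pos": poss}, index=dosages.columns)
    g = GenotypeMatrix(dosages, snps)
    recompute_snp_stats(g)
    return g


# ---------------------------------------------------------------------------
# expression + labels
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix, design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Expression, raw counts, covariates and annotation with planted effects.

    Returns ``(expression, counts, covariates, annotation, truth)``.
    Missing dosages are mean-imputed only for generating expression; the
    written genotypes keep their missing entries.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    n = design.n_samples
    samples = genotypes.samples

    # covariates
    age = rng.normal(50, 10, n)
    sex = rng.choice(["F", "M"], n)
    eth = rng.choice(["grpA", "grpB", "grpC"], n)
    pcs = rng.normal(0, 1, (n, 3))
    dose = genotypes.dosages.to_numpy(float)
    col_mean = np.nanmean(dose, axis=0)
    dose_imp = np.where(np.isnan(dose), col_mean, dose)
    if design.covariate_confounding > 0:
        burden = (dose_imp - col_mean).mean(axis=1)
        sd = burden.std()
        if sd > 0:
            pcs[:, 0] += design.covariate_confounding * burden / sd
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "ethnic_background": eth,
         "PC1_genet": pcs[:, 0], "PC2_genet": pcs[:, 1], "PC3_genet": pcs[:, 2]},
        index=samples,
    )
    cov_effect = (
        0.01 * age
        + 0.3 * (sex == "M")
        + np.select([eth == "grpB", eth == "grpC"], [0.2, -0.2], 0.0)
        + 0.2 * pcs.sum(axis=1)
    )

    snp_col = {s: i for i, s in enumerate(genotypes.snp_ids)}
    comm_blocks: dict[int, list[int]] = {c: [] for c in range(1, design.n_communities + 1)}
    for b in range(design.n_blocks):
        comm_blocks[design.block_community(b)].append(b)

    # risk blocks: spread evenly over the first n_risk_communities communities
    n_risk = int(round(design.frac_risk_blocks * design.n_blocks))
    risk_comms = list(range(1, min(design.n_risk_communities, design.n_communities) + 1))
    risk_block_idx: list[int] = []
    ptr = {c: 0 for c in risk_comms}
    while len(risk_block_idx) < n_risk:
        progressed = False
        for c in risk_comms:
            if len(risk_block_idx) >= n_risk:
                break
            if ptr[c] < len(comm_blocks[c]):
                risk_block_idx.append(comm_blocks[c][ptr[c]])
                ptr[c] += 1
                progressed = True
        if not progressed:
            break

    # cancer genes: preferentially from the risk communities
    n_cancer = int(round(design.frac_cancer_genes * design.n_genes))
    genes_by_pref = sorted(
        range(design.n_genes),
        key=lambda g: (design.gene_community(g) not in risk_comms, g),
    )
    cancer_gene_idx = set(genes_by_pref[:n_cancer])

    gene_ids, tss_list, chrom_list, strand_list = [], [], [], []
    pair_rows = []  # (snp_id, gene_id, beta, cis_flag)
    Y = np.zeros((n, design.n_genes + design.n_low_genes))
    gene_comm_records = {}
    comm_cycle = {c: 0 for c in comm_blocks}
    risk_set = set(risk_block_idx)
    nonrisk_with_promoter: set[int] = set()
    gene_cis_block: dict[str, int] = {}
    for g in range(design.n_genes):
        gid = f"gene_{g + 1}"
        c = design.gene_community(g)
        blocks_c = comm_blocks[c]
        cis_b = blocks_c[comm_cycle[c] % len(blocks_c)]
        comm_cycle[c] += 1
        cis_snp = design.snp_id(cis_b, design.snps_per_block // 2)
        y = design.cis_effect_size * dose_imp[:, snp_col[cis_snp]]
        pair_rows.append((cis_snp, gid, design.cis_effect_size, True))
        # promoter layout: cancer genes on risk blocks sit with their TSS just
        # downstream of the cis driver (promoter covers it); each non-risk
        # block gets one promoter-proximal non-cancer gene as a control, so
        # risk blocks stand out in cancer-gene promoters but not in all-gene
        # promoters
        if g in cancer_gene_idx and cis_b in risk_set:
            tss_offset = 200
        elif g not in cancer_gene_idx and cis_b not in risk_set and cis_b not in nonrisk_with_promoter:
            tss_offset = 200
            nonrisk_with_promoter.add(cis_b)
        else:
            tss_offset = 500_000
        other = [b for b in blocks_c if b != cis_b]
        n_trans = min(design.n_trans_per_gene, len(other))
        if n_trans:
            chosen = rng.choice(len(other), size=n_trans, replace=False)
            for idx in sorted(chosen):
                tsnp = design.snp_id(other[idx], 0)
                y = y + design.trans_effect_size * dose_imp[:, snp_col[tsnp]]
                pair_rows.append((tsnp, gid, design.trans_effect_size, False))
        gene_cis_block[gid] = cis_b
        Y[:, g] = y
        gene_ids.append(gid)
        gene_comm_records[gid] = c
        tss_list.append(design.snp_pos(design.snps_per_block // 2) + tss_offset)
        chrom_list.append(design.block_chrom(cis_b))
        strand_list.append("+" if g % 2 == 0 else "-")

    # extra trans wiring from risk blocks, biased toward cancer genes
    gene_targets: dict[str, set[str]] = {}
    for s, gid, *_ in pair_rows:
        gene_targets.setdefault(s, set()).add(gid)
    for b in risk_block_idx:
        lead = design.snp_id(b, 0)
        c = design.block_community(b)
        candidates = [g for g in range(design.n_genes)
                      if design.gene_community(g) == c
                      and gene_cis_block[f"gene_{g + 1}"] != b  # keep the pair trans
                      and f"gene_{g + 1}" not in gene_targets.get(lead, set())]
        if not candidates:
            continue
        w = np.array([design.risk_target_bias if g in cancer_gene_idx else 1.0 for g in candidates])
        k = min(design.core_shift, len(candidates))
        chosen = rng.choice(len(candidates), size=k, replace=False, p=w / w.sum())
        for idx in sorted(chosen):
            g = candidates[idx]
            gid = f"gene_{g + 1}"
            Y[:, g] += design.trans_effect_size * dose_imp[:, snp_col[lead]]
            pair_rows.append((lead, gid, design.trans_effect_size, False))
            gene_targets.setdefault(lead, set()).add(gid)

    # one weak bridge edge per community so the network is connected
    if design.bridge_edges and design.n_communities > 1:
        for c in range(1, design.n_communities + 1):
            src_b = comm_blocks[c][-1]
            lead = design.snp_id(src_b, 0)
            target_c = c % design.n_communities + 1
            g = target_c - 1  # first gene of the target community
            gid = f"gene_{g + 1}"
            Y[:, g] += design.trans_effect_size * dose_imp[:, snp_col[lead]]
            pair_rows.append((lead, gid, design.trans_effect_size, False))

    Y[:, : design.n_genes] += cov_effect[:, None]
    if design.noise_sd > 0:
        Y += design.noise_sd * rng.normal(0, 1, Y.shape)

    # filler low-expression genes: pure noise, filtered out by the count rule
    for j in range(design.n_low_genes):
        gid = f"lowgene_{j + 1}"
        gene_ids.append(gid)
        gene_comm_records[gid] = np.nan
        tss_list.append(10_000_000 + j * 10_000)
        chrom_list.append(design.block_chrom(0))
        strand_list.append("+")

    expression = pd.DataFrame(Y, index=samples, columns=pd.Index(gene_ids, name="gene_id"))
    counts = pd.DataFrame(
        np.column_stack([
            rng.poisson(60, (n, design.n_genes)),
            rng.poisson(1, (n, design.n_low_genes)),
        ]),
        index=samples,
        columns=expression.columns,
    )
    annotation = pd.DataFrame(
        {"chrom": chrom_list, "tss": tss_list, "strand": strand_list},
        index=expression.columns,
    )

    blocks = pd.Series(
        {design.snp_id(b, s): f"T{b + 1}"
         for b in range(design.n_blocks) for s in range(design.snps_per_block)},
        name="block_id",
    ).rename_axis("snp_id")
    snp_comm = pd.Series(
        {design.snp_id(b, s): design.block_community(b)
         for b in range(design.n_blocks) for s in range(design.snps_per_block)},
        name="community",
    ).rename_axis("snp_id")
    truth = GroundTruth(
        true_pairs=pd.DataFrame(pair_rows, columns=["snp_id", "gene_id", "beta", "cis_flag"]),
        snp_community=snp_comm,
        gene_community=pd.Series(gene_comm_records, name="community").rename_axis("gene_id"),
        blocks=blocks,
        risk_blocks=[f"T{b + 1}" for b in sorted(risk_block_idx)],
        cancer_genes=[f"gene_{g + 1}" for g in sorted(cancer_gene_idx)],
        risk_communities=risk_comms,
    )
    return expression, counts, covariates, annotation, truth


def gwas_label_table(design: SimulationDesign, truth: GroundTruth) -> pd.DataFrame:
    """GWAS-catalog-like labels: risk-block lead SNPs tagged with a cancer
    trait named after their community, plus a few non-cancer-trait labels."""
    rows = []
    risk_set = set(truth.risk_blocks)
    for b in range(design.n_blocks):
        blk = f"T{b + 1}"
        lead = design.snp_id(b, 0)
        if blk in risk_set:
            rows.append((lead, f"cancer_type_{design.block_community(b)}", 1e-12))
    non_risk = [b for b in range(design.n_blocks) if f"T{b + 1}" not in risk_set]
    for b in non_risk[:3]:
        rows.append((design.snp_id(b, 0), "standing_height", 1e-10))
    return pd.DataFrame(rows, columns=["snp_id", "trait", "p_value"])


def community_gene_sets(design: SimulationDesign, truth: GroundTruth,
                        rng: np.random.Generator | None = None) -> dict[str, set[str]]:
    """GMT-style sets: one per planted community plus random decoy sets."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    sets: dict[str, set[str]] = {}
    gc = truth.gene_community.dropna()
    for c in sorted(gc.unique()):
        sets[f"community_{int(c)}_process"] = set(gc.index[gc == c])
    all_genes = list(gc.index)
    for j in range(3):
        k = min(15, len(all_genes))
        sets[f"decoy_set_{j + 1}"] = set(rng.choice(all_genes, size=k, replace=False))
    return sets


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------

def simulate_dataset(design: SimulationDesign):
    """Generate every table in memory from a single seeded stream."""
    rng = np.random.default_rng(design.seed)
    genotypes = simulate_genotypes(design, rng)
    expression, counts, covariates, annotation, truth = simulate_expression(genotypes, design, rng)
    labels = gwas_label_table(design, truth)
    gene_sets = community_gene_sets(design, truth, rng)
    return genotypes, expression, counts, covariates, annotation, labels, gene_sets, truth


def write_dataset(design: SimulationDesign, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated study to ``outdir`` in the pipeline's input formats,
    plus ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes, expression, counts, covariates, annotation, labels, gene_sets, truth = simulate_dataset(design)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "expression": outdir / "expression.tsv",
        "counts": outdir / "counts.tsv",
        "covariates": outdir / "covariates.tsv",
        "annotation": outdir / "annotation.tsv",
        "gwas_labels": outdir / "gwas_labels.tsv",
        "cancer_genes": outdir / "cancer_genes.txt",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth_pairs": outdir / "ground_truth_pairs.tsv",
        "truth_communities": outdir / "ground_truth_communities.tsv",
        "truth_blocks": outdir / "ground_truth_blocks.tsv",
    }
    write_genotypes_tsv(genotypes, paths["genotypes"])
    write_matrix(expression, paths["expression"])
    write_matrix(counts, paths["counts"])
    covariates.to_csv(paths["covariates"], sep="\t", float_format="%.10g")
    write_annotation(annotation, paths["annotation"])
    labels.to_csv(paths["gwas_labels"], sep="\t", index=False, float_format="%.6g")
    paths["cancer_genes"].write_text("\n".join(truth.cancer_genes) + "\n")
    write_gmt(gene_sets, paths["gene_sets"])
    truth.true_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False, float_format="%.10g")
    comm = pd.concat([
        truth.snp_community.rename("community").rename_axis("node_id").reset_index().assign(node_type="snp"),
        truth.gene_community.rename("community").rename_axis("node_id").reset_index().assign(node_type="gene"),
    ])
    comm = comm[["node_id", "node_type", "community"]]
    comm.insert(3, "risk_unit", False)
    comm.loc[(comm["node_type"] == "snp")
             & comm["node_id"].isin(truth.blocks.index[truth.blocks.isin(truth.risk_blocks)]),
             "risk_unit"] = True
    comm.loc[(comm["node_type"] == "gene") & comm["node_id"].isin(truth.cancer_genes), "risk_unit"] = True
    comm.to_csv(paths["truth_communities"], sep="\t", index=False, float_format="%.10g")
    blocks_df = truth.blocks.reset_index()
    blocks_df["risk_block"] = blocks_df["block_id"].isin(truth.risk_blocks)
    blocks_df.to_csv(paths["truth_blocks"], sep="\t", index=False)
    return paths
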