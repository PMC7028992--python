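"""Stage orchestration: each stage reads the previous stage's TSV outputs,
so stages are independently runnable and testable.  The CLI in
:mod:`eqtlnet.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import communities as comm_mod
from . import enrichment as enr
from . import eqtl as eqtl_mod
from . import ld as ld_mod
from . import network as net_mod
from . import riskstats as rs
from .config import PipelineConfig
from .io import (
    GenotypeMatrix,
    align_samples,
    read_annotation,
    read_covariates,
    read_expression,
    read_gene_list,
    read_genotypes,
    read_gmt,
    read_gwas_labels,
    read_ld_blocks,
    write_ld_blocks,
)
from .simulate import SimulationDesign, write_dataset

logger = logging.getLogger(__name__)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name} (looked in {path.parent}); "
            "run the upstream stage first"
        )
    return path


def _log_config(stage: str, config: PipelineConfig) -> None:
    logger.info("stage %s config: %s", stage, config.as_dict())


# ---------------------------------------------------------------------------


def stage_simulate(design: SimulationDesign, outdir: str | Path) -> dict[str, Path]:
    logger.info("stage simulate design: %s", design)
    return write_dataset(design, outdir)


def stage_eqtl(datadir: str | Path, outdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Filter SNPs/genes, align samples, run the full cis+trans scan; writes
    edges.tsv (all tested pairs with q-values)."""
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log_config("eqtl", config)
    genotypes = read_genotypes(_require(datadir / "genotypes.tsv", "eqtl"), format="tsv")
    expression = read_expression(_require(datadir / "expression.tsv", "eqtl"))
    covariates = read_covariates(_require(datadir / "covariates.tsv", "eqtl"))
    annotation = read_annotation(_require(datadir / "annotation.tsv", "eqtl"))
    counts_path = datadir / "counts.tsv"
    genotypes, expression, covariates = align_samples(genotypes, expression, covariates)
    genotypes = eqtl_mod.filter_snps(genotypes, config)
    if counts_path.exists():
        counts = read_expression(counts_path)
        kept = eqtl_mod.filter_genes(counts.loc[expression.index], config)
        expression = expression[[g for g in expression.columns if g in set(kept)]]
    else:
        logger.warning("stage eqtl: no counts.tsv, expression filter skipped")
    table = eqtl_mod.run_eqtl_scan(genotypes, expression, covariates, config, gene_ann=annotation)
    table.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.10g")
    return table


def stage_network(outdir: str | Path, config: PipelineConfig) -> net_mod.BipartiteNetwork:
    """Build the significant-edge bipartite network and keep its giant
    component; writes network.tsv and components.log."""
    outdir = Path(outdir)
    _log_config("network", config)
    table = pd.read_csv(_require(outdir / "edges.tsv", "network"), sep="\t")
    full = net_mod.build_network(table, config.fdr_threshold)
    comps = net_mod.connected_components(full)
    gcc = net_mod.giant_component(full)
    with open(outdir / "components.log", "w") as fh:
        for c in sorted(comps, key=lambda c: (-len(c), min(c))):
            kept = "kept" if set(c) <= set(gcc.snp_nodes) | set(gcc.gene_nodes) else "dropped"
            fh.write(f"{kept}\t{len(c)}\n")
    net_mod.write_edge_list(gcc, outdir / "network.tsv")
    return gcc


def load_network(outdir: str | Path, stage: str = "communities") -> net_mod.BipartiteNetwork:
    table = pd.read_csv(_require(Path(outdir) / "network.tsv", stage), sep="\t")
    return net_mod.BipartiteNetwork(
        snp_nodes=table["snp_id"].unique().tolist(),
        gene_nodes=table["gene_id"].unique().tolist(),
        edges=list(zip(table["snp_id"], table["gene_id"])),
        edge_info=table,
    )


def stage_communities(outdir: str | Path, config: PipelineConfig,
                      max_iter: int = 100, tol: float = 1e-10):
    """Detect modularity-maximizing communities and compute SNP core scores;
    writes communities.tsv and core_scores.tsv."""
    outdir = Path(outdir)
    _log_config("communities", config)
    network = load_network(outdir)
    assignment = comm_mod.detect_communities(network, seed=config.rng_seed,
                                             max_iter=max_iter, tol=tol)
    frame = assignment.to_frame()
    frame.to_csv(outdir / "communities.tsv", sep="\t", index=False)
    scores = comm_mod.core_scores(network, assignment)
    scores.reset_index().to_csv(outdir / "core_scores.tsv", sep="\t",
                                index=False, float_format="%.12g")
    with open(outdir / "modularity.txt", "w") as fh:
        fh.write(f"Q\t{assignment.modularity:.12g}\n")
        fh.write(f"n_communities\t{assignment.n_communities}\n")
    return network, assignment, scores


def _network_blocks(datadir: Path, outdir: Path, network, config: PipelineConfig,
                    blocks_file: str | None, stage: str) -> tuple[pd.Series, GenotypeMatrix]:
    genotypes = read_genotypes(_require(datadir / "genotypes.tsv", stage), format="tsv")
    if blocks_file:
        blocks = read_ld_blocks(blocks_file)
    else:
        blocks = ld_mod.build_blocks_greedy(genotypes, r2_min=config.ld_r2_threshold)
        write_ld_blocks(blocks, outdir / "ld_blocks.tsv")
    ld_mod.validate_partition(blocks, genotypes.snp_ids.intersection(blocks.index))
    return blocks, genotypes


def stage_enrich(datadir: str | Path, outdir: str | Path, config: PipelineConfig,
                 blocks_file: str | None = None) -> pd.DataFrame:
    """Community risk-block enrichment (pooled + per trait), gene-set
    enrichment for risk-enriched communities, promoter enrichment and the
    cis/trans contrast; writes enrichment.tsv."""
    datadir, outdir = Path(datadir), Path(outdir)
    _log_config("enrich", config)
    comm_frame = pd.read_csv(_require(outdir / "communities.tsv", "enrich"), sep="\t")
    network = load_network(outdir, "enrich")
    snp_comm = dict(comm_frame[comm_frame["node_type"] == "snp"][["node_id", "community"]].values)
    blocks, genotypes = _network_blocks(datadir, outdir, network, config, blocks_file, "enrich")

    labels = read_gwas_labels(_require(datadir / "gwas_labels.tsv", "enrich"))
    status = rs.snp_status(labels, p_threshold=config.gwas_p_threshold)
    risk_ids = status.index[status == "risk"]
    snp_risk = ld_mod.map_risk_snps(risk_ids, network.snp_nodes, blocks,
                                    genotypes, config.ld_r2_threshold)

    block_comm = enr.dominant_community(blocks, snp_comm)
    block_risk = ld_mod.block_risk_flags(blocks.loc[blocks.index.isin(snp_risk.index)], snp_risk)

    results = []
    pooled = enr.community_risk_enrichment(block_comm, block_risk, config.min_risk_blocks)
    pooled.insert(0, "analysis", "community_risk_pooled")
    pooled.insert(1, "trait", "all_cancers")
    results.append(pooled)

    # per-trait analysis
    sig = labels[labels["p_value"] <= config.gwas_p_threshold]
    cancer_traits = sorted(set(sig["trait"]) & set(
        sig.loc[sig["snp_id"].isin(status.index[status == "risk"]), "trait"]))
    trait_cols = {}
    for trait in cancer_traits:
        t_ids = sig.loc[sig["trait"] == trait, "snp_id"]
        t_risk = ld_mod.map_risk_snps(t_ids, network.snp_nodes, blocks,
                                      genotypes, config.ld_r2_threshold)
        trait_cols[trait] = ld_mod.block_risk_flags(
            blocks.loc[blocks.index.isin(t_risk.index)], t_risk
        ).reindex(block_comm.index).fillna(False)
    if trait_cols:
        per_trait = enr.community_risk_enrichment_by_trait(
            block_comm, pd.DataFrame(trait_cols), config.min_risk_blocks)
        per_trait.insert(0, "analysis", "community_risk_by_trait")
        results.append(per_trait)

    # gene-set enrichment within risk-enriched communities
    gmt_path = datadir / "gene_sets.gmt"
    if gmt_path.exists():
        gene_sets = read_gmt(gmt_path)
        gene_comm = dict(comm_frame[comm_frame["node_type"] == "gene"][["node_id", "community"]].values)
        background = list(gene_comm)
        for comm in pooled.loc[pooled["enriched"], "unit_id"]:
            genes_c = [g for g, c in gene_comm.items() if c == comm]
            gse = enr.gene_set_enrichment(genes_c, gene_sets, background)
            gse.insert(0, "analysis", f"gene_sets_community_{comm}")
            gse.insert(1, "trait", "all_cancers")
            results.append(gse)

    # promoter + cis/trans contrasts
    annotation = read_annotation(_require(datadir / "annotation.tsv", "enrich"))
    cancer_genes = read_gene_list(_require(datadir / "cancer_genes.txt", "enrich"))
    snp_meta = genotypes.snps.loc[genotypes.snp_ids.intersection(blocks.index)]
    all_snp_risk = ld_mod.map_risk_snps(risk_ids, snp_meta.index, blocks, None,
                                        config.ld_r2_threshold)
    prom = enr.promoter_enrichment(snp_meta, annotation, cancer_genes, blocks, all_snp_risk,
                                   config.promoter_upstream_bp, config.promoter_downstream_bp)
    prom.insert(0, "analysis", "promoter")
    prom.insert(1, "trait", "all_cancers")
    results.append(prom)

    edge_info = network.edge_table()
    ct = enr.risk_cis_trans_enrichment(edge_info, snp_risk)
    ct.insert(0, "analysis", "risk_cis_trans")
    ct.insert(1, "trait", "all_cancers")
    results.append(ct)

    out = pd.concat(results, ignore_index=True)
    out.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    snp_risk.rename("risk").rename_axis("snp_id").reset_index().to_csv(
        outdir / "risk_flags.tsv", sep="\t", index=False)
    return out


def stage_risk_tests(datadir: str | Path, outdir: str | Path, config: PipelineConfig,
                     blocks_file: str | None = None, n_degree_bins: int = 10) -> pd.DataFrame:
    """Degree-matched cancer-degree resampling test and core-score LRT;
    writes risk_tests.tsv plus the two cancer-degree distributions."""
    datadir, outdir = Path(datadir), Path(outdir)
    _log_config("risk-tests", config)
    network = load_network(outdir, "risk-tests")
    scores = pd.read_csv(_require(outdir / "core_scores.tsv", "risk-tests"),
                         sep="\t").set_index("snp_id")
    blocks, genotypes = _network_blocks(datadir, outdir, network, config, blocks_file, "risk-tests")
    labels = read_gwas_labels(_require(datadir / "gwas_labels.tsv", "risk-tests"))
    cancer_genes = read_gene_list(_require(datadir / "cancer_genes.txt", "risk-tests"))

    status = rs.snp_status(labels, p_threshold=config.gwas_p_threshold)
    risk_ids = status.index[status == "risk"]
    snp_risk = ld_mod.map_risk_snps(risk_ids, network.snp_nodes, blocks,
                                    genotypes, config.ld_r2_threshold)

    deg_res = rs.degree_matched_resampling_test(
        network, snp_risk, cancer_genes,
        n_resamples=config.n_resamples, seed=config.rng_seed,
        blocks=blocks, n_degree_bins=n_degree_bins,
    )

    # propagate block risk to SNP status for the LRT (block-mates of risk SNPs
    # count as risk; labelled other-trait SNPs stay excluded)
    full_status = pd.Series("non_gwas", index=pd.Index(network.snp_nodes, name="snp_id"))
    full_status[snp_risk.reindex(full_status.index).fillna(False).astype(bool)] = "risk"
    other = status.index[status == "other_trait"]
    other_blocks = set(blocks.reindex(other).dropna())
    in_other = blocks.reindex(full_status.index).isin(other_blocks) & (full_status != "risk")
    full_status[in_other.fillna(False)] = "other_trait"

    collapsed = rs.collapse_by_block(scores, full_status, blocks)
    lrt = rs.core_score_lrt(collapsed)
    collapsed.to_csv(outdir / "core_scores_by_block.tsv", sep="\t", index=False,
                     float_format="%.12g")

    cdeg = rs.cancer_degree(network, cancer_genes)
    pd.DataFrame({
        "snp_id": cdeg.index,
        "cancer_degree": cdeg.values,
        "risk": snp_risk.reindex(cdeg.index).fillna(False).astype(bool).values,
    }).to_csv(outdir / "cancer_degree.tsv", sep="\t", index=False)

    out = pd.DataFrame(
        [
            ("degree_matched_resampling", deg_res.u_observed, deg_res.p_value,
             deg_res.n_resamples, config.rng_seed),
            ("core_score_lrt", lrt.statistic, lrt.p_value, np.nan, config.rng_seed),
        ],
        columns=["test", "statistic", "p_value", "n_resamples", "seed"],
    )
    out.to_csv(outdir / "risk_tests.tsv", sep="\t", index=False, float_format="%.6g")
    return out


def run_all(datadir: str | Path, outdir: str | Path, config: PipelineConfig,
            design: SimulationDesign | None = None, blocks_file: str | None = None) -> dict:
    """Run every stage in order.  When ``design`` is given, the dataset is
    simulated into ``datadir`` first."""
    if design is not None:
        stage_simulate(design, datadir)
    table = stage_eqtl(datadir, outdir, config)
    gcc = stage_network(outdir, config)
    network, assignment, scores = stage_communities(outdir, config)
    enrich = stage_enrich(datadir, outdir, config, blocks_file)
    tests = stage_risk_tests(datadir, outdir, config, blocks_file)
    return {
        "eqtl_table": table,
        "network": network,
        "assignment": assignment,
        "core_scores": scores,
        "enrichment": enrich,
        "risk_tests": tests,
    }
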