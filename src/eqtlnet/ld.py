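"""Linkage-disequilibrium utilities.

r² is the squared Pearson correlation of additive genotype codes on
pairwise-complete samples (composite LD; phase-free).  Blocks are built with
a simple left-to-right greedy rule suited to synthetic data — precomputed
block files (e.g. from plink) can be supplied instead and take precedence.
LD blocks, not individual SNPs, are the statistical unit of all enrichment
and likelihood-ratio tests downstream, which avoids counting correlated
SNPs as independent evidence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)


def ld_r2(genotype_i: np.ndarray, genotype_j: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete samples.

    Returns NaN when either vector is constant after removing missing pairs
    or fewer than 3 complete pairs remain.  Symmetric and invariant to the
    allele-coding flip x -> 2 - x.
    """
    x = np.asarray(genotype_i, float)
    y = np.asarray(genotype_j, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def build_blocks_greedy(
    genotypes: GenotypeMatrix, r2_min: float = 0.8, max_span_bp: int = 5_000_000
) -> pd.Series:
    """Greedy LD blocks: SNPs sorted by (chrom, pos); the current block is
    extended while the candidate has r² >= r2_min with the block's first SNP
    and the block span stays <= max_span_bp.

    Returns a Series snp_id -> block_id (``B1``, ``B2``, ... in scan order).
    """
    meta = genotypes.snps.sort_values(["chrom", "pos"], kind="mergesort")
    X = genotypes.dosages
    block_of: dict[str, str] = {}
    block_idx = 0
    anchor = None  # (snp_id, chrom, start_pos)
    for snp_id, row in meta.iterrows():
        chrom, pos = row["chrom"], row["pos"]
        extend = False
        if anchor is not None and chrom == anchor[1] and pos - anchor[2] <= max_span_bp:
            r2 = ld_r2(X[anchor[0]].to_numpy(), X[snp_id].to_numpy())
            extend = bool(r2 >= r2_min) if not np.isnan(r2) else False
        if not extend:
            block_idx += 1
            anchor = (snp_id, chrom, pos)
        block_of[snp_id] = f"B{block_idx}"
    out = pd.Series(block_of, name="block_id")
    out.index.name = "snp_id"
    logger.info("build_blocks_greedy: %d SNPs -> %d blocks", len(out), block_idx)
    return out.loc[genotypes.snp_ids]


def validate_partition(blocks: pd.Series, snp_ids) -> None:
    """Blocks must cover every SNP exactly once."""
    missing = pd.Index(snp_ids).difference(blocks.index)
    if len(missing):
        raise ValueError(f"LD blocks missing {len(missing)} SNPs, e.g. {list(missing[:3])}")
    if blocks.index.duplicated().any():
        raise ValueError("a SNP appears in more than one LD block")


def map_risk_snps(
    risk_ids,
    network_snps,
    blocks: pd.Series,
    genotypes: GenotypeMatrix | None = None,
    r2_threshold: float = 0.8,
) -> pd.Series:
    """Risk flag per network SNP.

    A network SNP is risk-flagged iff it is itself a labelled risk SNP, or
    shares an LD block with one, or (when genotypes are supplied) has
    r² strictly greater than ``r2_threshold`` with one.  Labelled risk SNPs
    absent from the genotype panel are logged and skipped for the r² route.
    """
    network_snps = list(network_snps)
    risk_ids = set(risk_ids)
    flags = pd.Series(False, index=pd.Index(network_snps, name="snp_id"), name="risk")
    flags[flags.index.isin(risk_ids)] = True

    risk_blocks = set(blocks.reindex(list(risk_ids)).dropna())
    in_risk_block = blocks.reindex(network_snps).isin(risk_blocks).fillna(False).to_numpy(bool)
    flags |= in_risk_block

    if genotypes is not None:
        panel_risk = [r for r in risk_ids if r in genotypes.snp_ids]
        absent = risk_ids - set(panel_risk)
        if absent:
            logger.info("map_risk_snps: %d risk SNPs absent from genotype panel, skipped", len(absent))
        if panel_risk:
            R = genotypes.dosages[panel_risk].to_numpy(float)
            for snp in flags.index[~flags]:
                if snp not in genotypes.snp_ids:
                    continue
                x = genotypes.dosages[snp].to_numpy(float)
                for jcol in range(R.shape[1]):
                    r2 = ld_r2(x, R[:, jcol])
                    if not np.isnan(r2) and r2 > r2_threshold:
                        flags[snp] = True
                        break
    return flags


def block_risk_flags(blocks: pd.Series, snp_risk: pd.Series) -> pd.Series:
    """Block-level risk flag: a block is risk iff any member SNP is flagged."""
    df = pd.DataFrame({"block": blocks.reindex(snp_risk.index), "risk": snp_risk})
    return df.groupby("block")["risk"].any()
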