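"""Enrichment tests: community risk-block Fisher tests, gene-set
overrepresentation, promoter enrichment and the cis/trans contrast.

All risk-related contingency tables are counted in LD-block units, so a
cluster of correlated SNPs contributes a single observation.  Fisher tests
are one-sided ("greater") since every question here is about excess.  Odds
ratios are the sample OR a*d / (b*c) with a 0.5 Haldane-Anscombe correction
applied only when a zero cell would make the ratio degenerate; p-values are
always the exact ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_adjust

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["unit_id", "a", "b", "c", "d", "odds_ratio", "p_value", "q_value", "enriched"]


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float


def fisher_test(a: int, b: int, c: int, d: int, alternative: str = "greater") -> FisherResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Exact hypergeometric p-value; the reported odds ratio is the sample OR
    (a*d)/(b*c), with 0.5 added to every cell only when a zero cell occurs.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"cell counts must be non-negative integers: {counts}")
    a, b, c, d = (int(x) for x in counts)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    return FisherResult(odds_ratio=float(orat), p_value=float(p))


# ---------------------------------------------------------------------------
# community risk-block enrichment
# ---------------------------------------------------------------------------

def dominant_community(blocks: pd.Series, snp_community: dict[str, int]) -> pd.Series:
    """Block -> most frequent community among its SNPs (ties -> lowest index).

    Only SNPs present in ``snp_community`` (i.e. in the network) count.
    """
    rows = [(blk, snp_community[s]) for s, blk in blocks.items() if s in snp_community]
    df = pd.DataFrame(rows, columns=["block", "community"])
    if df.empty:
        return pd.Series(dtype=int)

    def pick(s: pd.Series) -> int:
        counts = s.value_counts()
        top = counts[counts == counts.max()].index
        return int(min(top))

    return df.groupby("block")["community"].agg(pick)


def community_risk_enrichment(
    block_community: pd.Series,
    block_risk: pd.Series,
    min_risk_blocks: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-community Fisher enrichment of risk LD blocks, whole network as
    background.

    ``block_community`` maps each network block to its (dominant) community;
    ``block_risk`` flags risk blocks.  For community h the table is
    (risk, in h) / (non-risk, in h) / (risk, out) / (non-risk, out).
    A community is called enriched only when its risk-block count is at
    least ``min_risk_blocks`` AND its BH q-value (across communities) is
    below ``alpha``.
    """
    blocks = block_community.index
    risk = block_risk.reindex(blocks).fillna(False).astype(bool)
    n_risk = int(risk.sum())
    n_tot = len(blocks)
    rows = []
    for comm in sorted(block_community.unique()):
        in_c = block_community == comm
        a = int((in_c & risk).sum())
        b = int((in_c & ~risk).sum())
        c = n_risk - a
        d = (n_tot - n_risk) - b
        res = fisher_test(a, b, c, d, alternative="greater")
        rows.append((comm, a, b, c, d, res.odds_ratio, res.p_value))
    out = pd.DataFrame(rows, columns=["unit_id", "a", "b", "c", "d", "odds_ratio", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = (out["a"] >= min_risk_blocks) & (out["q_value"] < alpha)
    return out[ENRICHMENT_COLUMNS]


def community_risk_enrichment_by_trait(
    block_community: pd.Series,
    block_trait_risk: pd.DataFrame,
    min_risk_blocks: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`community_risk_enrichment` separately per trait.

    ``block_trait_risk``: boolean DataFrame blocks x traits.  Results gain a
    ``trait`` column; BH is applied within each trait's analysis.
    """
    frames = []
    for trait in block_trait_risk.columns:
        res = community_risk_enrichment(
            block_community, block_trait_risk[trait], min_risk_blocks, alpha
        )
        res.insert(0, "trait", trait)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gene-set overrepresentation
# ---------------------------------------------------------------------------

def gene_set_enrichment(
    community_genes,
    gene_sets: dict[str, set[str]],
    background_genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each gene set among a
    community's genes, against the network gene background; BH across sets.
    Sets with no overlap with the background are skipped with a warning.
    """
    background = set(background_genes)
    comm = set(community_genes) & background
    N, K = len(background), len(comm)
    rows = []
    for name in sorted(gene_sets):
        in_bg = gene_sets[name] & background
        if not in_bg:
            logger.warning("gene_set_enrichment: set %s has no background overlap, skipped", name)
            continue
        n_set = len(in_bg)
        k = len(in_bg & comm)
        # P(X >= k) for X ~ Hypergeom(N, n_set, K)
        p = float(stats.hypergeom.sf(k - 1, N, n_set, K))
        a, b = k, n_set - k
        c, d = K - k, N - n_set - (K - k)
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)) if min(a, b, c, d) == 0 else (a * d) / (b * c)
        rows.append((name, a, b, c, d, orat, p))
    out = pd.DataFrame(rows, columns=["unit_id", "a", "b", "c", "d", "odds_ratio", "p_value"])
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] < alpha
    return out[ENRICHMENT_COLUMNS]


# ---------------------------------------------------------------------------
# promoter enrichment
# ---------------------------------------------------------------------------

def promoter_intervals(
    gene_ann: pd.DataFrame, upstream_bp: int = 750, downstream_bp: int = 250
) -> pd.DataFrame:
    """Strand-aware promoter windows [TSS - upstream, TSS + downstream] in the
    direction of transcription (closed interval, 1-based).  Missing strand is
    treated as '+' with a warning."""
    ann = gene_ann.copy()
    if ann["strand"].isna().any():
        logger.warning("promoter_intervals: missing strand assumed '+'")
        ann["strand"] = ann["strand"].fillna("+")
    plus = ann["strand"] != "-"
    tss = ann["tss"].astype(int)
    start = np.where(plus, tss - upstream_bp, tss - downstream_bp)
    end = np.where(plus, tss + downstream_bp, tss + upstream_bp)
    return pd.DataFrame({"chrom": ann["chrom"], "start": start, "end": end}, index=ann.index)


def snps_in_promoters(snp_meta: pd.DataFrame, promoters: pd.DataFrame) -> pd.Series:
    """Boolean per SNP: does it fall inside any of the given promoter windows."""
    hit = pd.Series(False, index=snp_meta.index)
    for chrom, group in promoters.groupby("chrom"):
        on_chrom = snp_meta["chrom"] == chrom
        if not on_chrom.any():
            continue
        pos = snp_meta.loc[on_chrom, "pos"].to_numpy(float)
        inside = np.zeros(len(pos), bool)
        for _, row in group.iterrows():
            inside |= (pos >= row["start"]) & (pos <= row["end"])
        hit.loc[on_chrom] |= inside
    return hit


def promoter_enrichment(
    snp_meta: pd.DataFrame,
    gene_ann: pd.DataFrame,
    cancer_genes,
    blocks: pd.Series,
    snp_risk: pd.Series,
    upstream_bp: int = 750,
    downstream_bp: int = 250,
) -> pd.DataFrame:
    """Are risk LD blocks overrepresented among blocks touching cancer-gene
    promoters?  Counted per LD block; the same test against all-gene
    promoters is reported as a contrast row.
    """
    cancer_genes = [g for g in cancer_genes if g in gene_ann.index]
    results = []
    for label, genes in (("cancer_gene_promoters", cancer_genes),
                         ("all_gene_promoters", list(gene_ann.index))):
        proms = promoter_intervals(gene_ann.loc[genes], upstream_bp, downstream_bp)
        snp_hit = snps_in_promoters(snp_meta, proms)
        df = pd.DataFrame({
            "block": blocks.reindex(snp_meta.index),
            "hit": snp_hit,
            "risk": snp_risk.reindex(snp_meta.index).fillna(False).astype(bool),
        }).dropna(subset=["block"])
        per_block = df.groupby("block").agg(hit=("hit", "any"), risk=("risk", "any"))
        a = int((per_block["risk"] & per_block["hit"]).sum())
        b = int((per_block["risk"] & ~per_block["hit"]).sum())
        c = int((~per_block["risk"] & per_block["hit"]).sum())
        d = int((~per_block["risk"] & ~per_block["hit"]).sum())
        res = fisher_test(a, b, c, d, alternative="greater")
        results.append((label, a, b, c, d, res.odds_ratio, res.p_value))
    out = pd.DataFrame(results, columns=["unit_id", "a", "b", "c", "d", "odds_ratio", "p_value"])
    out["q_value"] = out["p_value"]
    out["enriched"] = out["q_value"] < 0.05
    return out[ENRICHMENT_COLUMNS]


# ---------------------------------------------------------------------------
# cis/trans contrast
# ---------------------------------------------------------------------------

def risk_cis_trans_enrichment(edge_table: pd.DataFrame, snp_risk: pd.Series) -> pd.DataFrame:
    """Are risk-SNP eQTL edges enriched for trans (vs cis) relative to
    non-risk edges?  One row, counted per significant edge."""
    risk = edge_table["snp_id"].map(snp_risk).fillna(False).astype(bool)
    trans = ~edge_table["cis_flag"].astype(bool)
    a = int((risk & trans).sum())
    b = int((risk & ~trans).sum())
    c = int((~risk & trans).sum())
    d = int((~risk & ~trans).sum())
    res = fisher_test(a, b, c, d, alternative="greater")
    out = pd.DataFrame(
        [("risk_trans_vs_cis", a, b, c, d, res.odds_ratio, res.p_value)],
        columns=["unit_id", "a", "b", "c", "d", "odds_ratio", "p_value"],
    )
    out["q_value"] = out["p_value"]
    out["enriched"] = out["q_value"] < 0.05
    return out[ENRICHMENT_COLUMNS]
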