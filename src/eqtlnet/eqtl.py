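"""cis/trans eQTL mapping with an additive linear model.

Each SNP-gene pair is tested with ordinary least squares of expression on
genotype dosage plus covariates (age, sex, ancestry, genotype PCs),
a two-sided t-test on the genotype coefficient, and Benjamini-Hochberg
adjustment applied to the cis and trans strata separately.  Samples with a
missing genotype are dropped pairwise.  The implementation residualizes
expression and dosage against the covariate design once per missingness
pattern (Frisch-Waugh-Lovell), which is algebraically identical to the full
joint fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import GenotypeMatrix, recompute_snp_stats

logger = logging.getLogger(__name__)

EQTL_COLUMNS = ["snp_id", "gene_id", "beta", "t_stat", "p_value", "q_value", "cis_flag"]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_snps(genotypes: GenotypeMatrix, config: PipelineConfig) -> GenotypeMatrix:
    """Drop SNPs with call rate below ``call_rate_min`` or MAF below ``maf_min``.

    Removal is strict ("under" the thresholds), so a SNP at exactly the
    call-rate or MAF boundary is retained.
    """
    if genotypes.snps["maf"].isna().all():
        recompute_snp_stats(genotypes)
    meta = genotypes.snps
    keep = (meta["call_rate"] >= config.call_rate_min) & (meta["maf"] >= config.maf_min)
    kept = meta.index[keep.fillna(False)]
    if len(kept) == 0:
        raise ValueError("all SNPs removed by call-rate/MAF filters")
    logger.info("filter_snps: kept %d / %d SNPs", len(kept), len(meta))
    return genotypes.subset_snps(kept)


def filter_genes(raw_counts: pd.DataFrame, config: PipelineConfig) -> list[str]:
    """Genes kept iff >= ``expr_min_samples`` samples have count >= ``expr_count_min``."""
    expressed = (raw_counts >= config.expr_count_min).sum(axis=0)
    kept = raw_counts.columns[expressed >= config.expr_min_samples]
    logger.info("filter_genes: kept %d / %d genes", len(kept), raw_counts.shape[1])
    return list(kept)


def classify_cis_trans(
    snp_meta: pd.DataFrame, gene_ann: pd.DataFrame, cis_window_bp: int = 1_000_000
) -> pd.DataFrame:
    """Boolean SNP x gene matrix: True where the pair is cis.

    cis iff same chromosome and |pos - TSS| <= window (inclusive).  Pairs
    whose SNP or gene lacks chromosome/position annotation are excluded by
    the caller; here they simply come out trans=False/cis=False via NaN
    handling.
    """
    snp_chrom = snp_meta["chrom"].to_numpy(object)
    gene_chrom = gene_ann["chrom"].to_numpy(object)
    same_chrom = snp_chrom[:, None] == gene_chrom[None, :]
    dist = np.abs(snp_meta["pos"].to_numpy(float)[:, None] - gene_ann["tss"].to_numpy(float)[None, :])
    cis = same_chrom & (dist <= cis_window_bp)
    return pd.DataFrame(cis, index=snp_meta.index, columns=gene_ann.index)


# ---------------------------------------------------------------------------
# single-pair OLS
# ---------------------------------------------------------------------------

@dataclass
class EqtlFit:
    beta: float
    t_stat: float
    p_value: float
    n: int


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Covariate design with intercept; categoricals dummy-coded (first level
    reference), categorical columns with <2 observed levels dropped."""
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "biufc":
            cols.append(col.to_numpy(float))
        else:
            levels = pd.unique(col.astype(str))
            if len(levels) < 2:
                continue
            for level in levels[1:]:
                cols.append((col.astype(str) == level).to_numpy(float))
    return np.column_stack(cols)


def fit_eqtl(
    genotype: np.ndarray, expression: np.ndarray, covariates: np.ndarray | None = None
) -> EqtlFit | None:
    """OLS of expression on genotype + covariates; t-test on the genotype slope.

    ``covariates`` is a design matrix WITHOUT the genotype column; an
    intercept is added if absent.  Samples with missing genotype or
    expression are dropped.  Returns ``None`` when the pair is untestable
    (constant genotype after dropping missing, or too few samples).
    """
    g = np.asarray(genotype, float)
    y = np.asarray(expression, float)
    if covariates is None:
        X = np.ones((len(g), 1))
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        has_const = bool(np.any(np.all(X == X[:1], axis=0)))
        if not has_const:
            X = np.column_stack([np.ones(len(g)), X])
    mask = ~(np.isnan(g) | np.isnan(y))
    g, y, X = g[mask], y[mask], X[mask]
    n, p = X.shape
    if n < p + 3 or np.ptp(g) == 0:
        return None
    Q, _ = np.linalg.qr(X)
    gr = g - Q @ (Q.T @ g)
    yr = y - Q @ (Q.T @ y)
    gg = gr @ gr
    if gg <= 1e-12 * (g @ g + 1.0):
        return None  # genotype collinear with covariates
    beta = (gr @ yr) / gg
    rss = yr @ yr - beta * beta * gg
    df = n - p - 1
    sigma2 = max(rss, 0.0) / df
    if sigma2 == 0:
        t = np.inf if beta != 0 else 0.0
    else:
        t = beta / np.sqrt(sigma2 / gg)
    pval = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return EqtlFit(beta=float(beta), t_stat=float(t), p_value=float(pval), n=int(n))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def run_eqtl_scan(
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None,
    config: PipelineConfig,
    gene_ann: pd.DataFrame | None = None,
    cis_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test every SNP x gene pair; return the full EqtlTable.

    The scan iterates over SNPs, residualizing each gene's expression against
    the covariate design restricted to that SNP's non-missing samples, so a
    pair's statistics equal :func:`fit_eqtl` on the same data.  q-values are
    BH within the cis stratum and within the trans stratum separately.
    Untestable pairs (constant genotype) are logged and omitted.
    """
    samples = genotypes.samples
    expr = expression.loc[samples]
    Y = expr.to_numpy(float)
    X = build_design(covariates.loc[samples]) if covariates is not None else np.ones((len(samples), 1))
    G = genotypes.dosages.to_numpy(float)
    snp_ids = list(genotypes.snp_ids)
    gene_ids = list(expr.columns)

    if cis_mask is None:
        if gene_ann is None:
            raise ValueError("need gene_ann or cis_mask to classify cis/trans")
        ann = gene_ann.loc[[g for g in gene_ids if g in gene_ann.index]]
        missing_genes = set(gene_ids) - set(ann.index)
        if missing_genes:
            logger.warning("run_eqtl_scan: %d genes lack annotation, excluded", len(missing_genes))
            gene_ids = [g for g in gene_ids if g in ann.index]
            Y = expr[gene_ids].to_numpy(float)
        cis_mask = classify_cis_trans(genotypes.snps, ann, config.cis_window_bp)
    cis_arr = cis_mask.loc[snp_ids, gene_ids].to_numpy(bool)

    n_all, p_cols = X.shape
    # fast path pre-computation for SNPs with complete calls
    Q_full, _ = np.linalg.qr(X)
    Yr_full = Y - Q_full @ (Q_full.T @ Y)
    y_nan = np.isnan(Y)
    if y_nan.any():
        raise ValueError("expression matrix must not contain missing values")

    rows_snp, rows_gene, betas, tstats, pvals, cis_out = [], [], [], [], [], []
    n_untestable = 0
    for s_idx, snp in enumerate(snp_ids):
        g = G[:, s_idx]
        mask = ~np.isnan(g)
        n = int(mask.sum())
        if n < p_cols + 3 or np.ptp(g[mask]) == 0:
            n_untestable += len(gene_ids)
            logger.info("run_eqtl_scan: SNP %s untestable (constant or too few calls)", snp)
            continue
        if n == n_all:
            gr = g - Q_full @ (Q_full.T @ g)
            Yr = Yr_full
        else:
            Xs = X[mask]
            Qs, _ = np.linalg.qr(Xs)
            gs = g[mask]
            gr = gs - Qs @ (Qs.T @ gs)
            Ys = Y[mask]
            Yr = Ys - Qs @ (Qs.T @ Ys)
        gg = gr @ gr
        if gg <= 1e-12 * (np.nansum(g * g) + 1.0):
            n_untestable += len(gene_ids)
            continue
        beta = (Yr.T @ gr) / gg
        rss = np.einsum("ij,ij->j", Yr, Yr) - beta * beta * gg
        df = n - p_cols - 1
        sigma2 = np.maximum(rss, 0.0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(sigma2 / gg)
        t = np.where(sigma2 == 0, np.where(beta == 0, 0.0, np.inf), t)
        p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df), 0.0)
        rows_snp.extend([snp] * len(gene_ids))
        rows_gene.extend(gene_ids)
        betas.append(beta)
        tstats.append(t)
        pvals.append(p)
        cis_out.append(cis_arr[s_idx])

    if not rows_snp:
        raise ValueError("no testable SNP-gene pairs")
    if n_untestable:
        logger.info("run_eqtl_scan: %d untestable pairs skipped", n_untestable)

    table = pd.DataFrame(
        {
            "snp_id": rows_snp,
            "gene_id": rows_gene,
            "beta": np.concatenate(betas),
            "t_stat": np.concatenate(tstats),
            "p_value": np.concatenate(pvals),
            "cis_flag": np.concatenate(cis_out),
        }
    )
    table["q_value"] = np.nan
    for flag in (True, False):
        m = table["cis_flag"] == flag
        if m.any():
            table.loc[m, "q_value"] = bh_adjust(table.loc[m, "p_value"].to_numpy())
    table = table.sort_values(["snp_id", "gene_id"], kind="mergesort").reset_index(drop=True)
    return table[EQTL_COLUMNS]


def significant_edges(eqtl_table: pd.DataFrame, fdr_threshold: float) -> pd.DataFrame:
    """Rows with q < threshold (union of the cis and trans strata)."""
    return eqtl_table[eqtl_table["q_value"] < fdr_threshold].reset_index(drop=True)
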