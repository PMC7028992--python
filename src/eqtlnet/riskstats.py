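"""Risk-SNP network statistics.

Two bespoke tests characterize where GWAS risk SNPs sit in the eQTL
network:

* a degree-matched resampling test asking whether risk SNPs target more
  cancer genes than expected given their overall connectivity ("cancer
  degree"), using the Mann-Whitney U statistic against an empirical null of
  pseudo-risk sets drawn within total-degree bins; and

* a likelihood-ratio test asking whether risk status explains SNP core
  scores beyond community membership, comparing nested Gaussian linear
  models (core score ~ community indicators, with vs without a risk
  indicator) on per-LD-block median core scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import BipartiteNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cancer degree
# ---------------------------------------------------------------------------

def cancer_degree(network: BipartiteNetwork, cancer_genes) -> pd.Series:
    """Per-SNP count of network edges to genes in the cancer-gene list."""
    cancer = set(cancer_genes)
    return pd.Series(
        {s: len(network.genes_of(s) & cancer) for s in sorted(network.snp_nodes)},
        name="cancer_degree",
    ).rename_axis("snp_id")


# ---------------------------------------------------------------------------
# degree-matched resampling test
# ---------------------------------------------------------------------------

@dataclass
class DegreeTestResult:
    u_observed: float
    p_value: float
    n_resamples: int
    n_risk_units: int
    n_units: int
    seed: int | None
    u_null_mean: float
    u_null_sd: float
    unit: str  # "block" or "snp"


def _u_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y (ties mid-ranked): U = R_x - n_x(n_x+1)/2."""
    n_x = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2)


def degree_matched_resampling_test(
    network: BipartiteNetwork,
    risk_flags: pd.Series,
    cancer_genes,
    n_resamples: int = 10_000,
    seed: int | None = None,
    blocks: pd.Series | None = None,
    n_degree_bins: int = 10,
) -> DegreeTestResult:
    """Do risk SNPs have higher cancer degree than degree-matched non-risk SNPs?

    The observed Mann-Whitney U compares cancer-degree between risk and
    non-risk units.  Units are LD blocks when ``blocks`` is supplied
    (degrees summed over member SNPs), individual SNPs otherwise.  The null
    redraws pseudo-risk unit sets of the same size from within total-degree
    quantile bins (default deciles), preserving the risk set's degree
    profile; the empirical p is (1 + #{U_null >= U_obs}) / (n_resamples + 1).
    If the whole network is risk-flagged the test is degenerate and p = 1.
    """
    cdeg = cancer_degree(network, cancer_genes)
    tdeg = pd.Series(network.snp_degrees).reindex(cdeg.index)
    risk = risk_flags.reindex(cdeg.index).fillna(False).astype(bool)

    if blocks is not None:
        unit_name = "block"
        grp = blocks.reindex(cdeg.index)
        df = pd.DataFrame({"block": grp, "cdeg": cdeg, "tdeg": tdeg, "risk": risk}).dropna(
            subset=["block"]
        )
        units = df.groupby("block").agg(
            cdeg=("cdeg", "sum"), tdeg=("tdeg", "sum"), risk=("risk", "any")
        )
    else:
        unit_name = "snp"
        units = pd.DataFrame({"cdeg": cdeg, "tdeg": tdeg, "risk": risk})

    is_risk = units["risk"].to_numpy(bool)
    n_risk = int(is_risk.sum())
    n_units = len(units)
    if n_risk == 0:
        raise ValueError("no risk units in the network")
    if n_risk == n_units:
        logger.warning("degree_matched_resampling_test: every unit is risk; degenerate, p = 1")
        return DegreeTestResult(np.nan, 1.0, n_resamples, n_risk, n_units, seed,
                                np.nan, np.nan, unit_name)

    cd = units["cdeg"].to_numpy(float)
    td = units["tdeg"].to_numpy(float)
    u_obs = _u_stat(cd[is_risk], cd[~is_risk])

    # total-degree quantile bins over all units
    edges = np.unique(np.quantile(td, np.linspace(0, 1, n_degree_bins + 1)))
    bin_of = np.clip(np.searchsorted(edges, td, side="right") - 1, 0, len(edges) - 2)
    # merge upward any bin whose pseudo-risk pool has no non-risk member
    for b in sorted(np.unique(bin_of)):
        in_b = bin_of == b
        if in_b.any() and is_risk[in_b].all() and b + 1 <= bin_of.max():
            warnings.warn(f"degree bin {b} has no non-risk units; merged upward")
            bin_of[in_b] = b + 1

    rng = np.random.default_rng(seed)
    bin_ids = np.unique(bin_of)
    members = {b: np.flatnonzero(bin_of == b) for b in bin_ids}
    need = {b: int(is_risk[members[b]].sum()) for b in bin_ids}

    count_ge = 0
    u_null = np.empty(n_resamples)
    all_idx = np.arange(n_units)
    for r in range(n_resamples):
        chosen = []
        for b in bin_ids:
            if need[b]:
                chosen.append(rng.choice(members[b], size=need[b], replace=False))
        pseudo = np.zeros(n_units, bool)
        pseudo[np.concatenate(chosen)] = True
        u = _u_stat(cd[pseudo], cd[~pseudo])
        u_null[r] = u
        if u >= u_obs:
            count_ge += 1
    p = (1 + count_ge) / (n_resamples + 1)
    return DegreeTestResult(
        u_observed=u_obs,
        p_value=float(p),
        n_resamples=n_resamples,
        n_risk_units=n_risk,
        n_units=n_units,
        seed=seed,
        u_null_mean=float(u_null.mean()),
        u_null_sd=float(u_null.std()),
        unit=unit_name,
    )


# ---------------------------------------------------------------------------
# core-score LRT on per-block medians
# ---------------------------------------------------------------------------

def snp_status(gwas_labels: pd.DataFrame, cancer_traits=None, p_threshold: float = 5e-8) -> pd.Series:
    """Classify labelled SNPs as 'risk' (cancer trait at genome-wide
    significance) or 'other_trait'; SNPs absent from the labels are
    'non_gwas' by convention downstream.

    ``cancer_traits``: iterable of trait names to treat as cancer; defaults
    to traits whose name matches common cancer terms.
    """
    sig = gwas_labels[gwas_labels["p_value"] <= p_threshold]
    if cancer_traits is None:
        pat = "cancer|carcinoma|leukaemia|leukemia|lymphoma|melanoma|glioma|myeloma|tumour|tumor"
        is_cancer = sig["trait"].str.contains(pat, case=False, regex=True)
    else:
        is_cancer = sig["trait"].isin(set(cancer_traits))
    status = pd.Series("other_trait", index=pd.Index(sig["snp_id"].unique(), name="snp_id"))
    risk_ids = sig.loc[is_cancer, "snp_id"].unique()
    status.loc[status.index.isin(risk_ids)] = "risk"
    return status


def collapse_by_block(
    core_scores: pd.DataFrame,
    snp_status: pd.Series,
    blocks: pd.Series,
) -> pd.DataFrame:
    """Median core score per (LD block, status), for risk and non-GWAS SNPs.

    ``snp_status`` maps labelled SNPs to 'risk' or 'other_trait'; SNPs not
    present are non-GWAS.  Other-trait SNPs are excluded entirely.  Each
    block also carries its dominant community (most frequent among its SNPs
    in the network; ties -> lowest index) for use as a covariate.  Blocks
    with no eligible SNPs are dropped.
    """
    df = core_scores.copy()
    df["status"] = snp_status.reindex(df.index).fillna("non_gwas")
    df["block"] = blocks.reindex(df.index)
    df = df.dropna(subset=["block"])
    df = df[df["status"] != "other_trait"]
    if df.empty:
        return pd.DataFrame(columns=["block", "status", "median_core_score", "community"])

    def dom_comm(s: pd.Series) -> int:
        counts = s.value_counts()
        return int(min(counts[counts == counts.max()].index))

    block_comm = df.groupby("block")["community"].agg(dom_comm)
    out = (
        df.groupby(["block", "status"])["core_score"].median().rename("median_core_score").reset_index()
    )
    out["community"] = out["block"].map(block_comm)
    return out.sort_values(["block", "status"], kind="mergesort").reset_index(drop=True)


@dataclass
class LrtResult:
    statistic: float
    p_value: float
    df: int
    loglik_null: float
    loglik_full: float
    risk_coefficient: float
    n: int


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def core_score_lrt(collapsed: pd.DataFrame, use_f_test: bool = False) -> LrtResult:
    """Nested-model LRT for a risk effect on block-median core scores.

    Null model: score ~ community indicators (n-1 of them + intercept).
    Full model: null + I(risk).  The statistic is 2*(l_full - l_null) with
    Gaussian profile likelihoods, equivalently N * log(RSS_null / RSS_full),
    referred to chi-square with 1 df (or, with ``use_f_test``, the exact
    F(1, N - p_full) reference).
    """
    if collapsed.empty:
        raise ValueError("no collapsed core-score records")
    statuses = set(collapsed["status"])
    if not {"risk", "non_gwas"} <= statuses:
        raise ValueError(f"need both 'risk' and 'non_gwas' records, got {sorted(statuses)}")
    y = collapsed["median_core_score"].to_numpy(float)
    n = len(y)
    comms = sorted(collapsed["community"].unique())
    cols = [np.ones(n)]
    # n-1 community indicators, first community as reference
    for c in comms[1:]:
        cols.append((collapsed["community"] == c).to_numpy(float))
    X0 = np.column_stack(cols)
    risk_col = (collapsed["status"] == "risk").to_numpy(float)
    X1 = np.column_stack([X0, risk_col])

    rank0 = np.linalg.matrix_rank(X0)
    if rank0 < X0.shape[1]:
        logger.warning("core_score_lrt: community design rank-deficient; collinear columns dropped")
    rss0, _ = _ols_rss(X0, y)
    rss1, beta1 = _ols_rss(X1, y)
    rss1 = min(rss1, rss0)  # guard floating round-off; full model nests null
    if rss1 <= 0:
        stat = np.inf if rss0 > 0 else 0.0
    else:
        stat = n * np.log(rss0 / rss1)
    ll_null = -n / 2 * (np.log(2 * np.pi * max(rss0, 1e-300) / n) + 1)
    ll_full = -n / 2 * (np.log(2 * np.pi * max(rss1, 1e-300) / n) + 1)
    if use_f_test:
        df_resid = n - np.linalg.matrix_rank(X1)
        f = (rss0 - rss1) / (rss1 / df_resid) if rss1 > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_resid))
    else:
        p = float(stats.chi2.sf(stat, 1)) if np.isfinite(stat) else 0.0
    return LrtResult(
        statistic=float(stat),
        p_value=p,
        df=1,
        loglik_null=float(ll_null),
        loglik_full=float(ll_full),
        risk_coefficient=float(beta1[-1]),
        n=n,
    )
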