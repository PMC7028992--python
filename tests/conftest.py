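"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: OLS via
explicit normal equations, modularity via the full double loop over node
pairs, Fisher via fixed-margin enumeration, connected components via BFS.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlnet.network import BipartiteNetwork
from eqtlnet.simulate import SimulationDesign, simulate_dataset


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    return SimulationDesign(
        n_samples=150, n_blocks=12, snps_per_block=4, n_genes=45,
        n_communities=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """(genotypes, expression, counts, covariates, annotation, labels, gene_sets, truth)."""
    return simulate_dataset(small_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202409)


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def biclique_network(n_cliques: int, n_snps: int = 2, n_genes: int = 2,
                     bridge: bool = False) -> BipartiteNetwork:
    """Disjoint complete bipartite blocks s{c}_* x g{c}_*, optionally chained
    by single bridge edges."""
    edges = []
    for c in range(n_cliques):
        for i in range(n_snps):
            for j in range(n_genes):
                edges.append((f"s{c}_{i}", f"g{c}_{j}"))
    if bridge:
        for c in range(n_cliques - 1):
            edges.append((f"s{c}_0", f"g{c + 1}_0"))
    snps = sorted({e[0] for e in edges})
    genes = sorted({e[1] for e in edges})
    return BipartiteNetwork(snps, genes, edges)


def random_bipartite(rng: np.random.Generator, n_snps: int, n_genes: int,
                     p_edge: float = 0.35) -> BipartiteNetwork | None:
    """Random bipartite graph; returns None if any node ends up isolated."""
    edges = [
        (f"s{i}", f"g{j}")
        for i in range(n_snps)
        for j in range(n_genes)
        if rng.random() < p_edge
    ]
    snps = {e[0] for e in edges}
    genes = {e[1] for e in edges}
    if len(snps) < n_snps or len(genes) < n_genes:
        return None
    return BipartiteNetwork(sorted(snps), sorted(genes), edges)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ols_oracle(X: np.ndarray, y: np.ndarray, coef_idx: int):
    """Closed-form OLS via normal equations: beta, t and two-sided p for one
    coefficient."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * XtX_inv[coef_idx, coef_idx])
    t = beta[coef_idx] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[coef_idx], t, p


def modularity_double_loop(network: BipartiteNetwork, snp_comm: dict, gene_comm: dict) -> float:
    """Eq.-by-eq evaluation over every (SNP, gene) pair, edges and non-edges."""
    m = network.m
    total = 0.0
    for s in network.snp_nodes:
        for g in network.gene_nodes:
            if snp_comm[s] == gene_comm[g]:
                a = 1.0 if g in network.genes_of(s) else 0.0
                total += a - network.snp_degree(s) * network.gene_degree(g) / m
    return total / m


def set_partitions(items):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def brute_force_optimal_q(network: BipartiteNetwork) -> float:
    """Exact maximum bipartite modularity over all partitions.

    Enumerates set partitions of the gene side; for a fixed gene partition
    each SNP independently picks the community maximizing its own term
    (or a singleton community contributing 0), which is globally optimal
    because modularity decomposes over SNPs given the gene labels.
    """
    m = network.m
    best = -np.inf
    for parts in set_partitions(network.gene_nodes):
        D = [sum(network.gene_degree(g) for g in part) for part in parts]
        gene_comm = {g: idx for idx, part in enumerate(parts) for g in part}
        total = 0.0
        for s in network.snp_nodes:
            counts = {}
            for g in network.genes_of(s):
                c = gene_comm[g]
                counts[c] = counts.get(c, 0) + 1
            best_term = 0.0  # singleton community
            for c, e in counts.items():
                best_term = max(best_term, e - network.snp_degree(s) * D[c] / m)
            total += best_term
        best = max(best, total / m)
    return best


def fisher_enumeration_p(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Exact Fisher p by summing point probabilities over all tables with the
    observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        from math import lgamma

        def lchoose(nn, kk):
            if kk < 0 or kk > nn:
                return -np.inf
            return lgamma(nn + 1) - lgamma(kk + 1) - lgamma(nn - kk + 1)

        return lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: np.exp(log_prob(x)) for x in range(lo, hi + 1)}
    obs = probs[a]
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


def bfs_components(nodes, edges):
    """Connected components via breadth-first search over an edge list."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def adjusted_rand(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))
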