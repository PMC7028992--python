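"""Bipartite SNP-gene network assembly.

Significant eQTLs become unweighted edges between SNP nodes and gene nodes.
Community analyses operate on the giant connected component; smaller
components are logged and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BipartiteNetwork:
    """Unweighted bipartite graph between SNPs and genes.

    ``edges`` holds unique (snp_id, gene_id) pairs; degrees and the edge
    count m are derived.  SNP and gene id namespaces must be disjoint.
    """

    snp_nodes: list[str]
    gene_nodes: list[str]
    edges: list[tuple[str, str]]
    edge_info: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        overlap = set(self.snp_nodes) & set(self.gene_nodes)
        if overlap:
            raise ValueError(f"SNP and gene ids overlap: {sorted(overlap)[:5]}")
        self.snp_nodes = sorted(set(self.snp_nodes))
        self.gene_nodes = sorted(set(self.gene_nodes))
        self.edges = sorted(set(self.edges))
        self._adj_snp: dict[str, set[str]] = {s: set() for s in self.snp_nodes}
        self._adj_gene: dict[str, set[str]] = {g: set() for g in self.gene_nodes}
        for s, g in self.edges:
            self._adj_snp[s].add(g)
            self._adj_gene[g].add(s)
        zero = [n for n, nb in self._adj_snp.items() if not nb]
        zero += [n for n, nb in self._adj_gene.items() if not nb]
        if zero:
            raise ValueError(f"zero-degree nodes not allowed: {zero[:5]}")

    @property
    def m(self) -> int:
        return len(self.edges)

    def snp_degree(self, snp: str) -> int:
        return len(self._adj_snp[snp])

    def gene_degree(self, gene: str) -> int:
        return len(self._adj_gene[gene])

    @property
    def snp_degrees(self) -> dict[str, int]:
        return {s: len(nb) for s, nb in self._adj_snp.items()}

    @property
    def gene_degrees(self) -> dict[str, int]:
        return {g: len(nb) for g, nb in self._adj_gene.items()}

    def genes_of(self, snp: str) -> set[str]:
        return self._adj_snp[snp]

    def snps_of(self, gene: str) -> set[str]:
        return self._adj_gene[gene]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.snp_nodes, bipartite="snp")
        G.add_nodes_from(self.gene_nodes, bipartite="gene")
        G.add_edges_from(self.edges)
        return G

    def edge_table(self) -> pd.DataFrame:
        if self.edge_info is not None:
            return self.edge_info
        return pd.DataFrame(self.edges, columns=["snp_id", "gene_id"])


def build_network(eqtl_table: pd.DataFrame, fdr_threshold: float) -> BipartiteNetwork:
    """One edge per SNP-gene pair with q < threshold; duplicates collapsed.

    Raises ``ValueError`` when no pair is significant.
    """
    sig = eqtl_table[eqtl_table["q_value"] < fdr_threshold]
    if sig.empty:
        raise ValueError(f"no SNP-gene pair passes q < {fdr_threshold}: empty network")
    sig = sig.drop_duplicates(subset=["snp_id", "gene_id"])
    edges = list(zip(sig["snp_id"], sig["gene_id"]))
    net = BipartiteNetwork(
        snp_nodes=sig["snp_id"].unique().tolist(),
        gene_nodes=sig["gene_id"].unique().tolist(),
        edges=edges,
        edge_info=sig.sort_values(["snp_id", "gene_id"], kind="mergesort").reset_index(drop=True),
    )
    logger.info("build_network: %d SNPs, %d genes, %d edges",
                len(net.snp_nodes), len(net.gene_nodes), net.m)
    return net


def connected_components(network: BipartiteNetwork) -> list[set[str]]:
    G = network.to_networkx()
    return [set(c) for c in nx.connected_components(G)]


def giant_component(network: BipartiteNetwork) -> BipartiteNetwork:
    """Largest connected component by node count.

    Ties broken by larger edge count, then by lexicographically smallest
    member node id.  Removed components are logged with their sizes.
    """
    comps = connected_components(network)
    if len(comps) == 1:
        return network

    def edge_count(nodes: set[str]) -> int:
        return sum(1 for s, g in network.edges if s in nodes)

    ranked = sorted(
        comps, key=lambda c: (-len(c), -edge_count(c), min(c))
    )
    keep = ranked[0]
    for comp in ranked[1:]:
        logger.info("giant_component: dropping component with %d nodes, %d edges",
                    len(comp), edge_count(comp))
    edges = [(s, g) for s, g in network.edges if s in keep]
    info = network.edge_info
    if info is not None:
        info = info[info["snp_id"].isin(keep)].reset_index(drop=True)
    return BipartiteNetwork(
        snp_nodes=[s for s in network.snp_nodes if s in keep],
        gene_nodes=[g for g in network.gene_nodes if g in keep],
        edges=edges,
        edge_info=info,
    )


def is_connected(network: BipartiteNetwork) -> bool:
    return nx.is_connected(network.to_networkx())


def write_edge_list(network: BipartiteNetwork, path) -> None:
    network.edge_table().to_csv(path, sep="\t", index=False, float_format="%.10g")
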