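"""Bipartite modularity communities and SNP core scores.

The modularity of a SNP/gene partition of a bipartite network is

    Q = (1/m) * sum_{i,j} (A_ij - k_i * d_j / m) * delta(C_i, C_j)

with m the edge count, A the binary SNP x gene biadjacency block, k_i / d_j
the SNP and gene degrees and C the community labels.  Only SNP-gene pairs
sharing a community contribute, so for a fixed gene-side partition each SNP's
optimal community can be chosen independently, and vice versa; community
detection alternates these two closed-form reassignment sweeps (the condor /
BRIM scheme), seeded from a unipartite clustering of the weighted gene-space
projection, until the modularity gain drops below tolerance.

A SNP's core score is its additive contribution to its own community's
modularity,

    Q_ih = (1/m) * sum_j (A_ij - k_i d_j / m) * delta(C_i, h) * delta(C_j, h),

so core scores over all SNPs sum exactly to Q.  High Q_ih marks a local hub
of community h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import BipartiteNetwork

logger = logging.getLogger(__name__)


@dataclass
class CommunityAssignment:
    """Community index per node (contiguous, starting at 1)."""

    snp_community: dict[str, int]
    gene_community: dict[str, int]
    modularity: float = np.nan
    converged: bool = True

    @property
    def n_communities(self) -> int:
        labels = set(self.snp_community.values()) | set(self.gene_community.values())
        return len(labels)

    def labels(self, nodes) -> np.ndarray:
        merged = {**self.snp_community, **self.gene_community}
        return np.array([merged[n] for n in nodes])

    def compact(self) -> "CommunityAssignment":
        """Relabel communities to contiguous indices 1..n (order of first use
        by sorted node id)."""
        mapping: dict[int, int] = {}
        for node in sorted(self.snp_community) + sorted(self.gene_community):
            c = self.snp_community.get(node, self.gene_community.get(node))
            if c not in mapping:
                mapping[c] = len(mapping) + 1
        return CommunityAssignment(
            {s: mapping[c] for s, c in self.snp_community.items()},
            {g: mapping[c] for g, c in self.gene_community.items()},
            self.modularity,
            self.converged,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, "snp", c) for n, c in sorted(self.snp_community.items())]
        rows += [(n, "gene", c) for n, c in sorted(self.gene_community.items())]
        return pd.DataFrame(rows, columns=["node_id", "node_type", "community"])


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity(network: BipartiteNetwork, assignment: CommunityAssignment) -> float:
    """Evaluate bipartite modularity of ``assignment`` on ``network``.

    Computed per community as (E_c - K_c * D_c / m) summed and divided by m,
    where E_c is the number of within-community edges and K_c / D_c the
    summed SNP / gene degrees — identical to the double sum over all node
    pairs, including the null-model term of non-edges.
    """
    m = network.m
    snp_c = assignment.snp_community
    gene_c = assignment.gene_community
    missing = (set(network.snp_nodes) - snp_c.keys()) | (set(network.gene_nodes) - gene_c.keys())
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    E: dict[int, int] = {}
    K: dict[int, int] = {}
    D: dict[int, int] = {}
    for s, g in network.edges:
        if snp_c[s] == gene_c[g]:
            E[snp_c[s]] = E.get(snp_c[s], 0) + 1
    for s in network.snp_nodes:
        K[snp_c[s]] = K.get(snp_c[s], 0) + network.snp_degree(s)
    for g in network.gene_nodes:
        D[gene_c[g]] = D.get(gene_c[g], 0) + network.gene_degree(g)
    total = 0.0
    for c in set(K) | set(D):
        total += E.get(c, 0) - K.get(c, 0) * D.get(c, 0) / m
    return total / m


# ---------------------------------------------------------------------------
# initialization: weighted gene-space projection
# ---------------------------------------------------------------------------

def gene_projection(network: BipartiteNetwork) -> nx.Graph:
    """Unipartite gene graph weighted by the number of shared SNP neighbours."""
    G = nx.Graph()
    G.add_nodes_from(network.gene_nodes)
    for snp in network.snp_nodes:
        genes = sorted(network.genes_of(snp))
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                if G.has_edge(a, b):
                    G[a][b]["weight"] += 1
                else:
                    G.add_edge(a, b, weight=1)
    return G


def initial_partition(network: BipartiteNetwork, seed: int | None = None) -> CommunityAssignment:
    """Seed assignment: greedy modularity on the gene projection, then each
    SNP adopts the community holding the largest fraction of its gene
    neighbours (ties -> lowest community index)."""
    proj = gene_projection(network)
    if proj.number_of_edges() == 0:
        comms = [{g} for g in sorted(network.gene_nodes)]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(proj, weight="weight")]
        isolated = set(network.gene_nodes) - set().union(*comms)
        comms += [{g} for g in sorted(isolated)]
    # deterministic labels: order communities by smallest member id
    comms = sorted(comms, key=min)
    gene_comm = {g: idx + 1 for idx, comm in enumerate(comms) for g in comm}
    snp_comm = {}
    for snp in network.snp_nodes:
        counts: dict[int, int] = {}
        for g in network.genes_of(snp):
            counts[gene_comm[g]] = counts.get(gene_comm[g], 0) + 1
        best = min(sorted(counts), key=lambda c: (-counts[c], c))
        snp_comm[snp] = best
    out = CommunityAssignment(snp_comm, gene_comm).compact()
    out.modularity = modularity(network, out)
    return out


# ---------------------------------------------------------------------------
# bipartite maximization
# ---------------------------------------------------------------------------

def detect_communities(
    network: BipartiteNetwork,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CommunityAssignment:
    """Maximize bipartite modularity by alternating closed-form sweeps.

    Given the gene labels, every SNP i moves to the community c maximizing
    e_ic - k_i * D_c / m (its modularity term), with the option of an empty
    community (term 0); ties keep the current community, then prefer the
    lowest index.  The symmetric sweep updates genes.  Each sweep maximizes
    Q given the other side fixed, so Q never decreases.  Because single-node
    moves can neither split nor merge whole communities, each converged
    sweep phase is followed by a greedy community-merge phase (merge the
    pair with the largest positive modularity gain) and the alternation
    repeats until neither phase improves Q by ``tol``.  Two deterministic
    starts are tried — the weighted gene-projection clustering and the
    all-singleton gene partition — and the better final assignment is
    returned.
    """
    if min(len(network.snp_nodes), len(network.gene_nodes)) <= 7:
        return _exact_small(network)

    genes_sorted = sorted(network.gene_nodes)
    starts: list[dict] = []
    starts.append(dict(initial_partition(network, seed=seed).gene_community))
    starts.append({g: i + 1 for i, g in enumerate(genes_sorted)})  # all-singleton
    # a few random coarse starts; seeded, so the result is reproducible
    rng = np.random.default_rng(0 if seed is None else seed)
    for _ in range(4):
        n_groups = int(rng.integers(2, max(3, min(len(genes_sorted), 8))))
        labels = rng.integers(1, n_groups + 1, size=len(genes_sorted))
        starts.append({g: int(c) for g, c in zip(genes_sorted, labels)})

    best_out: CommunityAssignment | None = None
    for gene_comm in starts:
        snp_comm = {s: gene_comm[min(network.genes_of(s))] for s in network.snp_nodes}
        out = _optimize(network, dict(snp_comm), dict(gene_comm), max_iter, tol)
        if best_out is None or out.modularity > best_out.modularity + 1e-15:
            best_out = out

    # perturb-and-redescend: kick a fraction of genes out of the best
    # partition and re-optimize, keeping any improvement (seeded, so
    # deterministic for a given seed)
    for _ in range(6):
        gene_comm = dict(best_out.gene_community)
        labels = sorted(set(gene_comm.values())) + [max(gene_comm.values()) + 1]
        for g in sorted(gene_comm):
            if rng.random() < 0.25:
                gene_comm[g] = int(labels[rng.integers(0, len(labels))])
        snp_comm = {s: gene_comm[min(network.genes_of(s))] for s in network.snp_nodes}
        out = _optimize(network, dict(snp_comm), dict(gene_comm), max_iter, tol)
        if out.modularity > best_out.modularity + 1e-15:
            best_out = out
    return best_out


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def _exact_small(network: BipartiteNetwork) -> CommunityAssignment:
    """Exact maximum-modularity partition when one node side is small.

    Fixing the partition of one side, every node on the other side has a
    closed-form optimal community (argmax of its own modularity term, or a
    singleton scoring zero), so enumerating set partitions of the smaller
    side searches the full partition space exactly.
    """
    m = network.m
    genes_small = len(network.gene_nodes) <= len(network.snp_nodes)
    if genes_small:
        fixed, free = sorted(network.gene_nodes), sorted(network.snp_nodes)
        deg_fixed, deg_free = network.gene_degrees, network.snp_degrees
        nbrs = network.genes_of
    else:
        fixed, free = sorted(network.snp_nodes), sorted(network.gene_nodes)
        deg_fixed, deg_free = network.snp_degrees, network.gene_degrees
        nbrs = network.snps_of
    best_q, best_parts = -np.inf, None
    for parts in _set_partitions(fixed):
        D = [sum(deg_fixed[x] for x in part) for part in parts]
        fixed_comm = {x: i for i, part in enumerate(parts) for x in part}
        total = 0.0
        for node in free:
            counts: dict[int, int] = {}
            for x in nbrs(node):
                c = fixed_comm[x]
                counts[c] = counts.get(c, 0) + 1
            term = 0.0
            for c, cnt in counts.items():
                term = max(term, cnt - deg_free[node] * D[c] / m)
            total += term
        if total / m > best_q + 1e-15:
            best_q, best_parts = total / m, parts
    fixed_comm = {x: i + 1 for i, part in enumerate(best_parts) for x in part}
    D = {i + 1: sum(deg_fixed[x] for x in part) for i, part in enumerate(best_parts)}
    free_comm = {}
    fresh = len(best_parts)
    for node in free:
        counts: dict[int, int] = {}
        for x in nbrs(node):
            c = fixed_comm[x]
            counts[c] = counts.get(c, 0) + 1
        best_c, best_score = None, 0.0
        for c in sorted(counts):
            score = counts[c] - deg_free[node] * D[c] / m
            if score > best_score + 1e-15 or (best_c is None and score >= -1e-15):
                best_c, best_score = c, max(score, best_score)
        if best_c is None:
            fresh += 1
            best_c = fresh
        free_comm[node] = best_c
    if genes_small:
        out = CommunityAssignment(free_comm, fixed_comm)
    else:
        out = CommunityAssignment(fixed_comm, free_comm)
    out = out.compact()
    out.modularity = modularity(network, out)
    return out


def _optimize(network: BipartiteNetwork, snp_comm: dict, gene_comm: dict,
              max_iter: int, tol: float) -> CommunityAssignment:
    m = network.m
    k = network.snp_degrees
    d = network.gene_degrees
    snps = sorted(network.snp_nodes)
    genes = sorted(network.gene_nodes)

    def sweep_side(node_comm, other_comm, nodes, degrees, other_degree_sums, neighbors):
        """Reassign every node on one side to its optimal community."""
        for node in nodes:
            counts: dict[int, int] = {}
            for nb in neighbors(node):
                c = other_comm[nb]
                counts[c] = counts.get(c, 0) + 1
            current = node_comm[node]
            # score of staying/moving; an empty community scores 0
            best_c, best_score = None, 0.0
            for c in sorted(counts):
                score = counts[c] - degrees[node] * other_degree_sums.get(c, 0) / m
                if score > best_score + 1e-15:
                    best_c, best_score = c, score
                elif abs(score - best_score) <= 1e-15 and best_c is not None and c < best_c:
                    best_c = c
            cur_score = counts.get(current, 0) - degrees[node] * other_degree_sums.get(current, 0) / m
            if best_c is None:
                new_c = _fresh_label(node_comm, other_comm) if cur_score < -1e-15 else current
            elif best_score <= cur_score + 1e-15:
                new_c = current
            else:
                new_c = best_c
            node_comm[node] = new_c

    def Q_of() -> float:
        return modularity(network, CommunityAssignment(snp_comm, gene_comm))

    def merge_phase() -> bool:
        """Greedily merge community pairs while modularity improves.

        Merging c1 and c2 changes Q by (E_between - (K1*D2 + K2*D1)/m) / m.
        """
        improved = False
        while True:
            K = _degree_sums(snp_comm, k)
            D = _degree_sums(gene_comm, d)
            E_between: dict[tuple[int, int], int] = {}
            for s, g in network.edges:
                c1, c2 = snp_comm[s], gene_comm[g]
                if c1 != c2:
                    key = (min(c1, c2), max(c1, c2))
                    E_between[key] = E_between.get(key, 0) + 1
            best_gain, best_pair = tol, None
            for (c1, c2), e in E_between.items():
                gain = (e - (K.get(c1, 0) * D.get(c2, 0) + K.get(c2, 0) * D.get(c1, 0)) / m) / m
                if gain > best_gain:
                    best_gain, best_pair = gain, (c1, c2)
            if best_pair is None:
                return improved
            c1, c2 = best_pair
            for node, c in list(snp_comm.items()):
                if c == c2:
                    snp_comm[node] = c1
            for node, c in list(gene_comm.items()):
                if c == c2:
                    gene_comm[node] = c1
            improved = True

    prev_Q = Q_of()
    converged = False
    for _ in range(max_iter):
        D_sums = _degree_sums(gene_comm, d)
        sweep_side(snp_comm, gene_comm, snps, k, D_sums, network.genes_of)
        K_sums = _degree_sums(snp_comm, k)
        sweep_side(gene_comm, snp_comm, genes, d, K_sums, network.snps_of)
        merged = merge_phase()
        Q = Q_of()
        if Q - prev_Q < tol and not merged:
            converged = True
            prev_Q = max(prev_Q, Q)
            break
        prev_Q = Q
    if not converged:
        logger.warning("detect_communities: not converged after %d iterations", max_iter)
    snp_comm, gene_comm = _refine_gene_partition(network, gene_comm, tol)
    out = CommunityAssignment(dict(snp_comm), dict(gene_comm), converged=converged).compact()
    out.modularity = modularity(network, out)
    return out


def _refine_gene_partition(network: BipartiteNetwork, gene_comm: dict,
                           tol: float = 1e-10) -> tuple[dict, dict]:
    """Exact local search over gene-side partitions.

    For a fixed gene partition the optimal SNP labels are closed-form (each
    SNP takes argmax_c e_ic - k_i D_c / m, or a singleton when every term is
    negative), so modularity is a function of the gene partition alone.
    This phase greedily applies single-gene moves and whole-community merges
    scored under that exact objective, escaping the local optima that
    single-node sweeps cannot leave (they hold the other side fixed).
    Returns the refined (snp_comm, gene_comm).
    """
    m = network.m
    k = network.snp_degrees
    d = network.gene_degrees
    snps = sorted(network.snp_nodes)
    genes = sorted(network.gene_nodes)
    gene_comm = dict(gene_comm)

    # state: per-SNP edge counts into each community, community degree sums,
    # per-SNP optimal term, and which SNPs touch each community
    e: dict[str, dict[int, int]] = {s: {} for s in snps}
    D: dict[int, int] = {}
    members: dict[int, set[str]] = {}
    for g in genes:
        c = gene_comm[g]
        D[c] = D.get(c, 0) + d[g]
    for s, g in network.edges:
        c = gene_comm[g]
        e[s][c] = e[s].get(c, 0) + 1
        members.setdefault(c, set()).add(s)

    def term(s: str, D_over: dict[int, int]) -> float:
        best = 0.0
        for c, cnt in e[s].items():
            if cnt > 0:
                best = max(best, cnt - k[s] * D_over.get(c, D.get(c, 0)) / m)
        return best

    t = {s: term(s, {}) for s in snps}

    def _move_counts(gs: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in gs:
            for s in network.snps_of(g):
                counts[s] = counts.get(s, 0) + 1
        return counts

    def delta_move(gs: list[str], a: int, b: int) -> float:
        """Gain of moving genes ``gs`` (all in community a) to b (b may be fresh)."""
        d_tot = sum(d[g] for g in gs)
        D_over = {a: D.get(a, 0) - d_tot, b: D.get(b, 0) + d_tot}
        moved = _move_counts(gs)
        affected = members.get(a, set()) | members.get(b, set()) | moved.keys()
        gain = 0.0
        for s in affected:
            cnt = moved.get(s, 0)
            if cnt:
                e[s][a] = e[s].get(a, 0) - cnt
                e[s][b] = e[s].get(b, 0) + cnt
            gain += term(s, D_over) - t[s]
            if cnt:
                e[s][a] += cnt
                e[s][b] -= cnt
        return gain / m

    def apply_move(gs: list[str], a: int, b: int) -> None:
        d_tot = sum(d[g] for g in gs)
        D_over = {a: D.get(a, 0) - d_tot, b: D.get(b, 0) + d_tot}
        moved = _move_counts(gs)
        affected = members.get(a, set()) | members.get(b, set()) | moved.keys()
        for s, cnt in moved.items():
            e[s][a] = e[s].get(a, 0) - cnt
            if e[s][a] == 0:
                del e[s][a]
                members.setdefault(a, set()).discard(s)
            e[s][b] = e[s].get(b, 0) + cnt
            members.setdefault(b, set()).add(s)
        D[a] = D_over[a]
        D[b] = D_over[b]
        if D[a] == 0:
            D.pop(a)
            members.pop(a, None)
        for g in gs:
            gene_comm[g] = b
        for s in affected:
            t[s] = term(s, {})

    def delta_merge(a: int, b: int) -> float:
        """Gain of merging community b into a."""
        D_over = {a: D.get(a, 0) + D.get(b, 0), b: 0}
        gain = 0.0
        affected = members.get(a, set()) | members.get(b, set())
        for s in affected:
            ea, eb = e[s].get(a, 0), e[s].get(b, 0)
            best = 0.0
            for c, cnt in e[s].items():
                if c in (a, b) or cnt <= 0:
                    continue
                best = max(best, cnt - k[s] * D.get(c, 0) / m)
            if ea + eb > 0:
                best = max(best, ea + eb - k[s] * D_over[a] / m)
            gain += best - t[s]
        return gain / m

    def apply_merge(a: int, b: int) -> None:
        for g in [g for g, c in gene_comm.items() if c == b]:
            gene_comm[g] = a
        for s in members.get(b, set()).copy():
            e[s][a] = e[s].get(a, 0) + e[s].pop(b, 0)
            members.setdefault(a, set()).add(s)
        members.pop(b, None)
        D[a] = D.get(a, 0) + D.pop(b, 0)
        for s in members.get(a, set()):
            t[s] = term(s, {})

    fresh = max(gene_comm.values(), default=0)

    def single_and_merge_round() -> bool:
        nonlocal fresh
        improved = False
        # single-gene moves
        for g in genes:
            a = gene_comm[g]
            best_gain, best_b = tol, None
            candidates = sorted(c for c in D if c != a)
            if D.get(a, 0) > d[g]:  # moving out leaves a non-empty; fresh target sensible
                candidates.append(fresh + 1)
            for b in candidates:
                gain = delta_move([g], a, b)
                if gain > best_gain + 1e-15:
                    best_gain, best_b = gain, b
            if best_b is not None:
                if best_b == fresh + 1:
                    fresh += 1
                apply_move([g], a, best_b)
                improved = True
        # community merges
        while True:
            comms = sorted(D)
            best_gain, best_pair = tol, None
            for i in range(len(comms)):
                for j in range(i + 1, len(comms)):
                    gain = delta_merge(comms[i], comms[j])
                    if gain > best_gain + 1e-15:
                        best_gain, best_pair = gain, (comms[i], comms[j])
            if best_pair is None:
                break
            apply_merge(*best_pair)
            improved = True
        return improved

    def pair_move_round() -> bool:
        """Coordinated moves of two same-community genes that share a SNP —
        escapes optima where each single move is individually losing."""
        nonlocal fresh
        improved = False
        for g1 in genes:
            a = gene_comm[g1]
            partners = sorted({g2 for s in network.snps_of(g1) for g2 in network.genes_of(s)
                               if g2 > g1 and gene_comm[g2] == a})
            for g2 in partners:
                best_gain, best_b = tol, None
                candidates = sorted(c for c in D if c != a)
                if D.get(a, 0) > d[g1] + d[g2]:
                    candidates.append(fresh + 1)
                for b in candidates:
                    gain = delta_move([g1, g2], a, b)
                    if gain > best_gain + 1e-15:
                        best_gain, best_b = gain, b
                if best_b is not None:
                    if best_b == fresh + 1:
                        fresh += 1
                    apply_move([g1, g2], a, best_b)
                    improved = True
                    a = gene_comm[g1]
        return improved

    def delta_swap(g1: str, g2: str) -> float:
        """Gain of exchanging g1 and g2 between their communities."""
        a, b = gene_comm[g1], gene_comm[g2]
        D_over = {a: D.get(a, 0) - d[g1] + d[g2], b: D.get(b, 0) - d[g2] + d[g1]}
        m1, m2 = _move_counts([g1]), _move_counts([g2])
        affected = members.get(a, set()) | members.get(b, set()) | m1.keys() | m2.keys()
        gain = 0.0
        for s in affected:
            c1, c2 = m1.get(s, 0), m2.get(s, 0)
            if c1 or c2:
                e[s][a] = e[s].get(a, 0) - c1 + c2
                e[s][b] = e[s].get(b, 0) - c2 + c1
            gain += term(s, D_over) - t[s]
            if c1 or c2:
                e[s][a] += c1 - c2
                e[s][b] += c2 - c1
        return gain / m

    def swap_round() -> bool:
        """Exchange pairs of SNP-sharing genes across communities."""
        improved = False
        for g1 in genes:
            partners = sorted({g2 for s in network.snps_of(g1) for g2 in network.genes_of(s)
                               if g2 > g1 and gene_comm[g2] != gene_comm[g1]})
            for g2 in partners:
                if delta_swap(g1, g2) > tol + 1e-15:
                    a, b = gene_comm[g1], gene_comm[g2]
                    apply_move([g1], a, b)
                    apply_move([g2], b, a)
                    improved = True
        return improved

    for _ in range(200):
        improved = single_and_merge_round()
        if not improved:
            improved = pair_move_round() or swap_round()
        if not improved:
            break

    # closed-form SNP labels for the final gene partition
    snp_comm = {}
    for s in snps:
        best_c, best_score = None, 0.0
        for c in sorted(e[s]):
            if e[s][c] <= 0:
                continue
            score = e[s][c] - k[s] * D.get(c, 0) / m
            if best_c is None or score > best_score + 1e-15:
                best_c, best_score = c, score
        if best_c is None or best_score < -1e-15:
            fresh += 1
            best_c = fresh
        snp_comm[s] = best_c
    return snp_comm, gene_comm


def _degree_sums(comm: dict[str, int], degrees: dict[str, int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for node, c in comm.items():
        out[c] = out.get(c, 0) + degrees[node]
    return out


def _fresh_label(a: dict[str, int], b: dict[str, int]) -> int:
    return max(list(a.values()) + list(b.values()), default=0) + 1


# ---------------------------------------------------------------------------
# core scores
# ---------------------------------------------------------------------------

def core_scores(network: BipartiteNetwork, assignment: CommunityAssignment) -> pd.DataFrame:
    """Per-SNP modularity contribution Q_ih to its own community.

    Returns a DataFrame indexed by snp_id with columns ``core_score`` and
    ``community``.  Summing ``core_score`` over all SNPs reproduces the
    assignment's modularity exactly.
    """
    m = network.m
    gene_c = assignment.gene_community
    D_sums = _degree_sums(gene_c, network.gene_degrees)
    rows = []
    for snp in sorted(network.snp_nodes):
        h = assignment.snp_community[snp]
        e_ih = sum(1 for g in network.genes_of(snp) if gene_c[g] == h)
        score = (e_ih - network.snp_degree(snp) * D_sums.get(h, 0) / m) / m
        rows.append((snp, score, h))
    return pd.DataFrame(rows, columns=["snp_id", "core_score", "community"]).set_index("snp_id")
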