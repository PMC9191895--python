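"""Similarity network construction and Louvain community selection.

Candidates are linked whenever their local-alignment percent identity
exceeds a threshold (strictly above, mirroring the published "above 20%" /
"above 50%" rules); communities are resolved by two-phase Louvain
modularity optimisation, and only communities containing at least one
seed sequence are kept as family candidates.

The Louvain implementation is deterministic under a seed (node order is a
seeded shuffle) and the modularity it reports is exactly the weighted
Newman–Girvan Q recomputable with :func:`modularity`.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .align import DEFAULT_SCHEME, ScoringScheme, local_align
from .famfilter import CandidateSet
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: default raw-score gate for network edges; plays the role of the search
#: significance cutoff applied before identities are thresholded
EDGE_MIN_SCORE = 50.0


@dataclass
class Partition:
    """Node -> community assignment with its modularity Q.

    ``q_trace`` records Q after each completed Louvain pass (local moves +
    aggregation); it is non-decreasing by construction.
    """

    communities: dict[str, int]
    q: float
    q_trace: list[float] = field(default_factory=list)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.communities.items():
            out.setdefault(c, []).append(node)
        return out


def build_similarity_graph(candidates: Sequence[SequenceRecord],
                           scheme: ScoringScheme = DEFAULT_SCHEME,
                           threshold_pct: float = 20.0,
                           min_score: float = EDGE_MIN_SCORE) -> nx.Graph:
    """All-vs-all local alignment network thresholded on percent identity.

    An edge (u, v) exists iff pct_identity > ``threshold_pct`` (strict)
    and the raw alignment score reaches ``min_score``; the edge weight is
    the percent identity.  Isolated nodes are retained.
    """
    if not candidates:
        raise ValueError("no candidates to build a network from")
    g = nx.Graph()
    for rec in candidates:
        g.add_node(rec.id)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            aln = local_align(candidates[i], candidates[j], scheme)
            if aln.is_empty:
                continue
            if aln.pct_identity > threshold_pct and aln.score >= min_score:
                g.add_edge(candidates[i].id, candidates[j].id,
                           weight=aln.pct_identity)
    return g


def modularity(graph: nx.Graph, communities: dict[str, int]) -> float:
    """Weighted Newman–Girvan modularity of a full partition.

    ``Q = sum_c [ S_in,c / (2m) - (S_tot,c / (2m))^2 ]`` where ``S_in,c``
    is twice the intra-community edge weight and ``S_tot,c`` the summed
    (weighted) degree of community c.
    """
    missing = set(graph.nodes) - set(communities)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]}")
    m2 = 2.0 * graph.size(weight="weight")
    if m2 == 0:
        return 0.0
    s_in: dict[int, float] = {}
    s_tot: dict[int, float] = {}
    for node in graph.nodes:
        c = communities[node]
        s_tot[c] = s_tot.get(c, 0.0) + graph.degree(node, weight="weight")
        s_in.setdefault(c, 0.0)
    for u, v, w in graph.edges(data="weight", default=1.0):
        if communities[u] == communities[v]:
            s_in[communities[u]] += 2.0 * w
    return sum(s_in[c] / m2 - (s_tot[c] / m2) ** 2 for c in s_tot)


def _one_level(nodes: list, adj: dict, degrees: dict, m2: float,
               rng: random.Random) -> tuple[dict, bool]:
    """One Louvain local-move phase; returns (assignment, improved)."""
    comm = {n: n for n in nodes}
    c_tot = {n: degrees[n] for n in nodes}
    improved = False
    moved = True
    while moved:
        moved = False
        order = nodes[:]
        rng.shuffle(order)
        for node in order:
            c_old = comm[node]
            k_i = degrees[node]
            # weights from node into each neighbouring community
            links: dict = {}
            for nb, w in adj[node].items():
                if nb != node:
                    links[comm[nb]] = links.get(comm[nb], 0.0) + w
            c_tot[c_old] -= k_i
            comm[node] = None
            best_c, best_gain = c_old, links.get(c_old, 0.0) - c_tot[c_old] * k_i / m2
            for c, w_in in links.items():
                gain = w_in - c_tot[c] * k_i / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm[node] = best_c
            c_tot[best_c] += k_i
            if best_c != c_old:
                moved = True
                improved = True
    return comm, improved


def louvain(graph: nx.Graph, rng_seed: int = 0, resolution: float = 1.0) -> Partition:
    """Two-phase Louvain modularity optimisation.

    Local moves in seeded-shuffled node order until no single move
    improves Q, then community aggregation; the outer loop repeats until
    the Q gain falls below 1e-12.  The returned Q equals
    ``modularity(graph, partition)`` exactly.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolution != 1.0:
        raise NotImplementedError("only resolution 1 is supported")
    rng = random.Random(rng_seed)
    m2 = 2.0 * graph.size(weight="weight")
    assignment = {n: i for i, n in enumerate(graph.nodes)}
    if m2 == 0:
        return Partition(communities=assignment, q=0.0)

    # current coarse graph state: node -> (adjacency with weights), degree
    nodes = list(graph.nodes)
    adj = {n: {} for n in nodes}
    for u, v, w in graph.edges(data="weight", default=1.0):
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    degrees = {n: sum(adj[n].values()) for n in nodes}
    self_loops = {n: 0.0 for n in nodes}
    membership = {n: n for n in graph.nodes}  # original node -> coarse node

    prev_q = modularity(graph, {n: assignment[membership[n]] for n in graph.nodes})
    q_trace = [prev_q]
    while True:
        comm, improved = _one_level(nodes, adj, degrees, m2, rng)
        if not improved:
            break
        # aggregate communities into a coarse graph
        relabel = {c: i for i, c in enumerate(sorted(set(comm.values()), key=str))}
        new_nodes = sorted(relabel.values())
        new_adj = {n: {} for n in new_nodes}
        new_self = {n: 0.0 for n in new_nodes}
        for u in nodes:
            cu = relabel[comm[u]]
            new_self[cu] += self_loops[u]
            for v, w in adj[u].items():
                cv = relabel[comm[v]]
                if cu == cv:
                    new_self[cu] += w / 2.0 if u != v else 0.0
                else:
                    new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
        # degrees include twice the internal weight
        new_deg = {
            n: sum(new_adj[n].values()) + 2.0 * new_self[n] for n in new_nodes
        }
        membership = {orig: relabel[comm[membership[orig]]]
                      for orig in membership}
        nodes, adj, degrees, self_loops = new_nodes, new_adj, new_deg, new_self
        # adjacency for local moves must see internal weight via degrees only
        cur = {n: membership[n] for n in graph.nodes}
        q = modularity(graph, cur)
        q_trace.append(q)
        if q - prev_q < 1e-12:
            break
        prev_q = q
        if len(nodes) == 1:
            break
    final = {n: membership[n] for n in graph.nodes}
    relabel = {c: i for i, c in enumerate(sorted(set(final.values()), key=str))}
    final = {n: relabel[c] for n, c in final.items()}
    return Partition(communities=final, q=modularity(graph, final),
                     q_trace=q_trace)


def select_seed_communities(partition: Partition,
                            seed_ids: Iterable[str],
                            candidates: Sequence[SequenceRecord]) -> CandidateSet:
    """Union of all communities containing at least one seed.

    Seeds absent from the graph are logged and ignored; if none is
    present the family hypothesis is empty and an error is raised.
    """
    seed_ids = list(seed_ids)
    present = [s for s in seed_ids if s in partition.communities]
    for s in set(seed_ids) - set(present):
        logger.warning("seed %r not in graph; ignored", s)
    if not present:
        raise ValueError("no seed sequence present in the similarity graph")
    keep = {partition.communities[s] for s in present}
    members = [rec for rec in candidates
               if partition.communities.get(rec.id) in keep]
    return CandidateSet(
        stage="relaxed", members=members,
        provenance={m.id: m.source for m in members},
    )
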