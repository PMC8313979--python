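"""Bipartite TF–glycogene networks, TF projection and community detection.

Each cancer type's retained edges form a bipartite graph with TF and
glycogene node classes.  Projecting onto the TF side connects two TFs by an
edge weighted with the number of glycogene targets they share.  Communities
are found on that weighted projection by agglomerative greedy modularity
maximization (Clauset–Newman–Moore): starting from singleton communities,
repeatedly merge the connected pair with the largest modularity gain while a
positive gain exists.  Ties are broken on the lexicographically smallest
community-id pair, making the partition deterministic.  Glycogenes are then
attached to the TF community that holds the plurality of their regulators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from networkx.algorithms import bipartite as nx_bipartite
from networkx.algorithms import community as nx_community

from .errors import DomainError, ValidationError
from .filtering import binding_potential
from .ingest import PathwayClassification, TFGeneRecord
from . import enrichment as _enrichment


def build_bipartite(edges: Sequence[TFGeneRecord]) -> nx.Graph:
    """Bipartite graph of one cancer's retained edges.

    TF nodes carry ``kind="tf"`` (bipartite=0), gene nodes ``kind="glycogene"``
    (bipartite=1); edges carry rp, rho and bp attributes.  The graph's
    ``cancer`` attribute records the cancer code.
    """
    cancers = sorted({e.cancer for e in edges})
    if len(cancers) > 1:
        raise DomainError(f"edges span multiple cancers: {cancers}")
    g = nx.Graph(cancer=cancers[0] if cancers else None)
    tfs = sorted({e.tf for e in edges})
    genes = sorted({e.gene for e in edges})
    overlap = set(tfs) & set(genes)
    if overlap:
        raise ValidationError(f"symbols appear as both TF and gene: {sorted(overlap)}")
    g.add_nodes_from(tfs, kind="tf", bipartite=0)
    g.add_nodes_from(genes, kind="glycogene", bipartite=1)
    for e in sorted(edges, key=lambda r: (r.tf, r.gene)):
        g.add_edge(e.tf, e.gene, rp=e.rp, rho=e.rho, bp=binding_potential(e.rp, e.rho))
    return g


def tf_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "tf")


def gene_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "glycogene")


def project_tf_graph(network: nx.Graph) -> nx.Graph:
    """Weighted one-mode projection onto TFs.

    TFs are connected iff they share at least one glycogene target; the edge
    weight is the shared-target count.
    """
    tfs = tf_nodes(network)
    proj = nx_bipartite.weighted_projected_graph(network, tfs)
    out = nx.Graph(cancer=network.graph.get("cancer"))
    out.add_nodes_from(sorted(proj.nodes()))
    for u, v, d in sorted(proj.edges(data=True)):
        out.add_edge(u, v, weight=int(d["weight"]))
    return out


def modularity(graph: nx.Graph, partition: Sequence[Iterable[str]]) -> float:
    """Newman weighted modularity Q of a node partition.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j); zero-edge
    graphs return 0 by convention.
    """
    communities = [frozenset(c) for c in partition]
    covered: set[str] = set()
    for c in communities:
        if covered & c:
            raise DomainError("partition has overlapping communities")
        covered |= c
    if covered != set(graph.nodes()):
        raise DomainError("partition does not cover the node set exactly")
    if graph.number_of_edges() == 0:
        return 0.0
    return float(nx_community.modularity(graph, communities, weight="weight"))


def greedy_modularity_communities(graph: nx.Graph) -> list[frozenset[str]]:
    """Deterministic CNM greedy modularity partition of a weighted graph.

    Starts with singleton communities and repeatedly merges the pair of
    (connected) communities with the maximal modularity gain while a strictly
    positive gain exists; modularity increases at every step so the stopping
    partition is the max-Q cut of the merge path.  Gain ties are resolved by
    the lexicographically smallest (id, id) pair, where a community's id is
    its smallest member label.  Returned communities are sorted by
    (descending size, smallest member).
    """
    if graph.number_of_nodes() == 0:
        return []
    nodes = sorted(graph.nodes())
    if graph.number_of_edges() == 0:
        return [frozenset([n]) for n in nodes]

    m2 = 2.0 * sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    members: dict[str, set[str]] = {n: {n} for n in nodes}
    # a[c]: community's weighted-degree fraction; e[(ci,cj)]: between-weight fraction
    a = {n: graph.degree(n, weight="weight") / m2 for n in nodes}
    e: dict[tuple[str, str], float] = {}
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        key = (u, v) if u < v else (v, u)
        e[key] = e.get(key, 0.0) + d.get("weight", 1) / m2

    while True:
        best_pair = None
        best_dq = 0.0
        for (ci, cj), eij in sorted(e.items()):
            dq = 2.0 * (eij - a[ci] * a[cj])
            if dq > best_dq + 1e-15 or (
                best_pair is not None and abs(dq - best_dq) <= 1e-15 and (ci, cj) < best_pair
            ):
                best_dq = dq
                best_pair = (ci, cj)
        if best_pair is None or best_dq <= 1e-15:
            break
        ci, cj = best_pair  # merge cj into ci (ci < cj)
        members[ci] |= members.pop(cj)
        a[ci] += a.pop(cj)
        e.pop((ci, cj))
        # rewire cj's links onto ci
        for key in list(e):
            if cj in key:
                other = key[0] if key[1] == cj else key[1]
                w = e.pop(key)
                if other == ci:
                    continue
                nk = (ci, other) if ci < other else (other, ci)
                e[nk] = e.get(nk, 0.0) + w

    return sorted((frozenset(c) for c in members.values()), key=lambda c: (-len(c), min(c)))


@dataclass(frozen=True)
class Community:
    id: int
    tfs: frozenset[str]
    genes: frozenset[str]


@dataclass(frozen=True)
class CommunitySet:
    """A cancer's TF partition with attached glycogenes and its modularity Q."""

    cancer: str
    communities: tuple[Community, ...]
    modularity: float

    def community_of_tf(self, tf: str) -> int:
        for c in self.communities:
            if tf in c.tfs:
                return c.id
        raise KeyError(tf)

    def large(self, min_tfs: int = 5) -> tuple[Community, ...]:
        return tuple(c for c in self.communities if len(c.tfs) >= min_tfs)

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.communities:
            rows += [(self.cancer, c.id, t, "tf") for t in sorted(c.tfs)]
            rows += [(self.cancer, c.id, g, "glycogene") for g in sorted(c.genes)]
        return pd.DataFrame(rows, columns=["cancer", "community", "symbol", "kind"])


def assign_glycogenes(partition: Sequence[frozenset[str]], network: nx.Graph) -> CommunitySet:
    """Attach each glycogene to the community holding most of its regulators.

    Ties go to the community with the larger total BP toward the gene, then
    to the smaller community id.  Community ids are 1-based in descending
    TF-set size order.
    """
    tfs = set(tf_nodes(network))
    covered = set().union(*partition) if partition else set()
    if covered != tfs:
        raise DomainError("partition does not cover the network's TF nodes exactly")
    ordered = sorted((frozenset(c) for c in partition), key=lambda c: (-len(c), min(c)))
    comm_of: dict[str, int] = {}
    for idx, comm in enumerate(ordered, start=1):
        for tf in comm:
            comm_of[tf] = idx

    genes_by_comm: dict[int, set[str]] = {i: set() for i in range(1, len(ordered) + 1)}
    for gene in gene_nodes(network):
        votes: dict[int, int] = {}
        bp_sum: dict[int, float] = {}
        for tf in network.neighbors(gene):
            cid = comm_of[tf]
            votes[cid] = votes.get(cid, 0) + 1
            bp_sum[cid] = bp_sum.get(cid, 0.0) + network.edges[tf, gene]["bp"]
        winner = min(votes, key=lambda cid: (-votes[cid], -bp_sum[cid], cid))
        genes_by_comm[winner].add(gene)

    proj = project_tf_graph(network)
    q = modularity(proj, ordered) if proj.number_of_nodes() else 0.0
    communities = tuple(
        Community(id=i, tfs=comm, genes=frozenset(genes_by_comm[i]))
        for i, comm in enumerate(ordered, start=1)
    )
    return CommunitySet(cancer=network.graph.get("cancer") or "", communities=communities, modularity=q)


def detect_communities(edges: Sequence[TFGeneRecord]) -> CommunitySet:
    """Full per-cancer community pipeline: bipartite -> projection -> CNM -> assignment."""
    network = build_bipartite(edges)
    proj = project_tf_graph(network)
    partition = greedy_modularity_communities(proj)
    return assign_glycogenes(partition, network)


def community_glyco_enrichment(
    community: Community,
    edges: Sequence[TFGeneRecord],
    classification: PathwayClassification,
) -> pd.DataFrame:
    """Pathway overrepresentation of one community's edges vs the cancer background.

    For each pathway, a one-sided Fisher test of (community edges in pathway)
    against all retained edges of the cancer; BH correction across the
    pathways tested for this community.
    """
    cancers = {e.cancer for e in edges}
    if len(cancers) > 1:
        raise DomainError(f"edges span multiple cancers: {sorted(cancers)}")
    if not community.tfs:
        return pd.DataFrame(columns=["pathway", "a", "b", "c", "d", "p", "p_adj"])
    N = len(edges)
    inside = [e for e in edges if e.tf in community.tfs]
    n = len(inside)
    rows = []
    for pathway in sorted(classification.pathways):
        K = sum(1 for e in edges if pathway in classification.pathways_of(e.gene))
        a = sum(1 for e in inside if pathway in classification.pathways_of(e.gene))
        p = _enrichment.hypergeometric_tail(a, K, n, N)
        rows.append((pathway, a, n - a, K - a, N - n - (K - a), p))
    df = pd.DataFrame(rows, columns=["pathway", "a", "b", "c", "d", "p"])
    df["p_adj"] = _enrichment.benjamini_hochberg(df["p"].to_numpy())
    return df


def export_graphml(network: nx.Graph, path: str | Path, community_set: CommunitySet | None = None) -> None:
    """GraphML export with node kind/community and edge rp/rho/bp attributes."""
    g = network.copy()
    if community_set is not None:
        lookup: dict[str, int] = {}
        for c in community_set.communities:
            for s in c.tfs | c.genes:
                lookup[s] = c.id
        for node in g.nodes():
            g.nodes[node]["community"] = lookup.get(node, 0)
    if g.graph.get("cancer") is None:
        g.graph.pop("cancer", None)
    nx.write_graphml(g, str(path), named_key_ids=True)


def export_sif(network: nx.Graph, path: str | Path, relation: str = "regulates") -> None:
    """Cytoscape SIF export (tf<TAB>relation<TAB>gene), sorted for determinism."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            tf, gene = (u, v) if network.nodes[u].get("kind") == "tf" else (v, u)
            fh.write(f"{tf}\t{relation}\t{gene}\n")
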