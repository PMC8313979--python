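"""Independent brute-force oracles shared by the network tests."""

import itertools

from networkx.algorithms.community import modularity as nx_modularity


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def brute_force_max_modularity(graph):
    """(best Q, best partition) by exhaustive search; graphs of <= ~8 nodes only."""
    best_q, best_part = float("-inf"), None
    for part in set_partitions(sorted(graph.nodes())):
        q = nx_modularity(graph, [frozenset(c) for c in part], weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return best_q, [frozenset(c) for c in best_part]


def random_weighted_graph(rng, n_lo=3, n_hi=7, w_hi=5):
    """Erdos–Renyi graph with random integer weights, density U(0.3, 0.9)."""
    import networkx as nx

    n = int(rng.integers(n_lo, n_hi + 1))
    p = rng.uniform(0.3, 0.9)
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for u, v in itertools.combinations(sorted(g.nodes()), 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=int(rng.integers(1, w_hi + 1)))
    return g
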