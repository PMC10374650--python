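"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take a different route than the package: topology terms
come from networkx path/combination enumeration over an adjacency copy, and
pair separations from networkx shortest paths.
"""

import itertools

import networkx as nx


def _graph(sg):
    g = nx.Graph()
    g.add_nodes_from(range(len(sg.sites)))
    g.add_edges_from((i, j) for i, j, _ in sg.bonds)
    return g


def brute_force_terms(sg):
    """Sets of canonical site tuples per term kind, by exhaustive search."""
    g = _graph(sg)
    n = g.number_of_nodes()

    def canon(path):
        return min(tuple(path), tuple(reversed(path)))

    bonds = {canon(e) for e in g.edges}
    angles, torsions = set(), set()
    for a in range(n):
        for b in range(n):
            if a >= b:
                continue
            for path in nx.all_simple_paths(g, a, b, cutoff=3):
                if len(path) == 3:
                    angles.add(canon(path))
                elif len(path) == 4:
                    torsions.add(canon(path))
    impropers = set()
    for c in range(n):
        nbrs = sorted(g.neighbors(c))
        if len(nbrs) >= 3:
            for trio in itertools.combinations(nbrs, 3):
                impropers.add((c, *trio))
    return {
        "bond": bonds,
        "angle": angles,
        "torsion": torsions,
        "improper": impropers,
    }


def shortest_separations(sg):
    """{(i, j): bond-count distance} over all site pairs, i < j."""
    g = _graph(sg)
    dists = dict(nx.all_pairs_shortest_path_length(g))
    return {
        (i, j): dists[i][j]
        for i in range(len(sg.sites))
        for j in range(i + 1, len(sg.sites))
        if j in dists.get(i, {})
    }
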