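"""Weighted co-occurrence network and Louvain module detection.

The network is the complete weighted graph over species, with Sørensen
co-occurrence similarity as edge weight; zero-weight pairs carry no edge and
self-loops are excluded.  Modules are found by greedy Louvain optimization
of the weighted Newman modularity

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

where A_ij is the edge weight, k_i the node strength and m the total edge
weight.  The Louvain pass order is seeded, and multiple seeded restarts are
run with the best-Q partition kept, so results are reproducible for a fixed
(graph, seed) pair.  Isolated nodes end up as singleton modules — joining
any module cannot raise Q.
"""

from __future__ import annotations

import csv
from pathlib import Path
import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities

from .functional_modules import Partition, _contiguous
from .similarity import SimilarityMatrix


def build_graph(csim: SimilarityMatrix) -> nx.Graph:
    """Complete weighted graph from a co-occurrence similarity matrix.

    All species become nodes (a species with zero similarity to every other
    species is retained as an isolated node); only strictly positive
    off-diagonal weights become edges.
    """
    g = nx.Graph()
    g.add_nodes_from(csim.species)
    vals = csim.values
    n = csim.n_species
    for i in range(n):
        for j in range(i + 1, n):
            w = float(vals[i, j])
            if w > 0.0:
                g.add_edge(csim.species[i], csim.species[j], weight=w)
    return g


def modularity(g: nx.Graph, partition: Partition) -> float:
    """Weighted Newman modularity Q of a partition; pure recomputation."""
    if set(g.nodes) != set(partition.species):
        raise ValueError("partition and graph cover different species")
    m = g.size(weight="weight")
    if m <= 0.0:
        raise ValueError("graph has zero total weight; no structure to score")
    strength = dict(g.degree(weight="weight"))
    intra = {}
    for u, v, w in g.edges(data="weight"):
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    q = 0.0
    for c in range(partition.n_modules):
        k_c = sum(strength[s] for s, lab in partition.assignment.items() if lab == c)
        q += intra.get(c, 0.0) / m - (k_c / (2.0 * m)) ** 2
    return q


def louvain_modules(g: nx.Graph, seed: int = 0, restarts: int = 10) -> Partition:
    """Louvain community detection, best of ``restarts`` seeded runs.

    Returns a co-occurrence Partition whose ``modularity`` attribute is the
    achieved Q, recomputable exactly with :func:`modularity`.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes for module detection")
    if g.size(weight="weight") <= 0.0:
        raise ValueError("graph has zero total weight; no structure to optimize")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    nodes = list(g.nodes)
    child_seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best: Partition | None = None
    for s in child_seeds:
        comms = louvain_communities(g, weight="weight", resolution=1.0, seed=int(s % (2**31)))
        raw = {}
        for lab, comm in enumerate(comms):
            for sp in comm:
                raw[sp] = lab
        part = Partition(_contiguous(nodes, [raw[s_] for s_ in nodes]), "cooccurrence")
        q = modularity(g, part)
        part = Partition(part.assignment, "cooccurrence", modularity=q)
        if best is None or q > best.modularity:
            best = part
    return best


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Export the weighted graph as a source,target,weight CSV."""
    with open(Path(path), "w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(["source", "target", "weight"])
        for u, v, w in g.edges(data="weight"):
            out.writerow([u, v, repr(w)])
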