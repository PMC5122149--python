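"""Independent reference computations used to validate the inference code.

Nothing here is called by the inference path: these are brute-force or
closed-form oracles (exhaustive topology enumeration, ordinary-least-squares
scoring, patristic distances via dendropy) against which the package's own
algorithms are checked.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def random_unrooted_tree(labels: list[str], rng: np.random.Generator,
                         blmin: float = 0.05, blmax: float = 1.0
                         ) -> dendropy.Tree:
    """Random unrooted binary topology (sequential random joins) with
    i.i.d. uniform branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(lb)) for lb in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = dendropy.Node()
        p.add_child(nodes[i])
        p.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [p]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node:
            e.length = float(rng.uniform(blmin, blmax))
    return tree


def patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix, in ``labels`` order."""
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
            D[i, j] = D[j, i] = d
    return D


def all_unrooted_topologies(labels: list[str]) -> list[str]:
    """Every unrooted binary topology on ``labels`` as newick strings,
    built by stepwise insertion into each edge ((2n-5)!! trees)."""

    def grow(newicks: list[str], lb: str) -> list[str]:
        out = []
        for nwk in newicks:
            probe = dendropy.Tree.get(
                data=nwk, schema="newick",
                taxon_namespace=dendropy.TaxonNamespace())
            n_edges = sum(1 for e in probe.preorder_edge_iter()
                          if e.head_node is not probe.seed_node)
            for k in range(n_edges):
                t = dendropy.Tree.get(
                    data=nwk, schema="newick",
                    taxon_namespace=dendropy.TaxonNamespace())
                edge = [e for e in t.preorder_edge_iter()
                        if e.head_node is not t.seed_node][k]
                head = edge.head_node
                parent = head.parent_node
                mid = dendropy.Node()
                parent.remove_child(head)
                parent.add_child(mid)
                mid.add_child(head)
                mid.add_child(dendropy.Node(
                    taxon=t.taxon_namespace.new_taxon(lb)))
                out.append(t.as_string(schema="newick").strip())
        return out

    newicks = [f"({labels[0]},{labels[1]},{labels[2]});"]
    for lb in labels[3:]:
        newicks = grow(newicks, lb)
    return newicks


def ols_rss(newick: str, labels: list[str], D: np.ndarray) -> float:
    """Residual sum of squares of the unconstrained OLS branch-length fit
    of distance matrix ``D`` on the given topology."""
    t = dendropy.Tree.get(data=newick, schema="newick",
                          taxon_namespace=dendropy.TaxonNamespace())
    t.is_rooted = False
    edges = [e for e in t.preorder_edge_iter()
             if e.head_node is not t.seed_node]
    leafsets = [frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
                for e in edges]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        d[r] = D[i, j]
        for c, ls in enumerate(leafsets):
            if (labels[i] in ls) != (labels[j] in ls):
                A[r, c] = 1.0
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - A @ b
    return float(resid @ resid)


def min_ols_topology(labels: list[str], D: np.ndarray,
                     topologies: list[str] | None = None) -> dendropy.Tree:
    """Exhaustive minimum-OLS topology search (feasible up to ~7 taxa)."""
    if topologies is None:
        topologies = all_unrooted_topologies(labels)
    best_nwk = min(topologies, key=lambda nwk: ols_rss(nwk, labels, D))
    t = dendropy.Tree.get(data=best_nwk, schema="newick",
                          taxon_namespace=dendropy.TaxonNamespace())
    t.is_rooted = False
    return t


def near_additive_matrix(labels: list[str], rng: np.random.Generator,
                         noise: float = 0.02
                         ) -> tuple[np.ndarray, dendropy.Tree]:
    """Tree-derived matrix plus uniform +/-``noise`` perturbation.

    The default noise sits inside the NJ consistency radius (half the
    minimum branch length of 0.05), the regime where NJ and exhaustive
    least-squares search are expected to agree on the topology.
    """
    tree = random_unrooted_tree(labels, rng)
    D = patristic_matrix(tree, labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = D[i, j] + float(rng.uniform(-noise, noise))
    return D, tree
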