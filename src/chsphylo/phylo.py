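"""Distance-based tree inference with bootstrap support.

Neighbor-joining over p- or Poisson-corrected protein distances, with
nonparametric bootstrap support (column resampling), outgroup rooting,
Robinson-Foulds comparison, and long-branch flagging.  Trees are
``dendropy.Tree`` objects; internal node labels carry integer bootstrap
supports in [0, 100]; bipartition supports are also kept on the tree in a
``bipartition_supports`` attribute so supports survive rerooting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .io import Alignment

TIE_EPS = 1e-12


class UndefinedDistanceError(ValueError):
    """A sequence pair with no usable shared columns (or p >= 1)."""

    def __init__(self, pair: tuple[str, str], why: str):
        self.pair = pair
        super().__init__(f"undefined distance for pair {pair}: {why}")


class OutgroupError(ValueError):
    """Outgroup not monophyletic; carries the intruding leaves."""

    def __init__(self, intruders: Sequence[str]):
        self.intruders = sorted(intruders)
        super().__init__("outgroup is not monophyletic; intruding leaves: "
                         + ", ".join(self.intruders))


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite distances")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lb, row in zip(self.labels, self.matrix):
                fh.write(lb + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")


def pairwise_distance(aln: Alignment, correction: str = "p") -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns.

    ``p``: mismatch fraction; ``poisson``: -ln(1 - p).  A pair without any
    shared column, or with p >= 1 under the poisson correction, raises
    :class:`UndefinedDistanceError` naming the pair.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    if aln.n_rows < 3:
        raise ValueError("need at least 3 rows")
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1"
                        ).reshape(aln.n_rows, aln.width)
    nongap = arr != b"-"
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                raise UndefinedDistanceError((aln.ids[i], aln.ids[j]),
                                             "no shared non-gap columns")
            p = float((arr[i, shared] != arr[j, shared]).sum()) / ns
            if correction == "poisson":
                if p >= 1.0:
                    raise UndefinedDistanceError((aln.ids[i], aln.ids[j]),
                                                 "p-distance >= 1")
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining; returns an unrooted tree.

    Tie-breaking is deterministic: among pairs minimizing the Q criterion
    within 1e-12, the lexicographically smallest cluster-label pair is
    merged (a cluster is labeled by its smallest member).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister branch
    so the path length between the joined clusters is preserved.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    D = dm.matrix.astype(float).copy()
    nodes: list[dendropy.Node] = []
    tns = dendropy.TaxonNamespace()
    for lb in dm.labels:
        nd = dendropy.Node(taxon=tns.new_taxon(lb))
        nodes.append(nd)
    cluster_labels = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a, b in np.argwhere(Q <= qmin + TIE_EPS):
            if a >= b:
                continue
            la = cluster_labels[active[a]]
            lb = cluster_labels[active[b]]
            key = tuple(sorted((la, lb)))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        vi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = vi
        nj_.edge.length = vj
        # distances from the new cluster to the others
        newd = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            newd[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        nodes.append(parent)
        cluster_labels.append(min(cluster_labels[i], cluster_labels[j]))
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    # terminal three-point join
    i, j, k = active
    center = dendropy.Node()
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, v in zip((i, j, k), (vi, vj, vk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and Robinson-Foulds


def bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions as {side, complement} frozenset pairs."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        other = leaves - below
        if len(below) >= 2 and len(other) >= 2:
            out.add(frozenset((below, other)))
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(aln: Alignment, n_reps: int = 100,
                      correction: str = "p", seed: int = 0) -> dendropy.Tree:
    """NJ reference tree with nonparametric bootstrap supports.

    Columns are resampled with replacement per replicate; each internal
    edge's support is the percentage of valid replicate trees containing
    the same bipartition.  Replicates with an undefined distance are
    discarded and counted in the tree's ``discarded_replicates`` attribute.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref = nj_tree(pairwise_distance(aln, correction))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(ref)}
    valid = 0
    discarded = 0
    for _ in range(n_reps):
        cols = rng.integers(aln.width, size=aln.width)
        rep_aln = Alignment(list(aln.ids),
                            ["".join(r[c] for c in cols) for r in aln.rows])
        try:
            rep = nj_tree(pairwise_distance(rep_aln, correction))
        except UndefinedDistanceError:
            discarded += 1
            continue
        valid += 1
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    supports = {bp: (100.0 * c / valid if valid else 0.0)
                for bp, c in counts.items()}
    annotate_supports(ref, supports)
    ref.bipartition_supports = {bp: int(round(v)) for bp, v in supports.items()}
    ref.discarded_replicates = discarded
    return ref


def annotate_supports(tree: dendropy.Tree,
                      supports: dict[frozenset, float]) -> None:
    """Write integer supports onto internal node labels by bipartition."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        bp = frozenset((below, leaves - below))
        if bp in supports:
            nd.label = str(int(round(supports[bp])))


def node_support(nd: dendropy.Node) -> int | None:
    try:
        return int(nd.label) if nd.label is not None else None
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Rooting


def root_by_outgroup(tree: dendropy.Tree,
                     outgroup_labels: Iterable[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup (midpoint
    of that edge).  Refuses with :class:`OutgroupError` if the outgroup is
    not monophyletic in the unrooted tree."""
    og = set(outgroup_labels)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = og - leaves
    if unknown:
        raise ValueError(f"unknown outgroup labels {sorted(unknown)}")
    clone = tree.clone(depth=1)
    target = None
    if len(og) == 1:
        for lf in clone.leaf_node_iter():
            if lf.taxon.label in og:
                target = lf
                break
    else:
        for nd in clone.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = {lf.taxon.label for lf in nd.leaf_iter()}
            if below == og or leaves - below == og:
                target = nd if below == og else nd
                if leaves - below == og:
                    # outgroup is "above": the complementary edge is the same
                    pass
                break
    if target is None:
        # diagnostic: smallest clade side spanning the outgroup
        best = leaves
        for nd in clone.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = {lf.taxon.label for lf in nd.leaf_iter()}
            for side in (below, leaves - below):
                if og <= side and len(side) < len(best):
                    best = side
        raise OutgroupError(sorted(best - og))
    edge = target.edge
    half = (edge.length or 0.0) / 2
    clone.reroot_at_edge(edge, length1=half, length2=half,
                         suppress_unifurcations=True)
    clone.is_rooted = True
    supports = getattr(tree, "bipartition_supports", None)
    if supports:
        annotate_supports(clone, supports)
        clone.bipartition_supports = supports
    return clone


# ---------------------------------------------------------------------------
# Long-branch flagging


def flag_long_branches(tree: dendropy.Tree, k: float = 4.0) -> list[str]:
    """Leaves whose terminal branch exceeds k times the median terminal
    branch length — candidates for long-branch-attraction exclusion."""
    leaves = [lf for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves")
    lengths = np.array([lf.edge.length or 0.0 for lf in leaves])
    med = float(np.median(lengths))
    return [lf.taxon.label for lf, ln in zip(leaves, lengths)
            if ln > k * med]
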