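"""Gene-family evolution simulator with known ground truth.

Generates the study conditions every inference stage is validated against:
an ultrametric species tree; gene families evolving along it by duplication,
loss and horizontal transfer (HGT); protein sequences with planted, immutable
catalytic motifs (D, D, D, QXXRW and QXXXY) and a tracked true alignment;
codon back-translated coding sequences whose G+C composition is steerable,
so HGT recipients can retain donor composition with tunable amelioration;
chimeric fusions duplicating the QXXXY motif; and conserved multi-gene
neighborhoods co-transferred with the focal gene.

All randomness flows from one explicitly passed integer seed through
``numpy.random.default_rng``; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io import (AMINO_ACIDS, Alignment, CodingGene, Event, NeighborhoodTable,
                 genes_to_fasta, write_alignment, write_event_log,
                 write_fasta, write_newick, write_taxon_map)
from .motifs import (QXXRW, QXXXY, MotifDefinition, find_catalytic_motifs,
                     find_motif)

OUTGROUP_GROUP = "outgroup"


# ---------------------------------------------------------------------------
# Species tree


@dataclass
class SpeciesTree:
    """Rooted binary ultrametric species tree with taxon groups.

    Node annotation ``tau`` is time from the root (root 0, all leaves at the
    tree depth); branch lengths are in expected substitutions per site.
    """

    tree: dendropy.Tree
    taxon_groups: dict[str, str]
    depth: float

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        missing = set(labels) - set(self.taxon_groups)
        if missing:
            raise ValueError(f"leaves without group: {sorted(missing)}")
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None and not nd.edge.length > 0:
                raise ValueError("non-positive branch length")
            kids = nd.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError("species tree must be binary")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


GROUP_SPLIT_FRACTION = 0.7  # group subtrees coalesce within this depth share


def _random_join(labels: Sequence[str], sub_depth: float, label_prefix: str,
                 rng: np.random.Generator, tns: dendropy.TaxonNamespace,
                 ages: dict[int, float]) -> dendropy.Node:
    """Sequential random joins at sorted uniform ages; sub-root pinned at
    ``sub_depth`` so the subtree is ultrametric with that exact height."""
    lineages = []
    for lb in labels:
        nd = dendropy.Node(taxon=tns.new_taxon(lb))
        nd.label = lb
        lineages.append(nd)
        ages[id(nd)] = 0.0
    if len(labels) == 1:
        return lineages[0]
    join_ages = np.sort(rng.uniform(0.0, sub_depth, size=len(labels) - 2))
    join_ages = np.append(join_ages, sub_depth)
    for k, age in enumerate(join_ages):
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.label = f"{label_prefix}{k + 1}"
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = age - ages[id(a)]
        b.edge.length = age - ages[id(b)]
        ages[id(parent)] = float(age)
        lineages = [nd for m, nd in enumerate(lineages) if m not in (i, j)]
        lineages.append(parent)
    return lineages[0]


def _balanced_join(labels: Sequence[str], sub_depth: float, label_prefix: str,
                   rng: np.random.Generator, tns: dendropy.TaxonNamespace,
                   ages: dict[int, float], counter: list[int]) -> dendropy.Node:
    """Cherry-rich balanced ultrametric subtree with random node ages.

    Leaves are paired into cherries and the cherries joined in a balanced
    shape, mimicking a curated reference phylogeny in which every taxon has
    a close relative; node ages shrink by a random factor per level.
    """
    if len(labels) == 1:
        nd = dendropy.Node(taxon=tns.new_taxon(labels[0]))
        nd.label = labels[0]
        ages[id(nd)] = 0.0
        return nd
    # split at an even index so terminal units are cherries, not triplets
    half = max(2, 2 * ((len(labels) // 2) // 2)) if len(labels) > 2 else 1
    counter[0] += 1
    node = dendropy.Node()
    node.label = f"{label_prefix}{counter[0]}"
    ages[id(node)] = sub_depth
    for part in (labels[:half], labels[half:]):
        child_depth = (sub_depth * rng.uniform(0.4, 0.8)
                       if len(part) > 1 else 0.0)
        child = _balanced_join(part, child_depth, label_prefix, rng, tns,
                               ages, counter)
        child.edge.length = sub_depth - child_depth
        node.add_child(child)
    return node


def sample_species_tree(n_taxa: int, depth: float, seed: int,
                        n_groups: int = 2) -> SpeciesTree:
    """Random ultrametric rooted binary tree with taxon groups.

    With one group, leaves coalesce by sequential random joins at uniform
    ages with the root pinned at ``depth``, so every root-to-leaf path has
    length exactly ``depth``.  With two groups (the default) the taxa are
    split evenly and each group coalesces within its own subtree; the two
    group stems meet at the root, making both groups monophyletic — the
    reference situation for cross-group transfer detection.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_groups not in (1, 2):
        raise ValueError("n_groups must be 1 or 2")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    ages: dict[int, float] = {}
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    groups: dict[str, str] = {}
    if n_groups == 1:
        root = _random_join(labels, depth, "n", rng, tns, ages)
        groups = {lb: "g1" for lb in labels}
    else:
        n1 = n_taxa // 2
        sub_depth = GROUP_SPLIT_FRACTION * depth
        root = dendropy.Node()
        root.label = "root"
        ages[id(root)] = depth
        for gi, part in enumerate((labels[:n1], labels[n1:]), start=1):
            sub = _balanced_join(part, sub_depth, f"n{gi}_", rng, tns,
                                 ages, [0])
            sub.edge.length = depth - sub_depth if len(part) > 1 else depth
            root.add_child(sub)
            groups.update({lb: f"g{gi}" for lb in part})
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        nd.tau = depth - ages[id(nd)]  # time from root
    return SpeciesTree(tree=tree, taxon_groups=groups, depth=depth)


# ---------------------------------------------------------------------------
# Family evolution (duplication / loss / transfer)


@dataclass
class EventRates:
    """Per-lineage, per-unit-branch-length event rates."""

    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    hgt_rate: float = 0.0
    recombination_probability: float = 0.0

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "loss_rate", "hgt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.recombination_probability <= 1:
            raise ValueError("recombination_probability must be in [0,1]")


def evolve_family(sp: SpeciesTree, rates: EventRates, seed: int,
                  forced_hgts: Sequence[tuple[str, str, float]] = (),
                  ) -> tuple[dendropy.Tree, list[Event]]:
    """Birth-death-transfer process along the species tree.

    The founding gene enters at the root and evolves top-down.  Duplications
    split a lineage in place; losses terminate it; a transfer copies the
    lineage onto a contemporaneous branch of a different species (the donor
    lineage continues — additive acquisition).  ``forced_hgts`` plants
    transfers deterministically: (donor branch label, recipient branch label,
    time from root); the first lineage crossing that time on the donor branch
    emits the transfer.

    Returns the gene tree (leaves labeled ``taxon|geneid``; empty tree if
    all copies are lost) and the ordered event log.
    """
    rng = np.random.default_rng(seed)
    tree = sp.tree
    nodes = list(tree.preorder_node_iter())
    label_of = {id(nd): (nd.taxon.label if nd.is_leaf() else nd.label)
                for nd in nodes}
    node_by_label = {label_of[id(nd)]: nd for nd in nodes}
    events: list[Event] = []
    counter = [0]

    def new_gid() -> str:
        counter[0] += 1
        return f"g{counter[0]}"

    pending = sorted(forced_hgts, key=lambda f: (f[2], f[0], f[1]))
    pending = [list(f) + [False] for f in pending]  # consumed flag

    def next_forced(branch_label: str, t: float) -> list | None:
        for f in pending:
            if not f[3] and f[0] == branch_label and f[2] > t:
                return f
        return None

    def alive_branches(t: float) -> list[dendropy.Node]:
        out = []
        for nd in nodes:
            if nd.parent_node is None:
                continue
            if nd.parent_node.tau < t < nd.tau:
                out.append(nd)
        return out

    root_gnode = dendropy.Node()
    root_gnode.sim_time = 0.0
    total_rate = rates.duplication_rate + rates.loss_rate + rates.hgt_rate
    founder = new_gid()  # one founding lineage enters both root children
    # stack entries: (species node, time, lineage id, parent gene node)
    stack = [(child, 0.0, founder, root_gnode)
             for child in reversed(tree.seed_node.child_nodes())]
    leaves: list[tuple[dendropy.Node, str]] = []

    while stack:
        v, t, gid, parent = stack.pop()
        branch = label_of[id(v)]
        while True:
            t_end = v.tau
            forced = next_forced(branch, t)
            t_forced = forced[2] if forced and forced[2] <= t_end else math.inf
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            t_event = t + dt
            t_next = min(t_event, t_forced, t_end)
            if t_next == t_end:
                node = dendropy.Node()
                node.sim_time = t_end
                node.edge.length = t_end - parent.sim_time
                parent.add_child(node)
                if v.is_leaf():
                    leaves.append((node, f"{v.taxon.label}|{gid}"))
                else:
                    for child in reversed(v.child_nodes()):
                        stack.append((child, t_end, gid, node))
                break
            if t_next == t_forced:
                forced[3] = True
                recipient = node_by_label[forced[1]]
                node = dendropy.Node()
                node.sim_time = t_forced
                node.edge.length = t_forced - parent.sim_time
                parent.add_child(node)
                new_id = new_gid()
                events.append(Event("hgt", branch, forced[1], t_forced,
                                    new_id, parent_gene_id=gid))
                stack.append((recipient, t_forced, new_id, node))
                parent, t = node, t_forced
                continue
            # random event
            kind = rng.choice(3, p=np.array([rates.duplication_rate,
                                             rates.loss_rate,
                                             rates.hgt_rate]) / total_rate)
            if kind == 0:  # duplication
                node = dendropy.Node()
                node.sim_time = t_event
                node.edge.length = t_event - parent.sim_time
                parent.add_child(node)
                new_id = new_gid()
                events.append(Event("duplication", branch, None, t_event,
                                    new_id, parent_gene_id=gid))
                stack.append((v, t_event, new_id, node))
                parent, t = node, t_event
            elif kind == 1:  # loss
                events.append(Event("loss", branch, None, t_event, gid))
                node = dendropy.Node()
                node.sim_time = t_event
                node.edge.length = t_event - parent.sim_time
                node.dead = True
                parent.add_child(node)
                break
            else:  # transfer
                candidates = [nd for nd in alive_branches(t_event)
                              if id(nd) != id(v)]
                if not candidates:
                    t = t_event
                    continue
                recipient = candidates[rng.integers(len(candidates))]
                node = dendropy.Node()
                node.sim_time = t_event
                node.edge.length = t_event - parent.sim_time
                parent.add_child(node)
                new_id = new_gid()
                events.append(Event("hgt", branch, label_of[id(recipient)],
                                    t_event, new_id, parent_gene_id=gid))
                stack.append((recipient, t_event, new_id, node))
                parent, t = node, t_event

    gene_tree = _finalize_gene_tree(root_gnode, leaves)
    events.sort(key=lambda e: e.time)
    return gene_tree, events


def n_gene_leaves(tree: dendropy.Tree) -> int:
    """Number of surviving genes (leaves carrying a taxon label)."""
    return sum(1 for lf in tree.leaf_node_iter() if lf.taxon is not None)


def _finalize_gene_tree(root: dendropy.Node,
                        leaves: list[tuple[dendropy.Node, str]]
                        ) -> dendropy.Tree:
    """Prune extinct lineages, suppress unifurcations, attach taxa."""
    label_by_node = {id(nd): lb for nd, lb in leaves}
    changed = True
    while changed:
        changed = False
        for nd in list(_postorder(root)):
            if nd is root:
                continue
            is_surviving_leaf = id(nd) in label_by_node
            if not nd.child_nodes() and not is_surviving_leaf:
                nd.parent_node.remove_child(nd)
                changed = True
    tns = dendropy.TaxonNamespace()
    for nd in _postorder(root):
        lb = label_by_node.get(id(nd))
        if lb is not None:
            nd.taxon = tns.new_taxon(lb)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    tree.suppress_unifurcations()
    return tree


def _postorder(root: dendropy.Node):
    stack, out = [root], []
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(nd.child_nodes())
    return reversed(out)


def replay_event_log(sp: SpeciesTree, events: Sequence[Event]) -> list[str]:
    """Independent interpreter: derive the expected gene-tree leaf multiset
    from the species tree and an event log, without touching the simulator's
    tree-building path.  Used as the log/tree consistency oracle."""
    tree = sp.tree
    label_of = {}
    for nd in tree.preorder_node_iter():
        label_of[id(nd)] = nd.taxon.label if nd.is_leaf() else nd.label
    ev_by_branch: dict[str, list[Event]] = {}
    for e in events:
        ev_by_branch.setdefault(e.donor, []).append(e)
    injections: dict[str, list[Event]] = {}
    for e in events:
        if e.kind == "hgt":
            injections.setdefault(e.recipient, []).append(e)
    out: list[str] = []

    def walk(node, incoming: list[tuple[str, float]]):
        # incoming: (lineage id, time it entered this branch)
        branch = label_of[id(node)]
        timeline = []
        for e in ev_by_branch.get(branch, []):
            timeline.append(e)
        for e in injections.get(branch, []):
            timeline.append(e)
        timeline.sort(key=lambda e: e.time)
        lineages = dict(incoming)
        for e in timeline:
            if e.kind == "duplication" and e.parent_gene_id in lineages:
                lineages[e.gene_id] = e.time
            elif e.kind == "loss" and e.gene_id in lineages:
                del lineages[e.gene_id]
            elif e.kind == "hgt":
                if e.recipient == branch:
                    lineages[e.gene_id] = e.time
                # donor side: copy continues, nothing to do
        if node.is_leaf():
            out.extend(f"{branch}|{gid}" for gid in lineages)
        else:
            for child in node.child_nodes():
                walk(child, [(g, node.tau) for g in lineages])

    for child in tree.seed_node.child_nodes():
        walk(child, [("g1", 0.0)])
    return sorted(out)


# ---------------------------------------------------------------------------
# Sequence evolution with true-alignment tracking


def make_root_protein(length: int = 300, seed: int = 0,
                      d_positions: Sequence[int] = (40, 60, 80),
                      qxxrw_at: int = 120, qxxxy_at: int = 160) -> str:
    """Random root protein with the planted motif set.

    Plants three D anchors, one QXXRW and one QXXXY at the stated positions;
    all other residues are uniform random non-D letters (keeping the D
    anchors unambiguous does not matter for the filter, but avoids planting
    accidental extra QXXRW copies is checked below).
    """
    rng = np.random.default_rng(seed)
    letters = [a for a in AMINO_ACIDS if a not in "DW"]
    prot = [letters[i] for i in rng.integers(len(letters), size=length)]
    for p in d_positions:
        prot[p] = "D"
    prot[qxxrw_at:qxxrw_at + 5] = ["Q", "A", "A", "R", "W"]
    prot[qxxxy_at:qxxxy_at + 5] = ["Q", "A", "A", "A", "Y"]
    protein = "".join(prot)
    report = find_catalytic_motifs(protein)
    if not report.complete or not report.qxxxy_positions:
        raise AssertionError("root protein construction failed")
    return protein


def _planted_anchor_positions(root_protein: str) -> set[int]:
    report = find_catalytic_motifs(root_protein)
    if not report.complete:
        raise ValueError("root protein lacks the D,D,D,QXXRW motif set")
    if not report.qxxxy_positions:
        raise ValueError("root protein lacks a QXXXY motif")
    d1, d2, d3, q = report.chosen_assignment
    anchors = {d1, d2, d3}
    anchors.update(range(q, q + 5))
    y = report.qxxxy_positions[0]
    anchors.update(range(y, y + 5))
    return anchors


def evolve_sequences(gene_tree: dendropy.Tree, root_protein: str,
                     subst_rate: float, indel_rate: float, seed: int,
                     motif_decay: bool = False,
                     taxon_groups: Mapping[str, str] | None = None,
                     gc_targets: Mapping[str, float] | None = None,
                     true_class: Mapping[str, str] | None = None,
                     ) -> tuple[list[CodingGene], Alignment]:
    """Evolve proteins down the gene tree, tracking true homology columns.

    Substitutions are a per-site Poisson process at rate ``subst_rate`` per
    unit branch length, replacing the residue by a uniform random distinct
    amino acid.  Planted motif anchor positions are immutable unless
    ``motif_decay`` is set.  Indels are single-column events at rate
    ``indel_rate`` per site.  Coding sequences are generated per leaf by
    codon back-translation targeting the G+C of the leaf's taxon group
    (``gc_targets``); without targets no CDS is attached.
    """
    anchors = _planted_anchor_positions(root_protein)
    rng = np.random.default_rng(seed)
    L0 = len(root_protein)
    master: list[int] = list(range(L0))  # global column order
    next_col = [L0]
    anchor_cols = set(anchors) if not motif_decay else set()
    root_seq = {c: root_protein[c] for c in range(L0)}

    aa = np.array(list(AMINO_ACIDS))
    seqs: dict[int, dict[int, str]] = {id(gene_tree.seed_node): root_seq}
    order = {c: k for k, c in enumerate(master)}

    def seq_cols_sorted(seq: dict[int, str]) -> list[int]:
        return sorted(seq, key=lambda c: order[c])

    for nd in gene_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length or 0.0
        seq = dict(seqs[id(nd.parent_node)])
        mutable = [c for c in seq if c not in anchor_cols]
        # substitutions: per-site Poisson jump counts
        if subst_rate > 0 and mutable:
            ks = rng.poisson(subst_rate * bl, size=len(mutable))
            for c, k in zip(mutable, ks):
                cur = seq[c]
                for _ in range(k):
                    cur = str(rng.choice(aa[aa != cur]))
                seq[c] = cur
        # indels: single-column events
        if indel_rate > 0:
            n_ind = rng.poisson(indel_rate * bl * len(seq))
            for _ in range(n_ind):
                cols = seq_cols_sorted(seq)
                if rng.random() < 0.5 and len(cols) > 1:
                    deletable = [c for c in cols if c not in anchor_cols]
                    if not deletable:
                        continue
                    del seq[deletable[rng.integers(len(deletable))]]
                else:
                    pos = int(rng.integers(len(cols) + 1))
                    # never insert inside a planted-motif span
                    if (0 < pos < len(cols)
                            and cols[pos - 1] in anchor_cols
                            and cols[pos] in anchor_cols):
                        continue
                    new_c = next_col[0]
                    next_col[0] += 1
                    if pos == 0:
                        at = order[cols[0]]
                    else:
                        at = order[cols[pos - 1]] + 1
                    master.insert(at, new_c)
                    order.clear()
                    order.update({c: k for k, c in enumerate(master)})
                    seq[new_c] = str(rng.choice(aa))
        seqs[id(nd)] = seq

    groups = taxon_groups or {}
    genes: list[CodingGene] = []
    rows: dict[str, str] = {}
    leaf_seqs = {}
    for lf in gene_tree.leaf_node_iter():
        label = lf.taxon.label
        leaf_seqs[label] = seqs[id(lf)]
    # drop columns absent from every leaf
    live = set()
    for s in leaf_seqs.values():
        live.update(s)
    cols = [c for c in master if c in live]
    for label, seq in leaf_seqs.items():
        rows[label] = "".join(seq.get(c, "-") for c in cols)
        protein = "".join(seq[c] for c in cols if c in seq)
        taxon = label.split("|")[0]
        group = groups.get(taxon)
        cds = None
        host_gc = None
        if gc_targets is not None and group in gc_targets:
            host_gc = gc_targets[group]
            cds = back_translate(protein, host_gc, rng)
        genes.append(CodingGene(gene_id=label, taxon=taxon, protein=protein,
                                cds=cds, host_gc=host_gc,
                                true_class=(true_class or {}).get(label)))
    aln = Alignment(list(rows), list(rows.values()))
    return genes, aln


# ---------------------------------------------------------------------------
# Codon back-translation and composition shift

_CODON_TABLE = unambiguous_dna_by_id[1]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa_ in sorted(_CODON_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(aa_, []).append(codon)
CODON_TO_AA = dict(_CODON_TABLE.forward_table)


def _gc_count(codon: str) -> int:
    return sum(c in "GC" for c in codon)


def _expected_gc(protein: str, beta: float) -> float:
    total = 0.0
    counts: dict[str, float] = {}
    for a in set(protein):
        g = np.array([_gc_count(c) for c in AA_TO_CODONS[a]], dtype=float)
        w = np.exp(beta * g)
        counts[a] = float((w * g).sum() / w.sum())
    for a in protein:
        total += counts[a]
    return total / (3 * len(protein))


def solve_beta(protein: str, target_gc: float,
               lo: float = -30.0, hi: float = 30.0) -> float:
    """Exponential-tilting parameter such that the expected G+C of the
    back-translated CDS equals ``target_gc`` (clamped to the achievable
    range given the protein's amino-acid content)."""
    if _expected_gc(protein, lo) >= target_gc:
        return lo
    if _expected_gc(protein, hi) <= target_gc:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _expected_gc(protein, mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def back_translate(protein: str, target_gc: float,
                   rng: np.random.Generator) -> str:
    """Codon back-translation under the standard genetic code, choosing
    synonymous codons so the expected CDS G+C equals ``target_gc``."""
    beta = solve_beta(protein, target_gc)
    parts = []
    weight_cache: dict[str, np.ndarray] = {}
    for a in protein:
        codons = AA_TO_CODONS[a]
        if a not in weight_cache:
            g = np.array([_gc_count(c) for c in codons], dtype=float)
            w = np.exp(beta * g)
            weight_cache[a] = w / w.sum()
        parts.append(codons[rng.choice(len(codons), p=weight_cache[a])])
    return "".join(parts)


def translate_cds(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds), 3))


def apply_composition_shift(gene: CodingGene, donor_gc: float,
                            amelioration: float, seed: int,
                            host_gc: float | None = None) -> CodingGene:
    """Resample synonymous codon choices so the expected CDS G+C is the
    donor/host mixture donor_gc*(1-amelioration) + host_gc*amelioration.
    The protein is unchanged."""
    if gene.cds is None:
        raise ValueError(f"{gene.gene_id}: no cds to shift")
    if not 0 <= donor_gc <= 1 or not 0 <= amelioration <= 1:
        raise ValueError("donor_gc and amelioration must be in [0,1]")
    host = host_gc if host_gc is not None else gene.host_gc
    if host is None and amelioration > 0:
        raise ValueError("host G+C unknown but amelioration > 0")
    target = donor_gc * (1 - amelioration) + (host or 0.0) * amelioration
    rng = np.random.default_rng(seed)
    cds = back_translate(gene.protein, target, rng)
    return replace(gene, cds=cds)


def gc_fraction(seq: str) -> float:
    acgt = sum(c in "ACGT" for c in seq)
    return sum(c in "GC" for c in seq) / acgt if acgt else 0.0


# ---------------------------------------------------------------------------
# Recombinants (chimeric fusions)


def make_recombinant(geneN: CodingGene, geneC: CodingGene,
                     breakpoint_after_motif: MotifDefinition | str = QXXXY,
                     new_id: str | None = None) -> CodingGene:
    """Fuse the N-terminal part of ``geneN`` (through its first motif
    occurrence) to the C-terminal part of ``geneC`` (from its first motif
    occurrence), duplicating the motif in the product."""
    motif = breakpoint_after_motif
    if isinstance(motif, str):
        motif = MotifDefinition(motif, motif)
    hitsN = find_motif(geneN.protein, motif)
    hitsC = find_motif(geneC.protein, motif)
    if not hitsN or not hitsC:
        missing = geneN.gene_id if not hitsN else geneC.gene_id
        raise ValueError(f"motif {motif.pattern} absent in {missing}")
    endN = hitsN[0] + len(motif)
    startC = hitsC[0]
    protein = geneN.protein[:endN] + geneC.protein[startC:]
    cds = None
    if geneN.cds is not None and geneC.cds is not None:
        cds = geneN.cds[:3 * endN] + geneC.cds[3 * startC:]
    return CodingGene(gene_id=new_id or f"rec|{geneN.gene_id}+{geneC.gene_id}",
                      taxon=geneN.taxon, protein=protein, cds=cds,
                      is_recombinant=True)


def make_recombinant_aligned(aln: Alignment, idN: str, idC: str,
                             motif: MotifDefinition | str = QXXXY,
                             new_id: str = "chimera",
                             ) -> tuple[Alignment, CodingGene]:
    """Chimeric fusion expressed in alignment coordinates.

    The chimera row takes ``idN``'s columns through the end of its motif
    occurrence and ``idC``'s columns from the start of its occurrence; when
    the two occurrences share columns, duplicate columns are inserted (gap in
    every reference row), exactly as an aligner would place a tandem
    duplication.  The ungapped chimera equals ``make_recombinant`` output.
    """
    if isinstance(motif, str):
        motif = MotifDefinition(motif, motif)
    rowN, rowC = aln.row(idN), aln.row(idC)

    def col_of(row: str, ungapped: int) -> int:
        n = -1
        for j, ch in enumerate(row):
            if ch != "-":
                n += 1
                if n == ungapped:
                    return j
        raise ValueError("ungapped index out of range")

    sN = "".join(c for c in rowN if c != "-")
    sC = "".join(c for c in rowC if c != "-")
    hitsN = find_motif(sN, motif)
    hitsC = find_motif(sC, motif)
    if not hitsN or not hitsC:
        raise ValueError(f"motif {motif.pattern} absent in {idN if not hitsN else idC}")
    end_col = col_of(rowN, hitsN[0] + len(motif) - 1) + 1
    start_col = col_of(rowC, hitsC[0])
    if start_col >= end_col:
        chimera_row = (rowN[:end_col] + "-" * (start_col - end_col)
                       + rowC[start_col:])
        new_rows = list(aln.rows)
    else:
        v = end_col - start_col
        chimera_row = rowN[:end_col] + rowC[start_col:end_col] + rowC[end_col:]
        new_rows = [r[:end_col] + "-" * v + r[end_col:] for r in aln.rows]
    out = Alignment(list(aln.ids) + [new_id], new_rows + [chimera_row])
    protein = "".join(c for c in chimera_row if c != "-")
    gene = CodingGene(gene_id=new_id, taxon=new_id.split("|")[0],
                      protein=protein, is_recombinant=True)
    return out, gene


def decay_motifs(protein: str, rng: np.random.Generator,
                 motif: str = QXXRW) -> str:
    """Destroy every occurrence of the given catalytic motif (default QXXRW)
    by mutating its final residue, producing a guaranteed 'dubious' protein."""
    prot = list(protein)
    while True:
        hits = find_motif("".join(prot), motif)
        if not hits:
            return "".join(prot)
        pos = hits[0] + len(motif) - 1
        choices = [a for a in AMINO_ACIDS if a != prot[pos] and a not in "WQ"]
        prot[pos] = str(rng.choice(choices))


# ---------------------------------------------------------------------------
# Neighborhoods and genomic context


DEFAULT_OPERON = ("DUF1800", "DUF1501", "SE")


def make_neighborhoods(genes: Sequence[CodingGene], events: Sequence[Event],
                       seed: int, operon: Sequence[str] = DEFAULT_OPERON,
                       half_width: int = 3) -> NeighborhoodTable:
    """Gene-neighborhood table: vertical genes get genome-private flanking
    families; each HGT donor's focal gene carries a conserved operon, and
    the transferred copy arrives with that operon intact (co-transfer)."""
    rng = np.random.default_rng(seed)
    donor_of = {e.gene_id: e.donor for e in events if e.kind == "hgt"}
    donor_taxa = set(donor_of.values())
    rows = []

    def private(taxon: str) -> list[str]:
        return [f"{taxon}_fam{i}" for i in range(2 * half_width)]

    def operon_set(taxon: str) -> list[str]:
        return list(operon) + [f"{taxon}_x{i}"
                               for i in range(2 * half_width - len(operon))]

    def emit(gene: CodingGene, families: Sequence[str]) -> None:
        offsets = [o for o in range(-half_width, half_width + 1) if o != 0]
        for off, fam in zip(offsets, families):
            rows.append((gene.taxon, gene.gene_id, off, fam, "+"))

    for g in genes:
        lineage = g.gene_id.split("|")[-1]
        if lineage in donor_of:
            # the acquired copy arrives with the donor's neighborhood intact
            fams = operon_set(donor_of[lineage])
        elif g.taxon in donor_taxa:
            fams = operon_set(g.taxon)
        else:
            fams = private(g.taxon)
        emit(g, fams)
    df = pd.DataFrame(rows, columns=NeighborhoodTable.COLUMNS)
    return NeighborhoodTable(df, half_width=half_width)


def make_genomic_context(gc: float, length: int, rng: np.random.Generator) -> str:
    """Random genomic background sequence with the given expected G+C."""
    probs = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(np.array(list("GCAT"))[rng.choice(4, size=length, p=probs)])


# ---------------------------------------------------------------------------
# Fixture assembly


@dataclass
class FixtureConfig:
    """Study conditions for the simulated datasets.

    Defaults model a small two-group phylogeny (e.g. fungi vs bacteria-like
    hosts) with strong sequence signal: 12 taxa, tree depth 0.8 expected
    substitutions per site, 300-residue proteins, donor/host genome G+C of
    0.35 and 0.60 (roughly the span seen across real microbial genomes).
    """

    n_taxa: int = 12
    depth: float = 0.8
    n_groups: int = 2
    rates: EventRates = field(default_factory=EventRates)
    n_forced_hgt: int = 0
    hgt_amelioration: float = 0.0
    n_recombinants: int = 0
    n_decayed: int = 0
    subst_rate: float = 1.0
    indel_rate: float = 0.02
    protein_length: int = 300
    gc_targets: dict[str, float] = field(
        default_factory=lambda: {"g1": 0.35, "g2": 0.60,
                                 OUTGROUP_GROUP: 0.50})
    context_length: int = 5000
    outgroup_size: int = 2
    outgroup_stem: float = 0.5
    operon: tuple[str, ...] = DEFAULT_OPERON


@dataclass
class SimulatedDataset:
    species_tree: SpeciesTree
    gene_tree: dendropy.Tree
    genes: list[CodingGene]
    alignment: Alignment
    events: list[Event]
    taxon_map: dict[str, tuple[str, str]]  # seq_id -> (taxon, group)
    neighborhoods: NeighborhoodTable
    contexts: dict[str, str]  # genome -> background nucleotide sequence
    outgroup_ids: list[str]
    config: FixtureConfig
    decayed_ids: frozenset[str] = frozenset()

    @property
    def hgt_gene_ids(self) -> set[str]:
        lids = {e.gene_id for e in self.events if e.kind == "hgt"}
        return {g.gene_id for g in self.genes
                if g.gene_id.split("|")[-1] in lids}


def _attach_outgroup(family_root: dendropy.Node, n: int, stem: float,
                     tip: float, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    """New root with an outgroup clade of ``n`` leaves beside the family."""
    root = dendropy.Node()
    og = dendropy.Node()
    og.edge.length = stem
    prev = og
    for i in range(n):
        leaf = dendropy.Node(taxon=tns.new_taxon(f"outg{i + 1}|og{i + 1}"))
        leaf.edge.length = tip
        prev.add_child(leaf)
        if i < n - 2:
            inner = dendropy.Node()
            inner.edge.length = tip / 2
            prev.add_child(inner)
            prev = inner
    root.add_child(og)
    family_root.edge.length = stem
    root.add_child(family_root)
    return root


def generate_dataset(config: FixtureConfig, seed: int) -> SimulatedDataset:
    """Simulate one complete dataset under the configured conditions."""
    rng = np.random.default_rng(seed)
    s_tree, s_fam, s_seq, s_nb, s_ctx = rng.integers(2 ** 31, size=5)
    sp = sample_species_tree(config.n_taxa, config.depth, int(s_tree),
                             n_groups=config.n_groups)

    forced = _plan_forced_hgts(sp, config.n_forced_hgt, rng)
    gene_tree, events = evolve_family(sp, config.rates, int(s_fam),
                                      forced_hgts=forced)
    if n_gene_leaves(gene_tree) == 0:
        raise RuntimeError("family went extinct under these rates; "
                           "lower the loss rate or reseed")

    # splice in the outgroup clade before sequence evolution
    tns = gene_tree.taxon_namespace
    if config.outgroup_size > 0:
        new_root = _attach_outgroup(gene_tree.seed_node, config.outgroup_size,
                                    config.outgroup_stem, 0.1, tns)
        gene_tree = dendropy.Tree(taxon_namespace=tns, seed_node=new_root)
        gene_tree.is_rooted = True

    taxon_groups = dict(sp.taxon_groups)
    for i in range(config.outgroup_size):
        taxon_groups[f"outg{i + 1}"] = OUTGROUP_GROUP

    root_protein = make_root_protein(config.protein_length,
                                     seed=int(rng.integers(2 ** 31)))
    # division ground truth: the two clades under the family root
    true_class: dict[str, str] = {}
    if config.outgroup_size > 0:
        family_root = next(
            ch for ch in gene_tree.seed_node.child_nodes()
            if not any(lf.taxon.label.startswith("outg")
                       for lf in ch.leaf_iter()))
    else:
        family_root = gene_tree.seed_node
    for k, div in enumerate(family_root.child_nodes(), start=1):
        for lf in div.leaf_iter():
            true_class[lf.taxon.label] = f"D{k}"
    genes, aln = evolve_sequences(gene_tree, root_protein, config.subst_rate,
                                  config.indel_rate, int(s_seq),
                                  taxon_groups=taxon_groups,
                                  gc_targets=config.gc_targets,
                                  true_class=true_class)

    by_id = {g.gene_id: g for g in genes}
    # composition shift for transferred genes: recipient keeps donor G+C,
    # ameliorated toward the host by the configured fraction
    hgt_lineages = {e.gene_id: e for e in events if e.kind == "hgt"}
    for g in genes:
        lid = g.gene_id.split("|")[-1]
        if lid in hgt_lineages and g.cds is not None:
            e = hgt_lineages[lid]
            donor_taxon = e.donor
            donor_group = taxon_groups.get(donor_taxon)
            donor_gc = config.gc_targets.get(donor_group, 0.5)
            shifted = apply_composition_shift(
                g, donor_gc, config.hgt_amelioration,
                seed=int(rng.integers(2 ** 31)))
            shifted = replace(shifted, is_hgt=True)
            by_id[g.gene_id] = shifted
    genes = list(by_id.values())

    # motif decay: make the configured number of genes dubious
    decayable = [g for g in genes if not g.is_hgt
                 and not g.taxon.startswith("outg")]
    decayed_ids = set()
    for g in decayable[:config.n_decayed]:
        decayed = decay_motifs(g.protein, rng)
        # patch the alignment row to stay consistent with the protein
        row = list(aln.row(g.gene_id))
        it = iter(decayed)
        for j, ch in enumerate(row):
            if ch != "-":
                row[j] = next(it)
        aln.rows[aln.ids.index(g.gene_id)] = "".join(row)
        by_id[g.gene_id] = replace(g, protein=decayed, cds=None)
        decayed_ids.add(g.gene_id)
    genes = list(by_id.values())

    # chimeric fusions: cross-group N/C fusion duplicating the QXXXY motif
    if config.n_recombinants > 0:
        by_group: dict[str, list[str]] = {}
        for g in genes:
            grp = taxon_groups.get(g.taxon)
            if (grp in ("g1", "g2") and not g.is_hgt
                    and g.gene_id not in decayed_ids):
                by_group.setdefault(grp, []).append(g.gene_id)
        if len(by_group.get("g1", [])) == 0 or len(by_group.get("g2", [])) == 0:
            raise RuntimeError("recombinants need parents in both groups")
        for k in range(config.n_recombinants):
            idN = by_group["g1"][k % len(by_group["g1"])]
            idC = by_group["g2"][k % len(by_group["g2"])]
            new_id = f"rec{k + 1}|chim{k + 1}"
            aln, chim = make_recombinant_aligned(aln, idN, idC,
                                                 new_id=new_id)
            genes.append(chim)
            taxon_groups[chim.taxon] = "recombinant"

    neighborhoods = make_neighborhoods(genes, events, int(s_nb),
                                       operon=config.operon)
    ctx_rng = np.random.default_rng(int(s_ctx))
    contexts = {}
    for taxon in sorted({g.taxon for g in genes}):
        gc = config.gc_targets.get(taxon_groups.get(taxon, ""), 0.5)
        contexts[taxon] = make_genomic_context(gc, config.context_length,
                                               ctx_rng)

    taxon_map = {g.gene_id: (g.taxon, taxon_groups.get(g.taxon, ""))
                 for g in genes}
    outgroup_ids = [g.gene_id for g in genes if g.taxon.startswith("outg")]
    return SimulatedDataset(sp, gene_tree, genes, aln, events, taxon_map,
                            neighborhoods, contexts, outgroup_ids, config,
                            decayed_ids=frozenset(decayed_ids))


def _plan_forced_hgts(sp: SpeciesTree, n: int, rng: np.random.Generator
                      ) -> list[tuple[str, str, float]]:
    """Plant cross-group transfers on terminal branches at feasible times.

    Donors are chosen so that no chosen donor sits in the sibling subtree
    of another: the transferred copy attaches inside the donor's local
    clade, and keeping those local clades disjoint keeps each transfer's
    phylogenetic context clean (one transfer per neighborhood, as in real
    single-transfer events).  When the topology admits fewer such donors
    than requested, remaining transfers reuse donors in pool order.
    """
    if n == 0:
        return []
    by_group: dict[str, list] = {}
    for lf in sp.tree.leaf_node_iter():
        by_group.setdefault(sp.taxon_groups[lf.taxon.label], []).append(lf)
    groups = sorted(by_group)
    if len(groups) < 2:
        raise ValueError("forced HGTs need at least two taxon groups")
    donors_pool = by_group[groups[0]]
    recips = by_group[groups[1]]

    def sibling_leaves(leaf) -> set[str]:
        out: set[str] = set()
        for ch in leaf.parent_node.child_nodes():
            if ch is not leaf:
                out.update(x.taxon.label for x in ch.leaf_iter())
        return out

    chosen: list = []
    for leaf in donors_pool:
        if len(chosen) == n:
            break
        sibs = sibling_leaves(leaf)
        if all(c.taxon.label not in sibs
               and leaf.taxon.label not in sibling_leaves(c)
               for c in chosen):
            chosen.append(leaf)
    idx = 0
    while len(chosen) < n and idx < 2 * len(donors_pool):
        cand = donors_pool[idx % len(donors_pool)]
        if cand not in chosen:
            chosen.append(cand)
        idx += 1
    forced = []
    for k, d in enumerate(chosen[:n]):
        r = recips[k % len(recips)]
        t_min = max(d.parent_node.tau, r.parent_node.tau)
        t = 0.5 * (t_min + sp.depth)
        forced.append((d.taxon.label, r.taxon.label, float(t)))
    return forced


def emit_fixture(config: FixtureConfig, seed: int,
                 out_dir: str | Path) -> SimulatedDataset:
    """Write a complete fixture to ``out_dir``; byte-stable for a seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config, seed)
    genes_to_fasta(ds.genes, out / "proteins.fasta", "protein")
    genes_to_fasta(ds.genes, out / "cds.fasta", "cds")
    write_alignment(ds.alignment, out / "true_alignment.fasta")
    write_newick(ds.species_tree.tree, out / "species_tree.nwk")
    write_newick(ds.gene_tree, out / "gene_tree.nwk")
    write_event_log(ds.events, out / "events.tsv")
    write_taxon_map(ds.taxon_map, out / "taxon_map.tsv")
    ds.neighborhoods.write(out / "neighborhoods.tsv")
    write_fasta(ds.contexts, out / "contexts.fasta")
    return ds


# ---------------------------------------------------------------------------
# Multi-family (class) datasets


def generate_class_dataset(config: FixtureConfig, seed: int,
                           n_classes: int = 3, within_depth: float = 0.05,
                           between_stem: float = 0.2,
                           ) -> SimulatedDataset:
    """Dataset with ``n_classes`` planted classes: each class is a copy of
    the species tree (depth ``within_depth``) hanging from a long stem, so
    between-class divergence is at least 2*between_stem + ... while
    within-class divergence stays below 2*within_depth."""
    rng = np.random.default_rng(seed)
    s_tree, s_seq = rng.integers(2 ** 31, size=2)
    sp = sample_species_tree(config.n_taxa, within_depth, int(s_tree),
                             n_groups=1)
    tns = dendropy.TaxonNamespace()
    ingroup = dendropy.Node()
    true_class: dict[str, str] = {}
    for k in range(n_classes):
        sub = _copy_species_topology(sp.tree, tns, suffix=f"cls{k + 1}")
        sub.edge.length = between_stem
        ingroup.add_child(sub)
        for lf in sub.leaf_iter():
            true_class[lf.taxon.label] = f"C{k + 1}"
    # resolve the class polytomy into a caterpillar
    while len(ingroup.child_nodes()) > 2:
        kids = ingroup.child_nodes()
        a, b = kids[0], kids[1]
        joint = dendropy.Node()
        joint.edge.length = between_stem / 2
        ingroup.remove_child(a)
        ingroup.remove_child(b)
        joint.add_child(a)
        joint.add_child(b)
        ingroup.insert_child(0, joint)
    root = _attach_outgroup(ingroup, config.outgroup_size,
                            config.outgroup_stem, 0.05, tns)
    ingroup.edge.length = config.outgroup_stem
    gene_tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    gene_tree.is_rooted = True

    taxon_groups = {lb.split("|")[0]: "g1" for lb in true_class}
    for i in range(config.outgroup_size):
        taxon_groups[f"outg{i + 1}"] = OUTGROUP_GROUP
    root_protein = make_root_protein(config.protein_length,
                                     seed=int(rng.integers(2 ** 31)))
    genes, aln = evolve_sequences(gene_tree, root_protein, config.subst_rate,
                                  config.indel_rate, int(s_seq),
                                  taxon_groups=taxon_groups,
                                  gc_targets=config.gc_targets,
                                  true_class=true_class)
    taxon_map = {g.gene_id: (g.taxon, taxon_groups.get(g.taxon, ""))
                 for g in genes}
    outgroup_ids = [g.gene_id for g in genes if g.taxon.startswith("outg")]
    empty_nb = NeighborhoodTable(pd.DataFrame(columns=NeighborhoodTable.COLUMNS))
    return SimulatedDataset(sp, gene_tree, genes, aln, [], taxon_map,
                            empty_nb, {}, outgroup_ids, config)


def _copy_species_topology(tree: dendropy.Tree, tns: dendropy.TaxonNamespace,
                           suffix: str) -> dendropy.Node:
    def copy_node(nd: dendropy.Node) -> dendropy.Node:
        new = dendropy.Node()
        new.edge.length = nd.edge.length
        if nd.is_leaf():
            new.taxon = tns.new_taxon(f"{nd.taxon.label}_{suffix}|{suffix}")
        for child in nd.child_nodes():
            new.add_child(copy_node(child))
        return new

    top = copy_node(tree.seed_node)
    return top
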