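"""Monophyly-based class definition and query assignment.

A class is a set of sequences forming a well-supported monophyletic group
in trees built under two independent inference settings (here: NJ under the
p and Poisson distance corrections, each with its own bootstrap).  Queries
are assigned by smallest-including-clade logic: a query belongs to a class
iff the smallest supported clade containing it and at least one reference
sequence contains references of that class only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .phylo import node_support

DEFAULT_SUPPORT_MIN = 60  # the one printed support threshold

UNCLASSIFIED = "unclassified"


@dataclass
class ClassDefinition:
    name: str
    members: frozenset[str]
    support1: int | None = None
    support2: int | None = None
    division: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("class must have members")


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, labels: set[str]
                    ) -> tuple[bool, int | None]:
    """Whether ``labels`` form a clade in the rooted tree.

    Returns (monophyletic, support of the clade's parent edge) — support is
    None for the root or when no support annotation exists.  Non-monophyly
    returns (False, None).
    """
    leaf_of = _leaf_map(tree)
    unknown = set(labels) - set(leaf_of)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    if not labels:
        raise ValueError("empty label set")
    mrca = tree.mrca(taxa=[leaf_of[lb].taxon for lb in labels])
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    if clade != set(labels):
        return False, None
    return True, (node_support(mrca) if mrca.parent_node is not None else None)


def define_classes(tree1: dendropy.Tree, tree2: dendropy.Tree,
                   proposed: Mapping[str, set[str]],
                   support_min: int = DEFAULT_SUPPORT_MIN,
                   ) -> tuple[list[ClassDefinition], list[tuple[str, str]]]:
    """Accept each proposal iff monophyletic with support >= ``support_min``
    in BOTH trees; rejected proposals come back with the failing reason."""
    l1 = {lf.taxon.label for lf in tree1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in tree2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    accepted: list[ClassDefinition] = []
    rejected: list[tuple[str, str]] = []
    for name in proposed:
        labels = set(proposed[name])
        supports = []
        reason = None
        for k, tree in enumerate((tree1, tree2), start=1):
            mono, sup = is_monophyletic(tree, labels)
            if not mono:
                reason = f"not monophyletic (tree{k})"
                break
            if sup is None or sup < support_min:
                reason = (f"support {sup if sup is not None else 'n/a'} "
                          f"< {support_min} (tree{k})")
                break
            supports.append(sup)
        if reason is None:
            accepted.append(ClassDefinition(name, frozenset(labels),
                                            supports[0], supports[1]))
        else:
            rejected.append((name, reason))
    return accepted, rejected


def assign_query(tree: dendropy.Tree, classes: Sequence[ClassDefinition],
                 query_label: str,
                 support_min: int = DEFAULT_SUPPORT_MIN) -> str:
    """Class of the smallest supported clade around the query.

    Ascends from the query leaf to the first ancestor containing at least
    one reference leaf; the query is assigned to class C iff every
    reference leaf in that clade belongs to C and the clade's edge support
    is >= ``support_min``; otherwise "unclassified".
    """
    leaf_of = _leaf_map(tree)
    if query_label not in leaf_of:
        raise ValueError(f"query {query_label!r} not in tree")
    member_class: dict[str, str] = {}
    for c in classes:
        for m in c.members:
            member_class[m] = c.name
    node = leaf_of[query_label].parent_node
    while node is not None:
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        refs = {lb for lb in clade if lb in member_class}
        if refs:
            ref_classes = {member_class[lb] for lb in refs}
            sup = node_support(node) if node.parent_node is not None else None
            if len(ref_classes) == 1 and sup is not None and sup >= support_min:
                return next(iter(ref_classes))
            return UNCLASSIFIED
        node = node.parent_node
    return UNCLASSIFIED


def write_class_definitions(classes: Sequence[ClassDefinition],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tseq_id\tsupport1\tsupport2\n")
        for c in classes:
            for m in sorted(c.members):
                fh.write(f"{c.name}\t{m}\t{c.support1}\t{c.support2}\n")


def read_class_proposals(path: str | Path) -> dict[str, set[str]]:
    """TSV with columns class, seq_id (header optional)."""
    proposals: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.strip().split("\t")
            if len(parts) < 2 or parts[0] == "class":
                continue
            proposals.setdefault(parts[0], set()).add(parts[1])
    return proposals
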