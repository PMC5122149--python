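"""File formats and core containers.

Everything the pipeline reads or writes goes through here: FASTA (plain and
aligned), newick trees with integer support labels, and the TSV tables
(event log, taxon map, gene neighborhoods).  All coordinates written by this
package are 0-based, half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class ParseError(ValueError):
    """A malformed input file; message carries the offending record."""


# ---------------------------------------------------------------------------
# Sequences


@dataclass
class CodingGene:
    """A simulated or real gene: protein, optional CDS, and ground truth.

    ``true_class``, ``is_hgt`` and ``is_recombinant`` are only meaningful for
    simulated genes; ``host_gc`` records the G+C target of the genome the gene
    sits in (used by the composition-shift machinery).
    """

    gene_id: str
    taxon: str
    protein: str
    cds: str | None = None
    true_class: str | None = None
    is_hgt: bool = False
    is_recombinant: bool = False
    host_gc: float | None = None

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein")
        bad = set(self.protein) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{self.gene_id}: invalid residues {sorted(bad)}")
        if self.cds is not None and len(self.cds) != 3 * len(self.protein):
            raise ValueError(
                f"{self.gene_id}: cds length {len(self.cds)} is not 3x protein "
                f"length {len(self.protein)}"
            )


@dataclass
class Alignment:
    """Equal-length gapped amino-acid rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ParseError(f"duplicate ids: {dupes}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            off = next(i for i, r in zip(self.ids, self.rows)
                       if len(r) != len(self.rows[0]))
            raise ParseError(f"ragged alignment: row {off!r} has deviant length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment([i for i in keep_ids],
                         [self.rows[idx[i]] for i in keep_ids])

    def columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(list(self.ids),
                         ["".join(r[c] for c in cols) for r in self.rows])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def read_alignment(path: str | Path) -> Alignment:
    seqs = read_fasta(path)
    return Alignment(list(seqs), list(seqs.values()))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(dict(zip(aln.ids, aln.rows)), path)


# ---------------------------------------------------------------------------
# Trees

def read_newick(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"{path}: bad newick ({exc})") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def parse_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Tables


@dataclass
class Event:
    """One simulated evolutionary event.

    ``donor``/``recipient`` are species-tree branch labels (the label of the
    branch's child node); ``time`` is measured from the root; ``gene_id`` is
    the lineage created by the event (duplication copy, transferred copy) or,
    for losses, the lineage that died.
    """

    kind: str  # duplication | loss | hgt | recombination
    donor: str
    recipient: str | None
    time: float
    gene_id: str
    parent_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "loss", "hgt", "recombination"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "hgt" and self.donor == self.recipient:
            raise ValueError("hgt donor equals recipient")


def write_event_log(events: Sequence[Event], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.kind, e.donor, e.recipient or "", f"{e.time:.6f}", e.gene_id)
         for e in events],
        columns=["kind", "donor", "recipient", "time", "gene_id"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_event_log(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"donor": str, "recipient": str, "gene_id": str})
    return [Event(r.kind, r.donor, r.recipient or None, float(r.time), r.gene_id)
            for r in df.itertuples()]


def write_taxon_map(taxa: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    """taxa: seq_id -> (taxon, group)."""
    df = pd.DataFrame([(s, t, g) for s, (t, g) in taxa.items()],
                      columns=["seq_id", "taxon", "group"])
    df.to_csv(path, sep="\t", index=False)


def read_taxon_map(path: str | Path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {r.seq_id: (r.taxon, r.group) for r in df.itertuples()}


@dataclass
class NeighborhoodTable:
    """Flanking gene-family context of focal genes.

    One row per (genome, focal gene, flank position): ``position_index`` is the
    signed offset from the focal gene (…,-2,-1,1,2,…), ``family_label`` the
    gene-family label of the neighbor, ``strand`` in {+,-}.
    """

    table: pd.DataFrame
    half_width: int = 3

    COLUMNS = ["genome", "gene_id", "position_index", "family_label", "strand"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ParseError(f"neighborhood table missing columns {sorted(missing)}")
        bad = set(self.table["strand"]) - {"+", "-"}
        if bad:
            raise ParseError(f"bad strand values {sorted(bad)}")
        counts = self.table.groupby("gene_id").size()
        if (counts > 2 * self.half_width).any():
            raise ValueError("flanking list longer than 2x half-width")

    def neighbors(self, gene_id: str) -> list[str]:
        sub = self.table[self.table["gene_id"] == gene_id]
        sub = sub.sort_values("position_index")
        return list(sub["family_label"])

    def genome_of(self, gene_id: str) -> str:
        sub = self.table[self.table["gene_id"] == gene_id]
        if sub.empty:
            raise KeyError(gene_id)
        return sub["genome"].iloc[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, half_width: int = 3) -> "NeighborhoodTable":
        df = pd.read_csv(path, sep="\t",
                         dtype={"genome": str, "gene_id": str,
                                "family_label": str, "strand": str})
        return cls(df, half_width=half_width)


def genes_to_fasta(genes: Iterable[CodingGene], path: str | Path,
                   what: str = "protein") -> None:
    seqs = {}
    for g in genes:
        seq = g.protein if what == "protein" else g.cds
        if seq is not None:
            seqs[g.gene_id] = seq
    write_fasta(seqs, path)
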