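"""Horizontal gene transfer detection from three evidence lines.

A transferred gene betrays itself by (i) phylogenetic incongruence — it
nests inside a well-supported clade of a foreign taxon group; (ii) anomalous
nucleotide composition — its genomic region's G+C deviates from the host
genome background, because a recently acquired gene retains the donor's
composition until amelioration erases it; and (iii) conserved gene
neighborhoods shared across distantly related genomes, the signature of an
operon transferred as a unit.  Calls combine the three lines: two or more
lines make a "strong" call, exactly one a "weak" call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .io import NeighborhoodTable
from .phylo import node_support

DEFAULT_WINDOW = 1000  # bp
DEFAULT_STEP = 30      # bp
DEFAULT_Z_MIN = 2.0
DEFAULT_MIN_CONTEXT = 2
DEFAULT_SUPPORT_MIN = 60
FALLBACK_ABS_GC = 0.05  # used when the background has zero variance


# ---------------------------------------------------------------------------
# Composition


@dataclass
class GcProfile:
    starts: list[int]
    values: list[float]
    window: int
    step: int

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values differ in length")
        for a, b in zip(self.starts, self.starts[1:]):
            if b - a != self.step:
                raise ValueError("starts must increase by step")
        if any(not 0 <= v <= 1 for v in self.values):
            raise ValueError("G+C fractions must be in [0,1]")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tgc\n")
            for s, v in zip(self.starts, self.values):
                fh.write(f"{s}\t{v:.6f}\n")


def gc_windows(seq: str, window: int = DEFAULT_WINDOW,
               step: int = DEFAULT_STEP) -> GcProfile:
    """Overlapping sliding-window G+C profile (full windows only).

    Windows start at 0, step, 2*step, ... while start + window <= length.
    G+C is counted case-insensitively; ambiguous bases are excluded from
    both numerator and denominator.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C"]).astype(np.int64)
    is_acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    ca = np.concatenate([[0], np.cumsum(is_acgt)])
    starts, values = [], []
    start = 0
    while start + window <= n:
        gc = cg[start + window] - cg[start]
        tot = ca[start + window] - ca[start]
        starts.append(start)
        values.append(gc / tot if tot else 0.0)
        start += step
    return GcProfile(starts, values, window, step)


def gc_anomaly(region: str, background: GcProfile,
               z_min: float = DEFAULT_Z_MIN) -> tuple[float, bool]:
    """Z-score of the region's G+C against the background window values.

    With a zero-variance background the call falls back to an absolute
    G+C difference of 0.05 and the z is reported as +/- inf.
    """
    if not background.values:
        raise ValueError("empty background profile")
    arr = np.frombuffer(region.upper().encode(), dtype="S1")
    gc = int(np.isin(arr, [b"G", b"C"]).sum())
    tot = int(np.isin(arr, [b"A", b"C", b"G", b"T"]).sum())
    region_gc = gc / tot if tot else 0.0
    bg = np.asarray(background.values)
    mu, sd = float(bg.mean()), float(bg.std(ddof=0))
    diff = region_gc - mu
    if sd == 0.0:
        flag = abs(diff) >= FALLBACK_ABS_GC
        z = math.copysign(math.inf, diff) if diff else 0.0
        return z, flag
    z = diff / sd
    return z, abs(z) >= z_min


# ---------------------------------------------------------------------------
# Phylogenetic incongruence


def detect_incongruent_leaves(gene_tree: dendropy.Tree,
                              taxon_groups: Mapping[str, str],
                              support_min: int = DEFAULT_SUPPORT_MIN,
                              min_context: int = DEFAULT_MIN_CONTEXT,
                              ignore_groups: Iterable[str] = (),
                              ) -> list[tuple[str, str, str, int]]:
    """Leaves nesting inside a well-supported clade of a foreign group.

    For each leaf, ascend to the smallest clade with edge support >=
    ``support_min`` that contains at least ``min_context`` other leaves;
    the leaf is called iff all those other leaves belong to one group
    different from the leaf's own.  Returns (leaf, host group, foreign
    group, support) tuples.  Groups in ``ignore_groups`` (e.g. the
    outgroup) are neither called nor used as context.
    """
    leaves = [lf for lf in gene_tree.leaf_node_iter()]
    unmapped = [lf.taxon.label for lf in leaves
                if lf.taxon.label not in taxon_groups]
    if unmapped:
        raise ValueError(f"leaves without group: {sorted(unmapped)}")
    skip = set(ignore_groups)
    calls = []
    for lf in leaves:
        own = taxon_groups[lf.taxon.label]
        if own in skip:
            continue
        node = lf.parent_node
        while node is not None:
            sup = node_support(node) if node.parent_node is not None else None
            others = [x.taxon.label for x in node.leaf_iter()
                      if x is not lf and taxon_groups[x.taxon.label] not in skip]
            if sup is not None and sup >= support_min and len(others) >= min_context:
                groups = {taxon_groups[lb] for lb in others}
                if len(groups) == 1 and next(iter(groups)) != own:
                    calls.append((lf.taxon.label, own, next(iter(groups)), sup))
                break
            node = node.parent_node
    return calls


# ---------------------------------------------------------------------------
# Synteny


def neighborhood_similarity(nA: Sequence[str], nB: Sequence[str]) -> float:
    """Jaccard index of the two neighbor family-label sets (strands are
    ignored by default; callers wanting strand awareness should encode the
    strand into the labels)."""
    sA, sB = set(nA), set(nB)
    if not sA and not sB:
        return 0.0
    return len(sA & sB) / len(sA | sB)


@dataclass
class CotransferGroup:
    genomes: frozenset[str]
    shared_families: frozenset[str]
    gene_ids: frozenset[str]


def detect_cotransfer(neighborhoods: NeighborhoodTable,
                      taxon_groups: Mapping[str, str],
                      focal_gene_ids: Sequence[str],
                      jaccard_min: float = 0.5) -> list[CotransferGroup]:
    """Groups of genomes sharing a conserved focal-gene neighborhood across
    different taxon groups.

    Builds a genome graph with an edge wherever two focal genes in genomes
    of different groups have neighborhood Jaccard >= ``jaccard_min``;
    connected components of size >= 2 are reported with the family set
    shared across the component and the focal genes involved.
    """
    info = []
    for gid in focal_gene_ids:
        genome = neighborhoods.genome_of(gid)
        info.append((gid, genome, set(neighborhoods.neighbors(gid))))
    # union-find over genomes
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    edges = []
    matched_genes: set[str] = set()
    for i in range(len(info)):
        for j in range(i + 1, len(info)):
            gi, gmi, ni = info[i]
            gj, gmj, nj = info[j]
            if gmi == gmj:
                continue
            if taxon_groups.get(gmi) == taxon_groups.get(gmj):
                continue
            if neighborhood_similarity(ni, nj) >= jaccard_min:
                union(gmi, gmj)
                edges.append((i, j))
                matched_genes.update((gi, gj))
    comps: dict[str, set[str]] = {}
    for _, genome, _ns in info:
        if genome in parent:
            comps.setdefault(find(genome), set()).add(genome)
    out = []
    for root, genomes in sorted(comps.items()):
        if len(genomes) < 2:
            continue
        shared: set[str] | None = None
        gids = set()
        for gid, genome, ns in info:
            if genome in genomes and gid in matched_genes:
                gids.add(gid)
                shared = set(ns) if shared is None else shared & ns
        out.append(CotransferGroup(frozenset(genomes),
                                   frozenset(shared or ()), frozenset(gids)))
    return out


# ---------------------------------------------------------------------------
# Combination


@dataclass
class HgtCall:
    seq_id: str
    incongruent: bool = False
    foreign_group: str | None = None
    incongruence_support: int | None = None
    composition_flag: bool = False
    composition_z: float | None = None
    synteny_flag: bool = False
    synteny_partners: frozenset[str] = field(default_factory=frozenset)
    verdict: str = "none"
    island_annotations: tuple[str, ...] = ()  # informational only

    def evidence_count(self) -> int:
        return sum((self.incongruent, self.composition_flag, self.synteny_flag))


def combine_evidence(records: Sequence[HgtCall]) -> list[HgtCall]:
    """Set each record's verdict: strong (>=2 evidence lines), weak (1),
    none (0)."""
    for r in records:
        n = r.evidence_count()
        r.verdict = "strong" if n >= 2 else ("weak" if n == 1 else "none")
    return list(records)


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Minimal BED reader: chrom -> [(start, end, name)], 0-based half-open.

    Used for optional genomic-island / prophage annotations."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"bad BED line: {ln.strip()!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), name))
    return out


def annotate_island_overlap(calls: Sequence[HgtCall],
                            intervals: Mapping[str, list],
                            gene_locations: Mapping[str, tuple[str, int, int]],
                            ) -> list[HgtCall]:
    """Attach island/prophage annotations to calls by interval overlap.

    ``gene_locations`` maps seq_id -> (chrom, start, end), 0-based
    half-open.  Annotations are informational only: verdicts are never
    changed by them.
    """
    for c in calls:
        loc = gene_locations.get(c.seq_id)
        if loc is None:
            continue
        chrom, gstart, gend = loc
        hits = [name or f"{s}-{e}"
                for s, e, name in intervals.get(chrom, ())
                if s < gend and gstart < e]
        c.island_annotations = tuple(hits)
    return list(calls)


def write_hgt_calls(calls: Sequence[HgtCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tverdict\tincongruent\tforeign_group\tsupport\t"
                 "composition_flag\tz\tsynteny_flag\tpartners\n")
        for c in calls:
            z = "" if c.composition_z is None else f"{c.composition_z:.3f}"
            fh.write("\t".join([
                c.seq_id, c.verdict, str(int(c.incongruent)),
                c.foreign_group or "", str(c.incongruence_support or ""),
                str(int(c.composition_flag)), z, str(int(c.synteny_flag)),
                ",".join(sorted(c.synteny_partners)),
            ]) + "\n")
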