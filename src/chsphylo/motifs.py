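"""Candidate screening by PSSM similarity and catalytic-motif filtering.

Chitin synthases carry a set of conserved motifs required for catalysis:
three aspartate anchors followed by the QXXRW motif at the catalytic site.
Proteins lacking this ordered motif set are flagged "dubious" and excluded
from downstream phylogenetics.  A duplicated QXXXY motif is the sequence
signature of the chimeric (recombined) class.  The domain screen is a
position-specific scoring matrix (PSSM) scan; transmembrane segments are
predicted from Kyte-Doolittle hydropathy windows.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io import AMINO_ACIDS, Alignment, CodingGene

# Default motif grammar for the catalytic-site filter
QXXRW = "QXXRW"
QXXXY = "QXXXY"
DEFAULT_MIN_D_GAP = 10  # minimum residue separation between D anchors


@dataclass
class MotifDefinition:
    """A simple motif pattern over amino-acid letters plus wildcard X."""

    name: str
    pattern: str
    min_copies_expected: int = 1

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"invalid motif letters {sorted(bad)}")

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern.replace("X", "."))

    def __len__(self) -> int:
        return len(self.pattern)


def find_motif(protein: str, motif: MotifDefinition | str,
               overlapping: bool = True) -> list[int]:
    """All match start positions of ``motif`` in ``protein`` (0-based).

    With ``overlapping`` true a lookahead scan is used so that matches may
    overlap; otherwise matching is leftmost-greedy non-overlapping.
    """
    if isinstance(motif, str):
        motif = MotifDefinition(motif, motif)
    if overlapping:
        rx = re.compile("(?=(" + motif.pattern.replace("X", ".") + "))")
        return [m.start() for m in rx.finditer(protein)]
    return [m.start() for m in motif.regex.finditer(protein)]


@dataclass
class MotifReport:
    """Positions of the catalytic motifs in one protein."""

    d_positions: list[int]
    qxxrw_positions: list[int]
    qxxxy_positions: list[int]
    complete: bool
    chosen_assignment: tuple[int, int, int, int] | None = None

    @property
    def dubious(self) -> bool:
        return not self.complete


def find_catalytic_motifs(protein: str,
                          min_d_gap: int = DEFAULT_MIN_D_GAP) -> MotifReport:
    """Check the D, D, D, QXXRW catalytic motif set.

    ``complete`` is true iff three D residues, each separated by at least
    ``min_d_gap`` residues, can be chosen in increasing order upstream of a
    QXXRW occurrence.  Proteins failing this are "dubious" and are excluded
    from classification.
    """
    if not protein:
        raise ValueError("empty protein")
    d_pos = [i for i, a in enumerate(protein) if a == "D"]
    q_pos = find_motif(protein, QXXRW)
    y_pos = find_motif(protein, QXXXY)
    assignment = None
    # greedy: earliest feasible D anchors, then any downstream QXXRW
    for q in q_pos:
        ds = [p for p in d_pos if p < q]
        picked: list[int] = []
        for p in ds:
            if not picked or p - picked[-1] >= min_d_gap:
                picked.append(p)
            if len(picked) == 3:
                break
        if len(picked) == 3:
            assignment = (*picked, q)
            break
    return MotifReport(d_positions=d_pos, qxxrw_positions=q_pos,
                       qxxxy_positions=y_pos, complete=assignment is not None,
                       chosen_assignment=assignment)


def filter_candidates(genes: Sequence[CodingGene],
                      min_d_gap: int = DEFAULT_MIN_D_GAP
                      ) -> tuple[list[CodingGene], list[CodingGene]]:
    """Partition genes into (kept, dubious) by the catalytic-motif filter."""
    kept, dubious = [], []
    for g in genes:
        if find_catalytic_motifs(g.protein, min_d_gap=min_d_gap).complete:
            kept.append(g)
        else:
            dubious.append(g)
    return kept, dubious


def detect_motif_duplication(protein: str,
                             motif: MotifDefinition | str = QXXXY) -> list[int]:
    """Non-overlapping, leftmost-greedy matches; >=2 hits flags a duplication."""
    if isinstance(motif, str):
        motif = MotifDefinition(motif, motif, min_copies_expected=2)
    return find_motif(protein, motif, overlapping=False)


# ---------------------------------------------------------------------------
# PSSM


@dataclass
class PSSM:
    """Per-column log2-odds profile with a hit threshold."""

    scores: np.ndarray  # (width, 20) in AMINO_ACIDS order
    background: np.ndarray
    threshold: float = 0.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (width, 20)")
        if self.scores.shape[0] < 1:
            raise ValueError("width must be >= 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PSSM scores")

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# width={self.width} pseudocount={self.pseudocount} "
                     f"threshold={self.threshold:.6f}\n")
            fh.write("\t".join(AMINO_ACIDS) + "\n")
            for row in self.scores:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PSSM":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            fh.readline()  # amino-acid header
            rows = [list(map(float, ln.split())) for ln in fh if ln.strip()]
        return cls(np.array(rows), background=np.full(20, 1 / 20),
                   threshold=float(meta["threshold"]),
                   pseudocount=float(meta["pseudocount"]))


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def build_pssm(seed_alignment: Alignment, pseudocount: float = 1.0,
               background: np.ndarray | None = None,
               max_gap_fraction: float = 0.5) -> PSSM:
    """Log-odds PSSM from a seed alignment.

    Columns with >= ``max_gap_fraction`` gaps are dropped.  The score of
    amino acid a in a column with count c among n residues is
    log2(((c + pseudocount*bg_a) / (n + pseudocount)) / bg_a).
    """
    if seed_alignment.n_rows < 2:
        raise ValueError("need at least 2 sequences")
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background)
    cols = []
    for j in range(seed_alignment.width):
        column = [r[j] for r in seed_alignment.rows]
        gap_frac = column.count("-") / len(column)
        if gap_frac >= max_gap_fraction:
            continue
        residues = [a for a in column if a != "-"]
        n = len(residues)
        counts = np.zeros(20)
        for a in residues:
            counts[_AA_INDEX[a]] += 1
        probs = (counts + pseudocount * bg) / (n + pseudocount)
        cols.append(np.log2(probs / bg))
    if not cols:
        raise ValueError("no column with fewer than 50% gaps")
    return PSSM(np.vstack(cols), background=bg, pseudocount=pseudocount)


def pssm_scan(pssm: PSSM, protein: str) -> list[tuple[int, float]]:
    """Score every window of ``protein``; return (start, score) hits above
    the PSSM threshold, sorted by score descending (ties by start)."""
    w = pssm.width
    if len(protein) < w:
        return []
    idx = np.array([_AA_INDEX[a] for a in protein])
    col = np.arange(w)
    hits = []
    for s in range(len(protein) - w + 1):
        score = float(pssm.scores[col, idx[s:s + w]].sum())
        if score > pssm.threshold:
            hits.append((s, score))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def calibrate_threshold(pssm: PSSM, reference: str, n_shuffles: int = 1000,
                        quantile: float = 0.99, seed: int = 0) -> float:
    """Score threshold such that fewer than ``1 - quantile`` of shuffled
    length-matched sequences produce a hit.

    The reference protein is shuffled ``n_shuffles`` times; the best window
    score of each shuffle is recorded and the requested quantile returned.
    This preserves the permissive intent of a lenient domain-screen cutoff
    while remaining a pure score rule.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(reference))
    best = np.empty(n_shuffles)
    w = pssm.width
    col = np.arange(w)
    for k in range(n_shuffles):
        perm = rng.permutation(letters)
        idx = np.array([_AA_INDEX[a] for a in perm])
        if len(idx) < w:
            best[k] = -np.inf
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, w)
        best[k] = pssm.scores[col, windows].sum(axis=1).max()
    return float(np.quantile(best, quantile))


# ---------------------------------------------------------------------------
# Transmembrane stand-in


@dataclass
class TMSegment:
    start: int
    end: int  # half-open
    mean_hydropathy: float


def predict_tm_segments(protein: str, window: int = 19,
                        cutoff: float = 1.6) -> list[TMSegment]:
    """Hydrophobic-segment prediction from centered Kyte-Doolittle windows.

    Positions whose centered ``window``-mean hydropathy is >= ``cutoff`` are
    merged into maximal runs; runs shorter than the window are dropped.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 5:
        raise ValueError("window must be >= 5")
    vals = np.array([KYTE_DOOLITTLE[a] for a in protein])
    if len(vals) < window:
        return []
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    above = means >= cutoff  # index i -> window covering residues [i, i+window)
    segments: list[TMSegment] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            # residues covered by the run of qualifying windows
            start, end = i, j + window - 1
            if end - start >= window:
                segments.append(TMSegment(start, end,
                                          float(means[i:j].mean())))
            i = j
        else:
            i += 1
    return segments
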