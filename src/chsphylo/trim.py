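"""Alignment column trimming before tree inference.

Ambiguously aligned or highly variable columns destabilize phylogenetic
reconstruction, so each column gets a conservation score in [0, 1] — either
normalized mean pairwise substitution-matrix similarity or one minus
normalized Shannon entropy — and columns whose smoothed score falls below a
cutoff, or whose gap fraction exceeds a cutoff, are removed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io import Alignment

_MATRIX_CACHE: dict[str, tuple[dict[tuple[str, str], float], float, float]] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        m = substitution_matrices.load(name)
        pairs = {}
        vals = []
        for a in m.alphabet:
            for b in m.alphabet:
                pairs[(a, b)] = float(m[a, b])
                vals.append(float(m[a, b]))
        _MATRIX_CACHE[name] = (pairs, min(vals), max(vals))
    return _MATRIX_CACHE[name]


def score_columns(aln: Alignment, mode: str = "similarity",
                  matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Per-column conservation scores in [0, 1], gaps excluded.

    ``similarity``: mean pairwise substitution-matrix score over non-gap
    residue pairs, min-max normalized by the matrix's value range.
    ``entropy``: 1 - H(column) / log2(20).  Columns with fewer than two
    residues score 0 in similarity mode and 1 in entropy mode (no evidence
    of variability).
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    if mode not in ("similarity", "entropy"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    scores = np.zeros(aln.width)
    if mode == "similarity":
        pairs, lo, hi = _load_matrix(matrix_name)
        span = hi - lo
    for j in range(aln.width):
        col = [r[j] for r in aln.rows if r[j] != "-"]
        if mode == "entropy":
            if not col:
                scores[j] = 1.0
                continue
            _, counts = np.unique(col, return_counts=True)
            p = counts / counts.sum()
            h = float(-(p * np.log2(p)).sum())
            scores[j] = 1.0 - h / np.log2(20)
        else:
            if len(col) < 2:
                scores[j] = 0.0
                continue
            tot, n = 0.0, 0
            for x in range(len(col)):
                for y in range(x + 1, len(col)):
                    tot += pairs[(col[x], col[y])]
                    n += 1
            scores[j] = (tot / n - lo) / span
    return scores


def trim_alignment(aln: Alignment, score_cutoff: float = 0.5,
                   gap_cutoff: float = 0.5, smoothing_window: int = 3,
                   mode: str = "similarity", matrix_name: str = "BLOSUM62",
                   ) -> tuple[Alignment, list[int]]:
    """Keep columns whose smoothed score passes ``score_cutoff`` and whose
    gap fraction is at most ``gap_cutoff``.

    Selection is iterated to a fixpoint: after removing columns, scores are
    re-smoothed over the surviving neighbors and the rule re-applied until
    no further column drops.  This makes trimming idempotent by construction
    (smoothing across a removed neighbor can otherwise prop up a weak
    column on the first pass only).

    Returns the trimmed alignment and the index map (kept output column k
    came from input column ``index_map[k]``).  Column order is preserved.
    """
    if not 0 <= score_cutoff <= 1 or not 0 <= gap_cutoff <= 1:
        raise ValueError("cutoffs must be in [0,1]")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    current = aln
    index_map = list(range(aln.width))
    while True:
        keep = _select_columns(current, score_cutoff, gap_cutoff,
                               smoothing_window, mode, matrix_name)
        if len(keep) == current.width:
            return current, index_map
        current = current.columns(keep)
        index_map = [index_map[j] for j in keep]


def _select_columns(aln: Alignment, score_cutoff: float, gap_cutoff: float,
                    smoothing_window: int, mode: str,
                    matrix_name: str) -> list[int]:
    if aln.width == 0:
        return []
    scores = score_columns(aln, mode=mode, matrix_name=matrix_name)
    if smoothing_window > 1 and aln.width >= smoothing_window:
        half = smoothing_window // 2
        padded = np.pad(scores, half, mode="edge")
        kernel = np.ones(smoothing_window) / smoothing_window
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = scores
    gap_frac = np.array([sum(r[j] == "-" for r in aln.rows) / aln.n_rows
                         for j in range(aln.width)])
    return [j for j in range(aln.width)
            if smoothed[j] >= score_cutoff and gap_frac[j] <= gap_cutoff]


def write_index_map(index_map: list[int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kept_column_output_index\tinput_column_index\n")
        for k, j in enumerate(index_map):
            fh.write(f"{k}\t{j}\n")
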