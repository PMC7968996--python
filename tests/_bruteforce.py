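"""Independent per-base / exhaustive-enumeration oracles.

Everything here is deliberately naive (boolean base arrays, window-by-window
scoring in pure Python over numpy lookups) and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Per-base interval oracles (single chromosome, genome length L)
# ---------------------------------------------------------------------------

def occupancy(intervals, length: int) -> np.ndarray:
    """Boolean per-base coverage of (start, end) pairs."""
    occ = np.zeros(length, dtype=bool)
    for s, e in intervals:
        occ[s:e] = True
    return occ


def runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end) half-open."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def merge_oracle(intervals, gap: int, length: int) -> list[tuple[int, int]]:
    """Union occupancy, then join runs separated by <= gap uncovered bases."""
    merged = runs(occupancy(intervals, length))
    out = []
    for s, e in merged:
        if out and s - out[-1][1] <= gap:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect_oracle(a, b):
    """All (i, j) index pairs of overlapping intervals, plus a-indices with
    no partner, by direct pairwise comparison."""
    pairs = []
    lonely = []
    for i, (s1, e1) in enumerate(a):
        partners = [j for j, (s2, e2) in enumerate(b) if s1 < e2 and s2 < e1]
        if partners:
            pairs.extend((i, j) for j in partners)
        else:
            lonely.append(i)
    return pairs, lonely


def peaks_oracle(steps, threshold: float, min_length: int, length: int):
    """Per-base signal array scan: maximal runs >= threshold with the run
    maximum as score."""
    signal = np.zeros(length)
    for s, e, v in steps:
        signal[s:e] = v
    out = []
    for s, e in runs(signal >= threshold):
        if e - s >= min_length:
            out.append((s, e, float(signal[s:e].max())))
    return out


def classify_oracle(a, b, length: int):
    """Label the merged union runs of two peak sets by two-set occupancy."""
    occ_a = occupancy(a, length)
    occ_b = occupancy(b, length)
    labeled = []
    for s, e in runs(occ_a | occ_b):
        has_a = occ_a[s:e].any()
        has_b = occ_b[s:e].any()
        label = "F1F2" if has_a and has_b else ("PF1" if has_a else "PF2")
        labeled.append((s, e, label))
    return labeled


def element_state_oracle(tss_positions, k27ac, k4me1, length: int):
    """Per-base candidate-element state with promoter precedence.

    Returns (state array of '', 'prom', 'enh') plus per-base k27ac coverage
    to resolve run-level active/inactive states.
    """
    prom = np.zeros(length, dtype=bool)
    for t in tss_positions:
        prom[max(0, t - 1500) : t + 1500] = True
    k27 = occupancy(k27ac, length)
    k4 = occupancy(k4me1, length)
    enh = k4 & ~prom
    return prom, enh, k27


# ---------------------------------------------------------------------------
# Exhaustive motif scanning
# ---------------------------------------------------------------------------

def window_logodds(matrix: np.ndarray, window: str, background=0.25) -> float:
    """Sum of log2(p/bg) over positions; N scores 0."""
    total = 0.0
    for pos, base in enumerate(window):
        if base == "N":
            continue
        total += math.log2(matrix[pos, BASES.index(base)] / background)
    return total


def scan_oracle(matrix: np.ndarray, seq: str, min_ratio: float):
    """Every window x strand with score ratio strictly above min_ratio."""
    L = matrix.shape[0]
    lo = np.log2(matrix / 0.25)
    mn, mx = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    hits = []
    for start in range(len(seq) - L + 1):
        w = seq[start : start + L]
        for strand in "+-":
            raw = window_logodds(matrix, w if strand == "+" else revcomp(w))
            ratio = 1.0 if mx == mn else (raw - mn) / (mx - mn)
            if (ratio > min_ratio) or (min_ratio >= 1.0 and ratio >= 1.0 - 1e-9):
                hits.append((start, strand, raw, ratio))
    return hits


def max_ratio_oracle(matrix: np.ndarray, seq: str) -> float:
    lo = np.log2(matrix / 0.25)
    mn, mx = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    L = matrix.shape[0]
    best = -math.inf
    for start in range(len(seq) - L + 1):
        w = seq[start : start + L]
        best = max(
            best,
            window_logodds(matrix, w),
            window_logodds(matrix, revcomp(w)),
        )
    return 1.0 if mx == mn else (best - mn) / (mx - mn)


def random_intervals(rng, n: int, length: int, max_width: int = 400,
                     chrom: str = "chr1"):
    """(start, end) pairs for oracle tests, possibly overlapping."""
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [(int(s), int(min(s + w, length))) for s, w in zip(starts, widths)]
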