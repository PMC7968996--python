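"""Position weight matrices: score-ratio scanning, occurrence counting,
nucleotide composition features, PWM reconstruction and information content.

The central scanning statistic is the *score ratio*: the log-odds score of a
window, min-max normalized per PWM to [0, 1] so that a single threshold
(default 0.80) is comparable across motifs of different lengths and
information content.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval, reverse_complement

__all__ = [
    "PWM",
    "MotifOccurrence",
    "score_window",
    "scan",
    "max_score_ratio",
    "count_occurrences",
    "composition_features",
    "reconstruct_pwm",
    "information_content",
    "read_jaspar",
    "DINUCLEOTIDE_CLASSES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# N (and anything non-ACGT) encodes as 4 and scores 0 log-odds everywhere.
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices: A=0 C=1 G=2 T=3, other=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Per-position base probability matrix over {A, C, G, T}.

    matrix has shape (length, 4), each row summing to 1. Scores are log2
    odds against the background (default uniform 0.25 per base).
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray | None = None
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if len(self.matrix) < 1:
            raise ValueError("PWM must have length >= 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return len(self.matrix)

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Build from a (length, 4) count matrix with an additive pseudocount."""
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
        return cls(id, probs, background, pseudocount)

    @property
    def logodds(self) -> np.ndarray:
        """(length, 5) log2-odds lookup; column 4 (N) scores 0. Cached."""
        cached = self.__dict__.get("_logodds")
        if cached is None:
            with np.errstate(divide="ignore"):
                lo = np.log2(self.matrix / self.background)
            cached = np.hstack([lo, np.zeros((len(self), 1))])
            self.__dict__["_logodds"] = cached
        return cached

    @property
    def min_score(self) -> float:
        return float(self.logodds[:, :4].min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.logodds[:, :4].max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        cached = self.__dict__.get("_revcomp")
        if cached is None:
            cached = PWM(
                self.id,
                self.matrix[::-1, ::-1].copy(),
                self.background[::-1].copy(),
                self.pseudocount,
            )
            self.__dict__["_revcomp"] = cached
        return cached

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifOccurrence:
    """One scored motif hit: a motif-length span plus raw and normalized score."""

    interval: GenomicInterval
    strand: str
    raw_score: float
    score_ratio: float


def _ratio(raw: float, lo: float, hi: float) -> float:
    # Degenerate PWM (max == min, e.g. all-uniform columns): every window is
    # simultaneously best and worst possible; ratio defined as 1.0.
    if hi - lo <= 0:
        return 1.0
    return (raw - lo) / (hi - lo)


def score_window(pwm: PWM, window: str, strand: str = "+") -> tuple[float, float]:
    """Score one window of exactly PWM length; returns (raw_score, score_ratio).

    The minus strand scores the reverse complement of the window. N bases
    contribute 0 log-odds.
    """
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != PWM length {len(pwm)}"
        )
    if strand == "-":
        window = reverse_complement(window)
    idx = encode(window)
    raw = float(pwm.logodds[np.arange(len(pwm)), idx].sum())
    return raw, _ratio(raw, pwm.min_score, pwm.max_score)


def _window_scores(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Raw log-odds of every plus-strand window of an encoded sequence."""
    L = len(pwm)
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    lo = pwm.logodds
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, idx[j : j + n]]
    return scores


def scan(pwm: PWM, seq: str, min_ratio: float = 0.80) -> list[MotifOccurrence]:
    """All windows (both strands) with score_ratio strictly above min_ratio.

    Occurrences are reported on a pseudo-contig named "seq" in sequence-local
    coordinates, sorted by position then strand. Sequences shorter than the
    PWM yield an empty list.
    """
    if not 0 <= min_ratio <= 1:
        raise ValueError(f"min_ratio must be in [0, 1], got {min_ratio}")
    return scan_at(pwm, seq, "seq", 0, min_ratio)


def scan_at(
    pwm: PWM, seq: str, chrom: str, offset: int, min_ratio: float = 0.80
) -> list[MotifOccurrence]:
    """scan() with hits placed on `chrom` at sequence offset `offset`."""
    L = len(pwm)
    if len(seq) < L:
        return []
    idx = encode(seq)
    lo_min, lo_max = pwm.min_score, pwm.max_score
    span = lo_max - lo_min
    occs = []
    for strand, p in (("+", pwm), ("-", pwm.reverse_complement())):
        raws = _window_scores(p, idx)
        if span > 0:
            ratios = (raws - lo_min) / span
        else:
            ratios = np.ones(len(raws))
        # Strictly above threshold, except at min_ratio = 1.0 where
        # perfect-score windows are reported (up to float rounding).
        if min_ratio >= 1.0:
            mask = ratios >= 1.0 - 1e-9
        else:
            mask = ratios > min_ratio
        for pos in np.nonzero(mask)[0]:
            raw = float(raws[pos])
            occs.append(
                MotifOccurrence(
                    GenomicInterval(chrom, offset + int(pos), offset + int(pos) + L),
                    strand,
                    raw,
                    _ratio(raw, lo_min, lo_max),
                )
            )
    occs.sort(key=lambda o: (o.interval.start, o.strand))
    return occs


def max_score_ratio(pwm: PWM, seq: str) -> float:
    """Maximum score ratio over all windows and both strands.

    Raises for sequences shorter than the PWM (distinct from "no occurrence
    above a threshold", which scan() reports as an empty list).
    """
    if len(seq) < len(pwm):
        raise ValueError(
            f"sequence length {len(seq)} < PWM length {len(pwm)}"
        )
    return max_score_ratio_encoded(pwm, encode(seq))


def max_score_ratio_encoded(pwm: PWM, idx: np.ndarray) -> float:
    """max_score_ratio on an already-encoded sequence (hot path for
    feature-matrix construction)."""
    best = -np.inf
    for p in (pwm, pwm.reverse_complement()):
        raws = _window_scores(p, idx)
        best = max(best, float(raws.max()))
    return _ratio(best, pwm.min_score, pwm.max_score)


def count_occurrences(pwm: PWM, seq: str, min_ratio: float = 0.8) -> int:
    """Number of scan() hits after collapsing identical-span strand duplicates.

    Near-palindromic motifs (the AP-1/TRE consensus among them) produce a
    plus and a minus hit on the same span; these count as one site.
    """
    occs = scan(pwm, seq, min_ratio)
    spans = {(o.interval.start, o.interval.end) for o in occs}
    return len(spans)


# 16 dinucleotides collapsed by reverse-complement equivalence into 10 classes.
DINUCLEOTIDE_CLASSES: tuple[str, ...] = (
    "AA/TT", "AC/GT", "AG/CT", "AT", "CA/TG", "CC/GG", "CG", "GA/TC", "GC", "TA",
)
_DINUC_CLASS_OF: dict[str, str] = {}
for _cls in DINUCLEOTIDE_CLASSES:
    _rep = _cls.split("/")[0]
    _DINUC_CLASS_OF[_rep] = _cls
    _DINUC_CLASS_OF[reverse_complement(_rep)] = _cls

MONONUCLEOTIDE_CLASSES: tuple[str, ...] = ("A+T", "C+G")

COMPOSITION_FEATURES: tuple[str, ...] = MONONUCLEOTIDE_CLASSES + DINUCLEOTIDE_CLASSES


def composition_features(seq: str) -> dict[str, float]:
    """Strand-symmetric composition: 2 mononucleotide + 10 dinucleotide rates.

    Mononucleotide classes {A+T, C+G} are fractions of non-N bases;
    dinucleotide classes are rates over all windows free of N. Each group
    sums to 1. All-N (or empty) sequences are rejected.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    idx = encode(seq)
    valid = idx < 4
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    at = float(((idx == 0) | (idx == 3)).sum()) / n_valid
    feats = {"A+T": at, "C+G": 1.0 - at}
    counts = dict.fromkeys(DINUCLEOTIDE_CLASSES, 0)
    total = 0
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        cls = _DINUC_CLASS_OF.get(di)
        if cls is not None:
            counts[cls] += 1
            total += 1
    for cls in DINUCLEOTIDE_CLASSES:
        feats[cls] = counts[cls] / total if total else 0.0
    return feats


def reconstruct_pwm(
    occurrences: list[str], pseudocount: float = 0.0, id: str = "reconstructed"
) -> PWM:
    """Rebuild a PWM from aligned equal-length occurrence sequences.

    Minus-strand occurrences must already be reverse-complemented into motif
    orientation. Column probabilities are (count + pseudocount) /
    (n + 4*pseudocount).
    """
    if not occurrences:
        raise ValueError("need at least one occurrence")
    L = len(occurrences[0])
    counts = np.zeros((L, 4))
    for seq in occurrences:
        if len(seq) != L:
            raise ValueError(
                f"occurrence length {len(seq)} != expected {L}"
            )
        idx = encode(seq)
        for pos, b in enumerate(idx):
            if b < 4:
                counts[pos, b] += 1
    return PWM.from_counts(id, counts, pseudocount=pseudocount)


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Per-position and total information content in bits (uniform background).

    IC(col) = 2 + sum_b p(b) log2 p(b), with 0*log(0) = 0: a uniform column
    carries 0 bits, a single-base column 2 bits.
    """
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    per_position = 2.0 + plogp.sum(axis=1)
    return per_position, float(per_position.sum())


# ---------------------------------------------------------------------------
# JASPAR-style PFM reading
# ---------------------------------------------------------------------------

def read_jaspar(path) -> list[PWM]:
    """Read JASPAR position frequency matrices, converting counts to
    probabilities with the default pseudocount.

    Two dialects are accepted: the bracketed JASPAR format
    (">ID name" then "A [ 1 2 ... ]" rows, delegated to Bio.motifs) and the
    headered 4-row numeric form (">ID" then four whitespace-separated rows
    in A/C/G/T order).
    """
    with open(path) as fh:
        text = fh.read()
    if "[" in text:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.array(
                [m.counts[b] for b in BASES], dtype=float
            ).T  # (length, 4)
            out.append(PWM.from_counts(m.matrix_id or m.name, counts))
        return out
    out = []
    blocks = re.split(r"(?m)^>", text)
    for block in blocks:
        if not block.strip():
            continue
        lines = [ln for ln in block.splitlines() if ln.strip()]
        pwm_id = lines[0].split()[0]
        rows = [
            np.array([float(x) for x in ln.split()]) for ln in lines[1:5]
        ]
        if len(rows) != 4 or len({len(r) for r in rows}) != 1:
            raise ValueError(f"malformed 4-row PFM block for {pwm_id!r}")
        counts = np.vstack(rows).T
        out.append(PWM.from_counts(pwm_id, counts))
    return out


def write_occurrences_bed(occurrences, path) -> None:
    """Write occurrences as BED6 with score_ratio x 1000 in the score column."""
    with open(path, "w") as fh:
        for o in occurrences:
            iv = o.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or 'occ'}\t"
                f"{o.score_ratio * 1000:.0f}\t{o.strand}\n"
            )
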