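"""Peak-overlap classification, signal extraction, fold-change categories
and chromatin-state annotation of candidate regulatory elements.

Two paralogous factors' called peak sets are partitioned into three classes:
peaks bound preferentially by factor A (PF1), preferentially by factor B
(PF2), or efficiently by both (F1F2). Candidate regulatory elements are
annotated from histone marks: candidate active/inactive promoters (cAP/cIP)
are the 3-kb domains centered on TSSs with/without H3K27ac, and candidate
active/inactive enhancers (cAE/cIE) are H3K4me1-marked regions outside
promoter domains with/without H3K27ac.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    intersect,
    merge,
    peak_summit,
)

__all__ = [
    "ClassifiedPeak",
    "RegulatoryElement",
    "FoldChangeRecord",
    "classify_overlap",
    "signal_at",
    "fold_change",
    "fold_changes",
    "annotate_elements",
    "overlap_fractions",
]

PROMOTER_HALF_WIDTH = 1500  # 3-kb promoter domain centered on the TSS


@dataclass(frozen=True)
class ClassifiedPeak:
    """A binding site labeled PF1 (A-only), PF2 (B-only) or F1F2 (both),
    carrying both factors' signals so sub-threshold behaviour at
    preferential sites stays inspectable."""

    interval: GenomicInterval
    label: str  # PF1 | PF2 | F1F2
    signal_a: float = 0.0
    signal_b: float = 0.0
    summit: int | None = None

    @property
    def center(self) -> int:
        return self.summit if self.summit is not None else self.interval.midpoint


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    state: str  # cAP | cIP | cAE | cIE
    has_k4me3: bool = False


@dataclass(frozen=True)
class FoldChangeRecord:
    interval: GenomicInterval | None
    signal_cond: float
    signal_ctl: float
    fc: float
    category: str  # up | down | unchanged


def classify_overlap(
    peaks_a: IntervalSet,
    peaks_b: IntervalSet,
    track_a: SignalTrack | None = None,
    track_b: SignalTrack | None = None,
) -> list[ClassifiedPeak]:
    """Partition two factors' peak sets into PF1 / PF2 / F1F2 sites.

    Mutually overlapping a/b peaks are unified by transitive closure into a
    single union-span F1F2 site; a-only clusters become PF1, b-only PF2.
    The three labels partition the merged union of the inputs base-exactly.
    When signal tracks are given, each site records both factors' maximum
    signal and its summit (from the dominant factor's track).
    """
    tagged = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name="a") for iv in peaks_a
    ] + [GenomicInterval(iv.chrom, iv.start, iv.end, name="b") for iv in peaks_b]
    clusters = merge(IntervalSet(tagged), 0)
    members = intersect(clusters, IntervalSet(tagged))
    out: list[ClassifiedPeak] = []
    summit_lookup_a = {
        (iv.chrom, iv.start, iv.end): peak_summit(iv) for iv in peaks_a
    }
    summit_lookup_b = {
        (iv.chrom, iv.start, iv.end): peak_summit(iv) for iv in peaks_b
    }
    for cluster, parts in members:
        sources = {p.name for p in parts}
        label = "F1F2" if sources == {"a", "b"} else ("PF1" if sources == {"a"} else "PF2")
        site = GenomicInterval(cluster.chrom, cluster.start, cluster.end, name=label)
        sa = signal_at(track_a, site, "max") if track_a else 0.0
        sb = signal_at(track_b, site, "max") if track_b else 0.0
        lookup = summit_lookup_b if label == "PF2" else summit_lookup_a
        member_summits = [
            lookup[(p.chrom, p.start, p.end)]
            for p in parts
            if (p.chrom, p.start, p.end) in lookup
        ]
        summit = member_summits[0] if member_summits else site.midpoint
        out.append(ClassifiedPeak(site, label, sa, sb, summit))
    return out


def signal_at(track: SignalTrack, interval: GenomicInterval, stat: str = "max") -> float:
    """Max (summit height) or length-weighted mean of step values over an
    interval; intervals outside every step score 0."""
    if stat not in ("max", "mean"):
        raise ValueError(f"stat must be 'max' or 'mean', got {stat!r}")
    best = 0.0
    weighted = 0.0
    for s, e, v in track.steps.get(interval.chrom, ()):
        lo, hi = max(s, interval.start), min(e, interval.end)
        if hi > lo:
            best = max(best, v)
            weighted += v * (hi - lo)
    if stat == "max":
        return best
    return weighted / len(interval)


def fold_change(
    signal_cond: float,
    signal_ctl: float,
    threshold: float = 1.5,
    floor: float = 0.0,
    interval: GenomicInterval | None = None,
) -> FoldChangeRecord:
    """Signed fold change between conditions with an inclusive +/-threshold.

    fc = c/k if c >= k else -k/c with c, k the floored signals, so |fc| >= 1
    always; category is 'up' when fc >= +threshold, 'down' when
    fc <= -threshold (both bounds inclusive), else 'unchanged'. The floor is
    a pseudo-signal stabilizing ratios at weak sites.
    """
    if threshold <= 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    if signal_cond < 0 or signal_ctl < 0:
        raise ValueError("signals must be non-negative")
    c, k = signal_cond + floor, signal_ctl + floor
    if c <= 0 or k <= 0:
        raise ValueError("floored signals must be positive to form a ratio")
    fc = c / k if c >= k else -k / c
    if fc >= threshold:
        category = "up"
    elif fc <= -threshold:
        category = "down"
    else:
        category = "unchanged"
    return FoldChangeRecord(interval, signal_cond, signal_ctl, fc, category)


def fold_changes(
    track_cond: SignalTrack,
    track_ctl: SignalTrack,
    intervals: IntervalSet,
    threshold: float = 1.5,
    floor: float | None = None,
) -> list[FoldChangeRecord]:
    """Per-interval signed fold changes between two condition tracks.

    Default floor = 5% of the median control signal across the intervals,
    so near-zero control signals do not explode the ratio.
    """
    ctl = [signal_at(track_ctl, iv, "max") for iv in intervals]
    cond = [signal_at(track_cond, iv, "max") for iv in intervals]
    if floor is None:
        med = float(np.median(ctl)) if ctl else 0.0
        floor = 0.05 * med
        if floor <= 0:
            floor = 1e-6
    return [
        fold_change(c, k, threshold, floor, iv)
        for c, k, iv in zip(cond, ctl, intervals)
    ]


def annotate_elements(
    tss: IntervalSet,
    k27ac: IntervalSet,
    k4me1: IntervalSet,
    k4me3: IntervalSet | None = None,
) -> list[RegulatoryElement]:
    """Annotate candidate regulatory elements from TSSs and histone marks.

    Promoter domains are symmetric 3-kb windows centered on each TSS
    (overlapping domains are unified): cAP if touched by an H3K27ac peak,
    else cIP. H3K4me1 peaks with promoter-domain bases subtracted become
    enhancer candidates: pieces overlapping H3K27ac are cAE, the rest cIE.
    States are pairwise base-disjoint with promoter precedence. H3K4me3 is
    reported per element as an annotation layer only; it enters no rule.
    """
    domains = []
    for t in tss:
        center = t.start  # TSS is a point annotation: start == position
        start = max(0, center - PROMOTER_HALF_WIDTH)
        domains.append(GenomicInterval(t.chrom, start, center + PROMOTER_HALF_WIDTH))
    promoter_domains = merge(IntervalSet(domains), 0)

    elements: list[RegulatoryElement] = []
    for dom, marks in intersect(promoter_domains, k27ac):
        state = "cAP" if marks else "cIP"
        elements.append(RegulatoryElement(dom, state))

    # Enhancer candidates: K4me1 minus promoter bases, then split by K27ac.
    candidates: list[GenomicInterval] = []
    for peak, doms in intersect(merge(k4me1, 0), promoter_domains):
        pieces = [(peak.start, peak.end)]
        for d in doms:
            nxt = []
            for s, e in pieces:
                if d.start > s:
                    nxt.append((s, min(e, d.start)))
                if d.end < e:
                    nxt.append((max(s, d.end), e))
            pieces = nxt
        candidates.extend(
            GenomicInterval(peak.chrom, s, e) for s, e in pieces if e > s
        )
    for cand, marks in intersect(IntervalSet(candidates), k27ac):
        state = "cAE" if marks else "cIE"
        elements.append(RegulatoryElement(cand, state))

    if k4me3 is not None:
        flagged = []
        hits = intersect(
            IntervalSet(e.interval for e in elements), k4me3
        )
        k4me3_spans = {
            (iv.chrom, iv.start, iv.end): bool(m) for iv, m in hits
        }
        for e in elements:
            key = (e.interval.chrom, e.interval.start, e.interval.end)
            flagged.append(
                RegulatoryElement(e.interval, e.state, k4me3_spans.get(key, False))
            )
        elements = flagged
    elements.sort(key=lambda e: e.interval.sort_key())
    return elements


def overlap_fractions(
    query: dict[str, IntervalSet], targets: dict[str, IntervalSet]
) -> dict[str, dict[str, float | None]]:
    """Per-label fraction of query items overlapping >= 1 target interval.

    Empty query labels report None (undefined), never 0.
    """
    table: dict[str, dict[str, float | None]] = {}
    for label, qset in query.items():
        row: dict[str, float | None] = {}
        for tname, tset in targets.items():
            if len(qset) == 0:
                row[tname] = None
                continue
            hit = sum(1 for _, partners in intersect(qset, tset) if partners)
            row[tname] = hit / len(qset)
        table[label] = row
    return table


def write_fraction_table(table, path) -> None:
    """Tab-delimited fraction table with a header row; NA for undefined."""
    targets = sorted({t for row in table.values() for t in row})
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(targets) + "\n")
        for label in sorted(table):
            cells = [
                "NA" if table[label].get(t) is None else f"{table[label][t]:.4f}"
                for t in targets
            ]
            fh.write(label + "\t" + "\t".join(cells) + "\n")
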