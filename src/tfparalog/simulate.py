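"""Synthetic data generator for every pipeline stage.

Everything here is a pure function of (config, seed): genomes with planted
transcription-factor binding sites whose motif stringency and flank
composition differ by class, histone-mark landscapes realizing the
candidate-element rules, viewpoint interaction profiles with distance decay
and planted interacting regions, and per-gene knockdown modulation calls
realizing the regulation groups. Each generator emits a truth table next to
its dataset so downstream checks consume planted truth rather than
re-deriving it.

The generative assumption for binding classes mirrors the discrimination
analysis: sites preferred by factor B carry near-consensus (strict,
high-information) motif draws, sites preferred by factor A carry degenerate
draws in mildly AT-enriched flanks, and at shared sites the two factors'
signal ratio decreases with motif stringency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ClassifiedPeak
from .intervals import GenomicInterval, IntervalSet, SignalTrack
from .motif import PWM, score_window
from .regulation import ConditionCall, GeneRegulationCalls

__all__ = [
    "SimulationConfig",
    "strict_pwm",
    "degenerate_pwm",
    "decoy_pwms",
    "default_pwm_library",
    "simulate_genome",
    "plant_peaks",
    "truth_classified_peaks",
    "plant_histone_landscape",
    "simulate_capture_profiles",
    "simulate_expression_calls",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator, JSON-serializable.

    The defaults are the desk-scale study conditions every acceptance check
    runs under; peak-class sizes give the balanced 1000-vs-1000
    classification design and 2000 shared sites for the ratio regression.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    gc: float = 0.5
    n_tss_per_chrom: int = 40
    tss_min_spacing: int = 20_000
    # binding sites
    n_peaks: dict = field(
        default_factory=lambda: {"PF1": 1000, "PF2": 1000, "F1F2": 2000}
    )
    site_spacing: int = 1400  # minimum distance between planted site centers
    peak_height_mean: float = 150.0  # signal units; calling threshold is 50
    peak_height_sd: float = 30.0
    faint_height: float = 25.0  # sub-threshold signal of the other factor
    peak_core: int = 20  # bp at full height (summit plateau)
    peak_shoulder: int = 150  # bp of 0.6x-height shoulder each side
    at_rich_flank_boost: float = 0.01  # A/T excess in PF1 flanks (+-500 bp)
    ratio_beta: float = 1.0  # log10(Y1/Y2) = -beta * strict score ratio + noise
    ratio_noise_sd: float = 0.15
    # histone / element landscape
    n_cae: int = 40
    n_cie: int = 30
    element_width: int = 1200
    k27ac_width: int = 800
    mark_dropout: float = 0.0
    promoter_active_fraction: float = 0.6
    # capture model
    capture_mean_fragment: int = 2500
    capture_region: int = 1_000_000
    capture_amplitude: float = 100.0  # A in mean = A / (1 + d / d0)
    capture_d0: float = 50_000.0
    capture_dispersion: float = 0.3  # negative binomial: var = mu + disp*mu^2
    capture_replicates: int = 3
    n_planted_pirs: int = 4
    pir_width_fragments: int = 5
    pir_enrichment: float = 3.0
    # expression model
    n_genes: int = 500
    group_proportions: dict = field(
        default_factory=lambda: {
            "A": 0.2, "B": 0.15, "C": 0.1, "D": 0.1, "none": 0.45
        }
    )
    fc_range: tuple = (1.6, 4.0)
    call_error_rate: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        data = {k: v for k, v in data.items() if k in known}
        if "fc_range" in data:
            data["fc_range"] = tuple(data["fc_range"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Motif models
# ---------------------------------------------------------------------------

_CORE = "TGAGTCA"  # TRE/AP-1-like palindromic core (TGAG/CTCA)


def _consensus_pwm(id: str, consensus: str, p_major: float,
                   near_uniform: tuple[int, ...] = ()) -> PWM:
    cols = []
    for i, base in enumerate(consensus):
        if i in near_uniform:
            col = np.full(4, (1 - 0.28) / 3)
            col["ACGT".index(base)] = 0.28
        else:
            col = np.full(4, (1 - p_major) / 3)
            col["ACGT".index(base)] = p_major
        cols.append(col)
    return PWM(id, np.vstack(cols))


def strict_pwm() -> PWM:
    """High-information 7-column motif on the TRE-like core (0.91 per
    consensus base): the near-canonical recognition model."""
    return _consensus_pwm("strict_TRE", _CORE, 0.91)


def degenerate_pwm() -> PWM:
    """Lower-information motif on the same core: 0.55 consensus probability
    with two near-uniform positions."""
    return _consensus_pwm("degenerate_TRE", _CORE, 0.55, near_uniform=(3, 5))


def decoy_pwms(n: int = 8, length: int = 8, seed: int = 99) -> list[PWM]:
    """Unrelated random-consensus PWMs padding the scanning library."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        consensus = "".join(rng.choice(list("ACGT"), size=length))
        out.append(_consensus_pwm(f"decoy_{i}_{consensus}", consensus, 0.85))
    return out


def default_pwm_library() -> list[PWM]:
    return [strict_pwm(), degenerate_pwm()] + decoy_pwms()


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], IntervalSet]:
    """I.i.d. background genome at the configured GC plus point TSS
    annotations with minimum spacing. Deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    tss: list[GenomicInterval] = []
    margin = 5000
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq = _random_seq(rng, config.chrom_length, config.gc)
        genome[chrom] = seq.tobytes().decode("ascii")
        usable = config.chrom_length - 2 * margin
        needed = config.n_tss_per_chrom * config.tss_min_spacing
        if needed > usable:
            raise ValueError(
                f"cannot place {config.n_tss_per_chrom} TSSs with spacing "
                f"{config.tss_min_spacing} on a {config.chrom_length}-bp chrom"
            )
        slack = usable - needed
        offsets = np.sort(rng.choice(slack, config.n_tss_per_chrom, replace=False))
        positions = margin + offsets + np.arange(config.n_tss_per_chrom) * \
            config.tss_min_spacing
        for g, pos in enumerate(positions):
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(
                GenomicInterval(chrom, int(pos), int(pos) + 1,
                                name=f"gene_{chrom}_{g}", strand=strand)
            )
    return genome, IntervalSet(tss)


# ---------------------------------------------------------------------------
# Binding sites and signal tracks
# ---------------------------------------------------------------------------

def _draw_motif(rng: np.random.Generator, pwm: PWM) -> str:
    return "".join(
        "ACGT"[rng.choice(4, p=col / col.sum())] for col in pwm.matrix
    )


def _site_positions(rng, config: SimulationConfig) -> list[tuple[str, int]]:
    """Non-overlapping site centers, >= site_spacing apart, away from edges."""
    total = sum(config.n_peaks.values())
    per_chrom = int(np.ceil(total / config.n_chroms))
    margin = 2000
    positions: list[tuple[str, int]] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        usable = config.chrom_length - 2 * margin - per_chrom * config.site_spacing
        if usable < 0:
            raise ValueError("peaks do not fit in the genome without overlap")
        offsets = np.sort(rng.choice(usable, per_chrom, replace=False))
        centers = margin + offsets + np.arange(per_chrom) * config.site_spacing
        positions.extend((chrom, int(p)) for p in centers)
    order = rng.permutation(len(positions))
    return [positions[i] for i in order[:total]]


def plant_peaks(config: SimulationConfig, genome: dict[str, str]):
    """Plant class-dependent motifs and build both factors' signal tracks.

    Returns (genome_with_motifs, peaks_a, peaks_b, track_a, track_b, truth).
    PF2-truth sites receive a strict-PWM draw, PF1-truth sites a degenerate
    draw with AT-boosted +-500-bp flanks, F1F2-truth sites a draw from a
    stringency mixture; at F1F2 sites log10(Y1/Y2) = -beta * strict score
    ratio + noise. Signal tracks carry shoulder/core peak shapes at the
    configured heights; the factor absent from a preferential site leaves a
    faint sub-threshold signal, as seen under the peak-calling threshold.
    """
    rng = np.random.default_rng(config.seed + 1)
    strict, degen = strict_pwm(), degenerate_pwm()
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    classes = [c for c, n in config.n_peaks.items() for _ in range(n)]
    positions = _site_positions(rng, config)
    steps_a: dict[str, list] = {c: [] for c in genome}
    steps_b: dict[str, list] = {c: [] for c in genome}
    peaks_a, peaks_b = [], []
    truth_rows = []
    L = len(strict)
    half_motif = L // 2
    for cls, (chrom, center) in zip(classes, positions):
        if cls == "PF2":
            motif = _draw_motif(rng, strict)
        elif cls == "PF1":
            motif = _draw_motif(rng, degen)
            # AT-enrich the +-500 bp flanks around the site center.
            at = 0.5 + config.at_rich_flank_boost
            p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
            flank = rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8), size=1001, p=p
            )
            seqs[chrom][center - 500 : center + 501] = flank.tobytes()
        else:  # F1F2: stringency mixture
            u = rng.random()
            mix = PWM("mix", u * strict.matrix + (1 - u) * degen.matrix)
            motif = _draw_motif(rng, mix)
        mstart = center - half_motif
        seqs[chrom][mstart : mstart + L] = motif.encode("ascii")
        _, strict_ratio = score_window(strict, motif)

        height = max(60.0, rng.normal(config.peak_height_mean,
                                      config.peak_height_sd))
        if cls == "F1F2":
            log_ratio = (-config.ratio_beta * strict_ratio
                         + rng.normal(0, config.ratio_noise_sd))
            y1 = height * 10 ** (log_ratio / 2)
            y2 = height * 10 ** (-log_ratio / 2)
        elif cls == "PF1":
            y1, y2, log_ratio = height, config.faint_height, np.nan
        else:
            y1, y2, log_ratio = config.faint_height, height, np.nan

        sh, core = config.peak_shoulder, config.peak_core
        for y, steps, peaks in ((y1, steps_a, peaks_a), (y2, steps_b, peaks_b)):
            steps[chrom].extend(
                [
                    (center - sh, center, 0.6 * y),
                    (center, center + core, y),
                    (center + core, center + sh, 0.6 * y),
                ]
            )
            if y >= 50:  # the study's calling threshold
                peaks.append(
                    GenomicInterval(chrom, center - sh, center + sh,
                                    name=f"summit={center}", score=y)
                )
        truth_rows.append(
            {
                "chrom": chrom, "center": center, "cls": cls,
                "motif_start": mstart, "motif": motif,
                "strict_ratio": strict_ratio, "log_ratio": log_ratio,
                "y1": y1, "y2": y2,
            }
        )
    genome2 = {c: bytes(b).decode("ascii") for c, b in seqs.items()}
    truth = pd.DataFrame(truth_rows)
    return (
        genome2,
        IntervalSet(peaks_a),
        IntervalSet(peaks_b),
        SignalTrack(steps_a),
        SignalTrack(steps_b),
        truth,
    )


def truth_classified_peaks(truth: pd.DataFrame, width: int = 300
                           ) -> list[ClassifiedPeak]:
    """Classified peaks straight from the planted truth table (summit =
    planted site center), for stages that consume truth rather than
    re-calling peaks."""
    out = []
    for _, row in truth.iterrows():
        iv = GenomicInterval(
            row["chrom"], int(row["center"]) - width // 2,
            int(row["center"]) + width // 2, name=row["cls"],
        )
        out.append(
            ClassifiedPeak(iv, row["cls"], float(row["y1"]), float(row["y2"]),
                           summit=int(row["center"]))
        )
    return out


# ---------------------------------------------------------------------------
# Histone landscape
# ---------------------------------------------------------------------------

def plant_histone_landscape(
    config: SimulationConfig, tss: IntervalSet, rng_seed_offset: int = 2
):
    """Histone/ATAC peak sets realizing the element-state rules.

    Promoter-truth elements sit at the supplied TSSs: active ones (the
    configured fraction) receive a K27ac peak inside the 3-kb domain (and
    K4me3); inactive ones do not. Enhancer-truth elements (cAE: K4me1 +
    K27ac + ATAC; cIE: K4me1 only) are placed midway between TSSs, clear of
    every promoter domain. Each expected mark is dropped independently with
    probability mark_dropout. Returns (marks dict, truth DataFrame).
    """
    rng = np.random.default_rng(config.seed + rng_seed_offset)
    k4me1, k27ac, k4me3, atac = [], [], [], []
    truth_rows = []

    def keep() -> bool:
        return rng.random() >= config.mark_dropout

    tss_list = list(tss)
    for t in tss_list:
        active = rng.random() < config.promoter_active_fraction
        center = t.start
        if active and keep():
            k27ac.append(GenomicInterval(
                t.chrom, center - config.k27ac_width // 2,
                center + config.k27ac_width // 2))
        if active:
            k4me3.append(GenomicInterval(t.chrom, center - 500, center + 500))
        truth_rows.append(
            {"chrom": t.chrom, "center": center,
             "state": "cAP" if active else "cIP"}
        )

    # enhancers midway between consecutive TSSs on the same chromosome
    slots = []
    for a, b in zip(tss_list, tss_list[1:]):
        if a.chrom == b.chrom and b.start - a.start > 12_000:
            slots.append((a.chrom, (a.start + b.start) // 2))
    n_enh = config.n_cae + config.n_cie
    if n_enh > len(slots):
        raise ValueError(
            f"only {len(slots)} enhancer slots for {n_enh} requested elements"
        )
    order = rng.permutation(len(slots))[:n_enh]
    states = ["cAE"] * config.n_cae + ["cIE"] * config.n_cie
    w = config.element_width
    for state, slot_i in zip(states, order):
        chrom, center = slots[slot_i]
        span = GenomicInterval(chrom, center - w // 2, center + w // 2)
        if keep():
            k4me1.append(span)
        if state == "cAE":
            if keep():
                k27ac.append(GenomicInterval(
                    chrom, center - config.k27ac_width // 2,
                    center + config.k27ac_width // 2))
            if keep():
                atac.append(GenomicInterval(chrom, center - 250, center + 250))
        truth_rows.append({"chrom": chrom, "center": center, "state": state})

    marks = {
        "k4me1": IntervalSet(k4me1),
        "k27ac": IntervalSet(k27ac),
        "k4me3": IntervalSet(k4me3),
        "atac": IntervalSet(atac),
    }
    return marks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Capture profiles
# ---------------------------------------------------------------------------

def _negative_binomial(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (Poisson at dispersion 0)."""
    mu = np.maximum(mu, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_capture_profiles(
    config: SimulationConfig,
    n_viewpoints: int = 1,
    planted: bool = True,
    seed_offset: int = 3,
):
    """Viewpoint profiles over a pseudo-digested fragment map.

    Fragment lengths are exponential around the configured mean; the
    viewpoint is the central fragment. Replicate counts are negative
    binomial around a distance-decay mean A / (1 + d/d0), multiplied by the
    planted enrichment over each truth PIR's fragments (when planted).
    Returns (profiles, truth) where truth maps viewpoint name to the list
    of planted PIR fragment index ranges.
    """
    from .capture import ViewpointProfile  # local import avoids a cycle

    rng = np.random.default_rng(config.seed + seed_offset)
    profiles = []
    truth: dict[str, list[tuple[int, int]]] = {}
    for v in range(n_viewpoints):
        chrom = f"vchr{v + 1}"
        # pseudo-digestion
        bounds = [0]
        while bounds[-1] < config.capture_region:
            frag = max(200, int(rng.exponential(config.capture_mean_fragment)))
            bounds.append(bounds[-1] + frag)
        fragments = [
            GenomicInterval(chrom, s, e) for s, e in zip(bounds, bounds[1:])
        ]
        n = len(fragments)
        vp_idx = n // 2
        viewpoint = fragments[vp_idx]
        mids = np.array([f.midpoint for f in fragments], float)
        d = np.abs(mids - viewpoint.midpoint)
        mu = config.capture_amplitude / (1 + d / config.capture_d0)

        enrich = np.ones(n)
        name = f"viewpoint_{v + 1}"
        truth[name] = []
        if planted:
            w = config.pir_width_fragments
            taken = set(range(vp_idx - 10, vp_idx + 11))
            attempts = 0
            while (len(truth[name]) < config.n_planted_pirs
                   and attempts < 200):
                attempts += 1
                start = int(rng.integers(5, n - w - 5))
                span = set(range(start - 2, start + w + 2))
                if span & taken:
                    continue
                taken |= span
                enrich[start : start + w] = config.pir_enrichment
                truth[name].append((start, start + w))
        counts = np.vstack(
            [
                _negative_binomial(rng, mu * enrich, config.capture_dispersion)
                for _ in range(config.capture_replicates)
            ]
        )
        profiles.append(
            ViewpointProfile(viewpoint, fragments, counts, name=name)
        )
    return profiles, truth


# ---------------------------------------------------------------------------
# Expression calls
# ---------------------------------------------------------------------------

def _modulated(rng, config, direction=None) -> ConditionCall:
    direction = direction or ("up" if rng.random() < 0.5 else "down")
    fc = float(rng.uniform(*config.fc_range))
    return ConditionCall(True, direction, fc if direction == "up" else -fc)


def simulate_expression_calls(config: SimulationConfig, seed_offset: int = 4):
    """Per-gene knockdown calls realizing the regulation groups.

    Genes draw a truth group from the configured proportions; calls are
    generated to satisfy the group's defining pattern (for D, the double
    knockdown exceeds the strongest single effect), then each condition's
    modulated flag is flipped independently with call_error_rate (a flip to
    modulated invents a random direction and fold change). Returns
    (calls list, truth Series indexed by gene).
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    groups = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups], float)
    probs = probs / probs.sum()
    calls, truth = [], {}
    none_call = ConditionCall(False)
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        grp = groups[rng.choice(len(groups), p=probs)]
        truth[gene] = grp
        direction = "up" if rng.random() < 0.5 else "down"
        if grp == "A":
            si1 = _modulated(rng, config, direction)
            si2 = none_call
            si12 = (_modulated(rng, config, direction)
                    if rng.random() < 0.5 else none_call)
        elif grp == "B":
            si1 = none_call
            si2 = _modulated(rng, config, direction)
            si12 = (_modulated(rng, config, direction)
                    if rng.random() < 0.5 else none_call)
        elif grp == "C":
            si1 = si2 = none_call
            si12 = _modulated(rng, config, direction)
        elif grp == "D":
            si1 = _modulated(rng, config, direction)
            si2 = _modulated(rng, config, direction)
            stronger = max(abs(si1.fc), abs(si2.fc)) + float(rng.uniform(0.2, 1.0))
            si12 = ConditionCall(
                True, direction, stronger if direction == "up" else -stronger
            )
        else:
            si1 = si2 = si12 = none_call

        def corrupt(call: ConditionCall) -> ConditionCall:
            if rng.random() >= config.call_error_rate:
                return call
            if call.modulated:
                return none_call
            return _modulated(rng, config)

        calls.append(
            GeneRegulationCalls(gene, corrupt(si1), corrupt(si2), corrupt(si12))
        )
    return calls, pd.Series(truth)
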