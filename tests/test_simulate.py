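"""Synthetic generators: determinism, calibration of the planted structure,
and recovery of planted truth by the downstream modules."""

import numpy as np
import pytest

from tfparalog.annotation import annotate_elements, classify_overlap
from tfparalog.intervals import call_peaks_threshold
from tfparalog.motif import information_content, scan_at, score_window
from tfparalog.regulation import classify_genes
from tfparalog.simulate import (
    SimulationConfig,
    decoy_pwms,
    degenerate_pwm,
    plant_histone_landscape,
    plant_peaks,
    simulate_capture_profiles,
    simulate_expression_calls,
    simulate_genome,
    strict_pwm,
)

SMALL = dict(
    n_chroms=1,
    chrom_length=500_000,
    n_tss_per_chrom=12,
    tss_min_spacing=15_000,
    n_peaks={"PF1": 60, "PF2": 60, "F1F2": 80},
    n_cae=6,
    n_cie=5,
)


class TestMotifModels:
    def test_strict_has_higher_information(self):
        _, ic_strict = information_content(strict_pwm())
        _, ic_degen = information_content(degenerate_pwm())
        assert ic_strict > ic_degen

    def test_shared_core_consensus(self):
        assert strict_pwm().consensus() == degenerate_pwm().consensus()

    def test_decoys_are_deterministic(self):
        a = decoy_pwms(3)
        b = decoy_pwms(3)
        assert [p.id for p in a] == [p.id for p in b]


class TestGenome:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert g1 == g2
        assert [iv.start for iv in t1] == [iv.start for iv in t2]

    def test_gc_within_tolerance_at_1mb(self):
        cfg = SimulationConfig(seed=0, n_chroms=1, chrom_length=1_000_000,
                               gc=0.5, n_tss_per_chrom=10,
                               tss_min_spacing=15_000)
        genome, _ = simulate_genome(cfg)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_tss_min_spacing_respected(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        _, tss = simulate_genome(cfg)
        positions = [iv.start for iv in tss]
        gaps = np.diff(sorted(positions))
        assert (gaps >= cfg.tss_min_spacing).all()

    def test_infeasible_spacing_rejected(self):
        cfg = SimulationConfig(seed=0, n_chroms=1, chrom_length=50_000,
                               n_tss_per_chrom=40)
        with pytest.raises(ValueError):
            simulate_genome(cfg)


class TestPlantPeaks:
    def test_determinism(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        genome, _ = simulate_genome(cfg)
        out1 = plant_peaks(cfg, genome)
        out2 = plant_peaks(cfg, genome)
        assert out1[0] == out2[0]  # genome strings identical
        assert out1[5].equals(out2[5])  # truth tables identical

    def test_planted_motifs_are_at_recorded_positions(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        genome, _ = simulate_genome(cfg)
        genome, *_t, truth = plant_peaks(cfg, genome)
        for _, row in truth.head(50).iterrows():
            s = int(row["motif_start"])
            assert genome[row["chrom"]][s : s + len(row["motif"])] == row["motif"]

    def test_high_scoring_planted_sites_rediscovered_by_scan(self):
        # every planted motif whose own score ratio clears the 0.8 threshold
        # must be reported by scanning the genome around the site
        cfg = SimulationConfig(seed=2, **SMALL)
        genome, _ = simulate_genome(cfg)
        genome, *_t, truth = plant_peaks(cfg, genome)
        pwm = strict_pwm()
        pf2 = truth[truth["cls"] == "PF2"]
        found = missed = 0
        for _, row in pf2.iterrows():
            s = int(row["motif_start"])
            _, ratio = score_window(pwm, row["motif"])
            if ratio <= 0.8:
                continue
            window = genome[row["chrom"]][s - 20 : s + 27]
            hits = scan_at(pwm, window, row["chrom"], s - 20, 0.8)
            if any(o.interval.start == s for o in hits):
                found += 1
            else:
                missed += 1
        assert missed == 0 and found > 0

    def test_called_peaks_match_planted_classes_at_high_snr(self):
        # null ratio model keeps both factors above threshold at F1F2 sites
        cfg = SimulationConfig(seed=6, ratio_beta=0.0, ratio_noise_sd=0.0,
                               **SMALL)
        genome, _ = simulate_genome(cfg)
        genome, pa, pb, ta, tb, truth = plant_peaks(cfg, genome)
        called_a = call_peaks_threshold(ta, 50)
        called_b = call_peaks_threshold(tb, 50)
        classified = classify_overlap(called_a, called_b)
        agree = 0
        for _, row in truth.iterrows():
            center = int(row["center"]) + 5  # inside the summit plateau
            label = next(
                (
                    p.label
                    for p in classified
                    if p.interval.chrom == row["chrom"]
                    and p.interval.start <= center < p.interval.end
                ),
                None,
            )
            agree += label == row["cls"]
        assert agree / len(truth) >= 0.99

    def test_zero_beta_makes_ratio_independent_of_stringency(self):
        cfg = SimulationConfig(seed=5, ratio_beta=0.0, ratio_noise_sd=0.0,
                               **SMALL)
        genome, _ = simulate_genome(cfg)
        *_t, truth = plant_peaks(cfg, genome)
        f12 = truth[truth["cls"] == "F1F2"]
        assert np.allclose(f12["log_ratio"], 0.0)


class TestHistoneLandscape:
    def test_zero_dropout_exact_recovery(self):
        cfg = SimulationConfig(seed=3, mark_dropout=0.0, **SMALL)
        _, tss = simulate_genome(cfg)
        marks, truth = plant_histone_landscape(cfg, tss)
        elements = annotate_elements(
            tss, marks["k27ac"], marks["k4me1"], marks["k4me3"]
        )
        recovered = {}
        for e in elements:
            recovered[(e.interval.chrom,
                       (e.interval.start + e.interval.end) // 2)] = e.state
        hits = 0
        for _, row in truth.iterrows():
            state = recovered.get((row["chrom"], int(row["center"])))
            hits += state == row["state"]
        assert hits / len(truth) >= 0.98

    def test_k27ac_dropout_turns_cae_into_cie(self):
        cfg = SimulationConfig(seed=3, mark_dropout=0.0, **SMALL)
        _, tss = simulate_genome(cfg)
        marks, truth = plant_histone_landscape(cfg, tss)
        # remove K27ac everywhere: all cAE become cIE, all cAP become cIP
        from tfparalog.intervals import IntervalSet
        elements = annotate_elements(
            tss, IntervalSet(), marks["k4me1"], marks["k4me3"]
        )
        states = {e.state for e in elements}
        assert "cAE" not in states and "cAP" not in states
        assert "cIE" in states

    def test_recovery_decreases_with_dropout(self):
        def recovery(dropout, seed=8):
            cfg = SimulationConfig(seed=seed, mark_dropout=dropout, **SMALL)
            _, tss = simulate_genome(cfg)
            marks, truth = plant_histone_landscape(cfg, tss)
            elements = annotate_elements(
                tss, marks["k27ac"], marks["k4me1"], marks["k4me3"]
            )
            rec = {
                (e.interval.chrom, (e.interval.start + e.interval.end) // 2):
                e.state
                for e in elements
            }
            return np.mean([
                rec.get((row["chrom"], int(row["center"]))) == row["state"]
                for _, row in truth.iterrows()
            ])

        assert recovery(0.0) > recovery(0.4)


class TestCaptureSimulation:
    def test_null_profile_without_planting(self):
        cfg = SimulationConfig(seed=1, n_planted_pirs=0)
        profs, truth = simulate_capture_profiles(cfg, n_viewpoints=1,
                                                 planted=False)
        assert truth[profs[0].name] == []

    def test_counts_decay_with_distance(self):
        cfg = SimulationConfig(seed=1)
        profs, _ = simulate_capture_profiles(cfg, n_viewpoints=1,
                                             planted=False)
        p = profs[0]
        d = p.distances()
        mean = p.counts.mean(axis=0)
        near = mean[(d > 10_000) & (d < 100_000)].mean()
        far = mean[d > 300_000].mean()
        assert near > far

    def test_determinism(self):
        cfg = SimulationConfig(seed=2)
        a, _ = simulate_capture_profiles(cfg, n_viewpoints=2)
        b, _ = simulate_capture_profiles(cfg, n_viewpoints=2)
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))


class TestExpressionSimulation:
    def test_zero_error_full_recovery(self):
        cfg = SimulationConfig(seed=4, call_error_rate=0.0, n_genes=400)
        calls, truth = simulate_expression_calls(cfg)
        assigned = classify_genes(calls)
        agree = sum(a.group == truth[a.gene] for a in assigned)
        assert agree == len(assigned)

    def test_error_rate_recovery_bounded(self):
        # a gene survives unchanged with probability (1-e)^3; corrupted genes
        # may still classify correctly, so recovery sits in [(1-e)^3, 1)
        cfg = SimulationConfig(seed=4, call_error_rate=0.1, n_genes=1000)
        calls, truth = simulate_expression_calls(cfg)
        assigned = classify_genes(calls)
        rate = np.mean([a.group == truth[a.gene] for a in assigned])
        assert 0.9**3 - 0.05 <= rate < 1.0

    def test_group_proportions_match_config(self):
        cfg = SimulationConfig(seed=4, n_genes=2000)
        _, truth = simulate_expression_calls(cfg)
        observed = truth.value_counts(normalize=True)
        for grp, expected in cfg.group_proportions.items():
            se = np.sqrt(expected * (1 - expected) / len(truth))
            assert abs(observed.get(grp, 0.0) - expected) < 5 * se


class TestConfigIO:
    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=11, gc=0.45)
        cfg.to_json(tmp_path / "cfg.json")
        back = SimulationConfig.from_json(tmp_path / "cfg.json")
        assert back == cfg
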