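"""Viewpoint profile normalization, background fitting and PIR calling
(small-n unit checks; the 50-seed calibration runs live in the acceptance
suite)."""

import numpy as np
import pytest

from tfparalog.capture import (
    Pir,
    PirCallParams,
    ViewpointProfile,
    annotate_pirs,
    background_fit,
    call_pirs,
    delta_profile,
    normalize_profile,
    pir_stats,
    read_profile,
    write_pirs_bed,
    write_profile,
)
from tfparalog.intervals import GenomicInterval, IntervalSet, read_bed, write_bed
from tfparalog.simulate import SimulationConfig, simulate_capture_profiles

from conftest import make_set


def tiling_fragments(n, size=1000, chrom="chr1"):
    return [
        GenomicInterval(chrom, i * size, (i + 1) * size) for i in range(n)
    ]


def decay_profile(n=200, amplitude=100.0, d0=50_000.0, reps=1):
    frags = tiling_fragments(n)
    vp = frags[n // 2]
    d = np.abs(np.array([f.midpoint for f in frags]) - vp.midpoint)
    mu = amplitude / (1 + d / d0)
    return ViewpointProfile(vp, frags, np.tile(mu, (reps, 1)))


class TestProfileAndNormalization:
    def test_fragment_count_mismatch_rejected(self):
        frags = tiling_fragments(5)
        with pytest.raises(ValueError):
            ViewpointProfile(frags[0], frags, np.zeros((1, 4)))

    def test_totals_equalized_to_replicate_mean(self):
        frags = tiling_fragments(20)
        counts = np.vstack([np.full(20, 5.0), np.full(20, 15.0)])
        p = ViewpointProfile(frags[10], frags, counts)
        norm = normalize_profile(p, exclusion_zone=2)
        keep = np.ones(20, dtype=bool)
        keep[8:13] = False  # viewpoint plus 2 fragments each side
        totals = norm.counts[:, keep].sum(axis=1)
        assert totals[0] == pytest.approx(totals[1])
        assert totals.mean() == pytest.approx(
            counts[:, keep].sum(axis=1).mean()
        )

    def test_single_replicate_unchanged(self):
        p = decay_profile(reps=1)
        norm = normalize_profile(p)
        assert np.allclose(norm.counts, p.counts)

    def test_scaling_preserves_within_replicate_ratios(self, rng):
        frags = tiling_fragments(30)
        counts = rng.integers(1, 50, size=(2, 30)).astype(float)
        p = ViewpointProfile(frags[15], frags, counts)
        norm = normalize_profile(p)
        for r in range(2):
            assert np.allclose(
                norm.counts[r] / norm.counts[r][0], counts[r] / counts[r][0]
            )

    def test_zero_total_replicate_named_in_error(self):
        frags = tiling_fragments(20)
        counts = np.vstack([np.full(20, 5.0), np.zeros(20)])
        p = ViewpointProfile(frags[10], frags, counts)
        with pytest.raises(ValueError, match="replicate 1"):
            normalize_profile(p)


class TestBackgroundFit:
    def test_nonincreasing_input_is_fixed_point(self):
        p = decay_profile(n=200)
        expected = background_fit(p)
        usable = np.isfinite(expected)
        assert np.allclose(expected[usable], p.counts.mean(axis=0)[usable])

    def test_recovers_pure_decay(self):
        p = decay_profile(n=300)
        expected = background_fit(p)
        usable = np.isfinite(expected)
        mean = p.counts.mean(axis=0)
        assert np.abs(expected[usable] - mean[usable]).max() < 1e-6

    def test_spike_leaves_positive_residual(self):
        p = decay_profile(n=300)
        counts = p.counts.copy()
        counts[0, 200:205] *= 4  # narrow planted interaction
        spiked = ViewpointProfile(p.viewpoint, p.fragments, counts)
        expected = background_fit(spiked)
        resid = spiked.counts.mean(axis=0)[200:205] - expected[200:205]
        assert (resid > 0).all()
        # fit stays near the local decay level, not the spike level
        clean = background_fit(p)
        assert np.abs(expected[200:205] - clean[200:205]).max() < (
            0.5 * spiked.counts.mean(axis=0)[200:205].min()
        )

    def test_short_side_skipped_with_warning(self):
        p = decay_profile(n=30)
        with pytest.warns(UserWarning, match="fragments"):
            expected = background_fit(p, min_side_fragments=20)
        assert np.isnan(expected).any()


class TestCallPirs:
    def test_too_few_permutations_refused(self):
        p = decay_profile()
        with pytest.raises(ValueError, match="n_permutations"):
            call_pirs(p, PirCallParams(n_permutations=50))

    def test_infinite_qwr_silences_everything(self):
        cfg = SimulationConfig(seed=0)
        profs, _ = simulate_capture_profiles(cfg, n_viewpoints=1)
        p = normalize_profile(profs[0])
        assert call_pirs(p, PirCallParams(q_wr=np.inf), seed=0) == []

    def test_planted_interactions_recovered(self):
        cfg = SimulationConfig(seed=11)
        profs, truth = simulate_capture_profiles(cfg, n_viewpoints=1)
        p = normalize_profile(profs[0])
        pirs = call_pirs(p, PirCallParams(), seed=11)
        assert len(pirs) >= 3  # most of the 4 planted regions found
        spans = [(pir.interval.start, pir.interval.end) for pir in pirs]
        for s, e in spans:
            assert e > s

    def test_pirs_disjoint_and_whole_fragments(self):
        cfg = SimulationConfig(seed=3)
        profs, _ = simulate_capture_profiles(cfg, n_viewpoints=1)
        p = normalize_profile(profs[0])
        pirs = call_pirs(p, PirCallParams(), seed=3)
        edges = {(f.start, f.end) for f in p.fragments}
        starts = {f.start for f in p.fragments}
        ends = {f.end for f in p.fragments}
        prev_end = None
        for pir in sorted(pirs, key=lambda x: x.interval.start):
            assert pir.interval.start in starts
            assert pir.interval.end in ends
            if prev_end is not None:
                assert pir.interval.start >= prev_end
            prev_end = pir.interval.end

    def test_invariant_params_validated(self):
        with pytest.raises(ValueError):
            PirCallParams(alpha_fdr=0.0)
        with pytest.raises(ValueError):
            PirCallParams(w_size=4)
        with pytest.raises(ValueError):
            PirCallParams(q_wr=-1)


class TestStatsAndAnnotation:
    def _pir(self, start, end, dist, chrom="chr1"):
        return Pir(GenomicInterval(chrom, start, end), 3.0, dist, 5)

    def test_median_counts_and_layout(self):
        vp = GenomicInterval("chr1", 500_000, 501_000)
        pirs = {
            "v1": [self._pir(600_000, 610_000, 104_500)],
            "v2": [self._pir(100_000, 110_000, 395_500),
                   self._pir(200_000, 210_000, 295_500),
                   self._pir(700_000, 710_000, 204_500),
                   self._pir(800_000, 810_000, 304_500)],
            "v3": [self._pir(550_000 + 20_000 * i, 560_000 + 20_000 * i, 0)
                   for i in range(9)],
        }
        stats = pir_stats(pirs, {k: vp for k in pirs})
        assert stats["median_pirs_per_viewpoint"] == 4.0
        assert stats["layout_per_viewpoint"]["v1"] == "downstream"
        assert stats["layout_per_viewpoint"]["v2"] == "both"
        assert stats["layout_per_viewpoint"]["v3"] == "downstream"

    def test_single_downstream_pir_distance(self):
        vp = GenomicInterval("chr1", 0, 1000)
        pir = Pir(GenomicInterval("chr1", 150_000, 151_000), 2.0,
                  abs(150_500 - 500), 1)
        stats = pir_stats({"v": [pir]}, {"v": vp})
        assert stats["median_distance"] == 150_000.0
        assert stats["layout_counts"]["downstream"] == 1

    def test_nested_fraction_toy(self):
        pirs = [self._pir(i * 10_000, i * 10_000 + 5_000, 0) for i in range(4)]
        atac = make_set(
            [(1_000, 1_200), (11_000, 11_200), (21_000, 21_200),
             (80_000, 80_200), (90_000, 90_200)]
        )
        cae = make_set(
            [(900, 1_300), (10_900, 11_300), (20_900, 21_300), (79_000, 81_000)]
        )
        tf = make_set([(1_050, 1_100), (11_050, 11_100)])
        out = annotate_pirs(pirs, atac, cae, tf)
        assert out["frac_pirs_with_atac"] == pytest.approx(3 / 4)
        assert out["frac_atac_in_pir_with_cae"] == pytest.approx(3 / 3)
        assert out["frac_cae_atac_bound_by_tf"] == pytest.approx(2 / 3)

    def test_empty_annotations_zero_first_level(self):
        pirs = [self._pir(0, 5_000, 0)]
        out = annotate_pirs(pirs, IntervalSet(), IntervalSet(), IntervalSet())
        assert out["frac_pirs_with_atac"] == 0.0
        assert out["frac_atac_in_pir_with_cae"] is None

    def test_empty_pirs_undefined(self):
        out = annotate_pirs([], IntervalSet(), IntervalSet(), IntervalSet())
        assert out["frac_pirs_with_atac"] is None


class TestDeltaProfile:
    def test_identical_conditions_zero(self):
        p = decay_profile()
        assert np.allclose(delta_profile(p, p), 0.0)

    def test_antisymmetric(self, rng):
        frags = tiling_fragments(50)
        a = ViewpointProfile(frags[25], frags,
                             rng.integers(0, 40, (2, 50)).astype(float))
        b = ViewpointProfile(frags[25], frags,
                             rng.integers(0, 40, (2, 50)).astype(float))
        assert np.allclose(delta_profile(a, b), -delta_profile(b, a))

    def test_planted_gain_localized(self):
        base = decay_profile(n=200)
        gained = base.counts.copy()
        gained[0, 150:155] *= 2
        a = ViewpointProfile(base.viewpoint, base.fragments, gained)
        delta = delta_profile(a, base)
        assert (delta[150:155] > 0).all()
        outside = np.delete(delta, slice(150, 155))
        assert np.allclose(outside, 0.0)

    def test_mismatched_fragment_maps_rejected(self):
        a = decay_profile(n=100)
        b = decay_profile(n=120)
        with pytest.raises(ValueError, match="fragment maps"):
            delta_profile(a, b)


class TestProfileIO:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=5)
        profs, _ = simulate_capture_profiles(cfg, n_viewpoints=1)
        p = profs[0]
        write_profile(p, tmp_path / "prof.tsv")
        write_bed(IntervalSet(p.fragments), tmp_path / "frags.bed")
        back = read_profile(
            tmp_path / "prof.tsv", read_bed(tmp_path / "frags.bed"), p.viewpoint
        )
        assert np.allclose(back.counts, p.counts)

    def test_pir_bed_written(self, tmp_path):
        pir = Pir(GenomicInterval("chr1", 100, 5_000), 3.21, 10_000, 4)
        write_pirs_bed([pir], tmp_path / "pirs.bed")
        line = (tmp_path / "pirs.bed").read_text().strip()
        assert line.split("\t")[4] == "3.210"
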