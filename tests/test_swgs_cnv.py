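"""sWGS stage: GC correction, log2 ratios, segmentation, focal calls."""

import numpy as np
import pytest

import plasmacnv as pc
from plasmacnv.genome_model import GenomicBin, make_bins
from plasmacnv.swgs_cnv import (
    Log2RatioProfile,
    call_focal_amplification,
    gc_correct,
    log2_ratio,
    profile_pipeline,
    segment,
)
from plasmacnv.synthetic_cfdna import assign_gc_fractions


def _flat_profile(bins, value=0.0, sample_id="s"):
    return Log2RatioProfile(sample_id, tuple(bins), np.full(len(bins), value))


@pytest.fixture(scope="module")
def gc_bins(bins):
    return assign_gc_fractions(bins, seed=9)


class TestGcCorrect:
    def test_without_bias_correction_is_near_noop(self, gc_bins):
        prof = pc.simulate_bin_counts(
            pc.TumorGenotype(), pc.SimulationConfig(seed=21), gc_bins
        )
        corrected, _ = gc_correct(prof, gc_bins)
        ok = np.isfinite(corrected)
        rel = np.abs(corrected[ok] - prof.counts[ok]) / np.maximum(prof.counts[ok], 1)
        assert np.median(rel) < 0.01

    def test_quadratic_bias_removed(self, gc_bins):
        prof = pc.simulate_bin_counts(
            pc.TumorGenotype(),
            pc.SimulationConfig(seed=21, gc_bias_coeffs=(1.2, -6.0)),
            gc_bins,
        )
        gc = np.array([b.gc_fraction for b in gc_bins])
        corrected, _ = gc_correct(prof, gc_bins)
        ok = np.isfinite(corrected)
        raw_rho = np.corrcoef(prof.counts[ok], gc[ok])[0, 1]
        post_rho = np.corrcoef(corrected[ok], gc[ok])[0, 1]
        assert abs(raw_rho) > 0.3  # the injected bias is real
        assert abs(post_rho) < 0.05

    def test_gc_outliers_excluded_with_reason(self, toy_build):
        bins = [
            GenomicBin("c1", 0, 10**6, 0.45),
            GenomicBin("c1", 10**6, 2 * 10**6, 0.45),
            GenomicBin("c1", 2 * 10**6, 25 * 10**5, 0.45),
            GenomicBin("c2", 0, 10**6, 0.95),  # outside [0.3, 0.6]
        ]
        prof = pc.simulate_bin_counts(
            pc.TumorGenotype(), pc.SimulationConfig(total_reads=10_000, seed=0), bins
        )
        corrected, reasons = gc_correct(prof, bins)
        assert np.isnan(corrected[3]) and reasons[3] == "gc-outlier"

    def test_missing_gc_rejected(self, toy_build):
        bins = make_bins(toy_build, 1_000_000)  # no gc_fraction
        prof = pc.simulate_bin_counts(
            pc.TumorGenotype(), pc.SimulationConfig(total_reads=10_000, seed=0), bins
        )
        with pytest.raises(ValueError, match="GC"):
            gc_correct(prof, bins)


class TestLog2Ratio:
    def test_sample_identical_to_control_is_zero(self, toy_build):
        bins = make_bins(toy_build, 1_000_000)
        counts = np.array([100.0, 200.0, 50.0, 150.0])
        prof = log2_ratio(counts, [counts.copy()], bins)
        assert np.allclose(prof.log2, 0.0)

    def test_noise_free_focal_ratio_matches_forward_model(
        self, bins, noise_free_control, fgfr1
    ):
        wstart = (fgfr1[1] // 10**6) * 10**6
        geno = pc.TumorGenotype(
            (pc.CnaEvent("chr8", wstart, wstart + 10**6, 16),)
        )
        s = pc.simulate_bin_counts(
            geno, pc.SimulationConfig(tumor_fraction=0.05, noise=False, seed=3), bins
        )
        prof, _ = profile_pipeline(s, [noise_free_control])
        idx = next(
            i for i, b in enumerate(bins) if b.chrom == "chr8" and b.start == wstart
        )
        # log2(1 - 0.05 + 0.05*8) = 0.4330
        assert prof.log2[idx] == pytest.approx(0.433, abs=0.005)

    def test_empty_panel_rejected(self, toy_build):
        bins = make_bins(toy_build, 1_000_000)
        with pytest.raises(ValueError, match="empty"):
            log2_ratio(np.ones(4), [], bins)

    def test_zero_control_bins_flagged(self, toy_build):
        bins = make_bins(toy_build, 1_000_000)
        control = np.array([100.0, 0.0, 100.0, 100.0])
        prof = log2_ratio(np.full(4, 100.0), [control], bins)
        assert np.isnan(prof.log2[1])
        assert prof.exclusion_reasons[1] == "zero-control"

    def test_control_scored_against_own_panel_centers_at_zero(
        self, bins, bin_panel
    ):
        sample = bin_panel[0]
        prof = log2_ratio(
            sample.counts.astype(float),
            [p.counts.astype(float) for p in bin_panel],
            bins,
            recenter=False,
        )
        assert abs(np.nanmedian(prof.log2)) < 0.02


class TestSegmentation:
    def test_flat_profile_gives_one_segment_per_chromosome(self):
        bins = [
            GenomicBin(c, i * 10**6, (i + 1) * 10**6)
            for c in ("c1", "c2")
            for i in range(10)
        ]
        segs = segment(_flat_profile(bins))
        assert [(s.chrom, s.n_bins, s.state_label) for s in segs] == [
            ("c1", 10, "balanced"),
            ("c2", 10, "balanced"),
        ]

    def test_chromosome_below_min_bins_skipped(self, toy_build):
        bins = make_bins(toy_build, 1_000_000)  # c2 has a single bin
        segs = segment(_flat_profile(bins))
        assert [s.chrom for s in segs] == ["c1"]

    def test_noiseless_step_found_exactly(self):
        bins = [GenomicBin("c1", i * 10**6, (i + 1) * 10**6) for i in range(100)]
        x = np.r_[np.zeros(50), np.full(50, 0.5)]
        segs = segment(Log2RatioProfile("s", tuple(bins), x))
        assert len(segs) == 2
        assert segs[0].end == 50 * 10**6 and segs[1].start == 50 * 10**6
        assert segs[0].mean_log2 == pytest.approx(0.0)
        assert segs[1].mean_log2 == pytest.approx(0.5)
        assert segs[1].state_label == "gain"

    def test_segment_means_reconstruct_profile_mean(self, bins, bin_panel):
        geno = pc.default_tumor_genotype(focal_amp=False)
        s = pc.simulate_bin_counts(
            geno, pc.SimulationConfig(tumor_fraction=0.2, seed=31), bins
        )
        prof, segs = profile_pipeline(s, bin_panel)
        used = np.isfinite(prof.log2)
        weighted = sum(x.mean_log2 * x.n_bins for x in segs) / sum(
            x.n_bins for x in segs
        )
        assert weighted == pytest.approx(float(prof.log2[used].mean()), abs=1e-9)

    def test_segments_ordered_disjoint_exhaustive(self, bins, bin_panel):
        s = pc.simulate_bin_counts(
            pc.default_tumor_genotype(focal_amp=True),
            pc.SimulationConfig(tumor_fraction=0.3, seed=32),
            bins,
        )
        prof, segs = profile_pipeline(s, bin_panel)
        n_used = int(np.isfinite(prof.log2).sum())
        assert sum(x.n_bins for x in segs) == n_used
        by_chrom = {}
        for x in segs:
            by_chrom.setdefault(x.chrom, []).append(x)
        for chrom, ss in by_chrom.items():
            ss.sort(key=lambda x: x.start)
            assert all(a.end <= b.start for a, b in zip(ss, ss[1:]))

    def test_interior_breakpoint_localized(self, build, bins, bin_panel, fgfr1):
        # 4-copy gain from 120 Mb to 3qter plus the focal amp, tf 0.2:
        # the 3q breakpoint should land within +-2 bins in >= 90% of runs
        wstart = (fgfr1[1] // 10**6) * 10**6
        hits = 0
        for rep in range(25):
            geno = pc.TumorGenotype(
                (
                    pc.CnaEvent(
                        "chr3", 120_000_000, build.chromosome("chr3").length, 4
                    ),
                    pc.CnaEvent("chr8", wstart, wstart + 10**6, 16),
                )
            )
            s = pc.simulate_bin_counts(
                geno, pc.SimulationConfig(tumor_fraction=0.2, seed=8_000 + rep), bins
            )
            _, segs = profile_pipeline(s, bin_panel)
            starts = [x.start for x in segs if x.chrom == "chr3"]
            hits += any(abs(x - 120_000_000) <= 2_000_000 for x in starts)
        assert hits >= 23  # 92%+


class TestFocalCall:
    def test_flat_profile_not_called(self, bins, fgfr1):
        call = call_focal_amplification(_flat_profile(bins), fgfr1)
        assert not call.called

    def test_noise_free_focal_called(self, bins, noise_free_control, fgfr1):
        wstart = (fgfr1[1] // 10**6) * 10**6
        geno = pc.TumorGenotype((pc.CnaEvent("chr8", wstart, wstart + 10**6, 16),))
        s = pc.simulate_bin_counts(
            geno, pc.SimulationConfig(tumor_fraction=0.05, noise=False, seed=3), bins
        )
        prof, segs = profile_pipeline(s, [noise_free_control])
        call = call_focal_amplification(prof, fgfr1, segs)
        assert call.called
        assert call.criteria["amplified_run_bp"] <= 20e6

    def test_whole_arm_gain_not_called_focal(
        self, build, bins, noise_free_control, fgfr1
    ):
        arm_start, arm_end = 0, build.chromosome("chr8").centromere
        geno = pc.TumorGenotype((pc.CnaEvent("chr8", arm_start, arm_end, 3),))
        s = pc.simulate_bin_counts(
            geno, pc.SimulationConfig(tumor_fraction=0.3, noise=False, seed=3), bins
        )
        prof, segs = profile_pipeline(s, [noise_free_control])
        call = call_focal_amplification(prof, fgfr1, segs)
        assert not call.called
        assert not call.criteria["meets_delta"]  # gene tracks the arm background

    @pytest.mark.parametrize(
        "tf,copies,expected",
        [
            (0.0035, 7, False),  # ~7 copies at AF 0.35%: below detection
            (0.0035, 24, False),
            (0.0086, 7, False),
            (0.0086, 24, True),  # high-level amp detectable below 1% AF
            (0.05, 7, True),
            (0.05, 24, True),
        ],
    )
    def test_detection_limit_grid(
        self, bins, noise_free_control, fgfr1, tf, copies, expected
    ):
        wstart = (fgfr1[1] // 10**6) * 10**6
        geno = pc.TumorGenotype(
            (pc.CnaEvent("chr8", wstart, wstart + 10**6, copies),)
        )
        s = pc.simulate_bin_counts(
            geno, pc.SimulationConfig(tumor_fraction=tf, noise=False, seed=3), bins
        )
        prof, segs = profile_pipeline(s, [noise_free_control])
        assert call_focal_amplification(prof, fgfr1, segs).called is expected

    def test_gene_outside_build_rejected(self, bins):
        with pytest.raises(ValueError):
            call_focal_amplification(
                _flat_profile(bins), ("chrZ", 0, 10**6)
            )
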