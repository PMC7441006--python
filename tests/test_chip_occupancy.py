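import numpy as np
import pytest

from sigstrat.chip_occupancy import (
    AnnotationScheme,
    Normalization,
    SpikeInPair,
    annotate_peaks,
    interval_auc,
    occupancy_fold_change,
    occupancy_report,
    peak_overlap,
    proportional_occupancy,
    spike_in_factor,
)
from sigstrat.cohort_io import CoverageTrack, Interval, IntervalSet
from sigstrat.synthetic_data import ChipSimConfig, simulate_chip


def auc_per_base_oracle(track: CoverageTrack, interval: Interval) -> float:
    """Brute-force per-base summation over the interval."""
    total = 0.0
    if interval.chrom not in track.runs:
        return 0.0
    starts, ends, depths = track.runs[interval.chrom]
    for pos in range(interval.start, interval.end):
        for s, e, d in zip(starts, ends, depths):
            if s <= pos < e:
                total += d
                break
    return total


class TestIntervalAuc:
    def test_rectangle(self):
        track = CoverageTrack.from_records([("chr1", 0, 100, 2.0)])
        assert interval_auc(track, Interval("chr1", 10, 20)) == pytest.approx(20.0)

    def test_disjoint_interval_zero(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 5.0)])
        assert interval_auc(track, Interval("chr1", 100, 200)) == 0.0

    def test_absent_chromosome_warns_zero(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 5.0)])
        with pytest.warns(UserWarning):
            assert interval_auc(track, Interval("chrX", 0, 10)) == 0.0

    def test_random_tracks_match_per_base_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pos, records = 0, []
            for _ in range(50):
                pos += int(rng.integers(0, 20))
                width = int(rng.integers(1, 30))
                records.append(("chr1", pos, pos + width, float(rng.integers(0, 10))))
                pos += width
            track = CoverageTrack.from_records(records)
            start = int(rng.integers(0, pos))
            interval = Interval("chr1", start, start + int(rng.integers(1, 400)))
            assert interval_auc(track, interval) == pytest.approx(
                auc_per_base_oracle(track, interval)
            )


class TestProportionalOccupancy:
    def _toy(self):
        # 5 peaks with flat depths 1..5, width 10 each
        records = [("chr1", i * 100, i * 100 + 10, float(i + 1)) for i in range(5)]
        track = CoverageTrack.from_records(records)
        peaks = IntervalSet(
            [Interval("chr1", i * 100, i * 100 + 10, f"p{i}") for i in range(5)]
        )
        return track, peaks

    def test_single_peak_is_whole(self):
        track = CoverageTrack.from_records([("chr1", 0, 10, 3.0)])
        peaks = IntervalSet([Interval("chr1", 0, 10)])
        assert proportional_occupancy(track, peaks, peaks[0]) == pytest.approx(1.0)

    def test_uniform_scaling_invariance(self):
        track, peaks = self._toy()
        before = proportional_occupancy(track, peaks, peaks[2])
        after = proportional_occupancy(track.scaled(7.3), peaks, peaks[2])
        assert before == pytest.approx(after)

    def test_hand_summed_ratio(self):
        track, peaks = self._toy()
        # AUCs are 10,20,30,40,50 -> total 150; peak 2 contributes 30/150
        assert proportional_occupancy(track, peaks, peaks[2]) == pytest.approx(30 / 150)

    def test_shares_sum_to_one(self):
        track, peaks = self._toy()
        shares = [proportional_occupancy(track, peaks, p) for p in peaks]
        assert sum(shares) == pytest.approx(1.0, abs=1e-9)

    def test_occupancy_report_shares_sum_to_one(self, chip_sim):
        records = occupancy_report(chip_sim.tracks, chip_sim.consensus_peaks)
        for condition in chip_sim.tracks:
            total = sum(r.proportional for r in records if r.condition == condition)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestSpikeInFactor:
    def test_identical_reads_factor_one(self):
        a = SpikeInPair("a", 100, 500)
        b = SpikeInPair("b", 200, 500)
        assert spike_in_factor(a, b) == pytest.approx(1.0)

    def test_doubled_spike_reads_halve_factor(self):
        ref = SpikeInPair("ctrl", 100, 500)
        sample = SpikeInPair("kd", 100, 1000)
        assert spike_in_factor(sample, ref) == pytest.approx(0.5)

    def test_three_condition_closed_form(self):
        ref = SpikeInPair("ctrl", 100, 600)
        for reads in (200, 300, 1200):
            s = SpikeInPair("x", 100, reads)
            assert spike_in_factor(s, ref) == pytest.approx(600 / reads)

    def test_zero_reference_reads_rejected(self):
        with pytest.raises(ValueError):
            SpikeInPair("bad", 100, 0)


class TestOccupancyFoldChange:
    def test_case_equal_control_fold_one(self):
        track = CoverageTrack.from_records(
            [("chr1", 0, 10, 3.0), ("chr1", 100, 110, 5.0)]
        )
        peaks = IntervalSet([Interval("chr1", 0, 10), Interval("chr1", 100, 110)])
        folds, mean = occupancy_fold_change([track], track, peaks, peaks[0])
        assert folds == [pytest.approx(1.0)]
        assert mean == pytest.approx(1.0)

    def test_depth_rescaling_invariance_proportional(self, chip_sim):
        cases = [chip_sim.tracks[f"kd{i}"] for i in (1, 2, 3)]
        _, mean1 = occupancy_fold_change(
            cases, chip_sim.tracks["control"], chip_sim.consensus_peaks, chip_sim.target
        )
        _, mean2 = occupancy_fold_change(
            [t.scaled(3.0) for t in cases],
            chip_sim.tracks["control"].scaled(0.5),
            chip_sim.consensus_peaks,
            chip_sim.target,
        )
        assert mean1 == pytest.approx(mean2)

    def test_spikein_preserving_rescale_invariance(self, chip_sim):
        """Scaling a case's depths and its spike-in factor inversely cancels."""
        cases = [chip_sim.tracks["kd1"]]
        pairs = [chip_sim.spikeins["kd1"]]
        ctrl = chip_sim.spikeins["control"]
        _, mean1 = occupancy_fold_change(
            cases, chip_sim.tracks["control"], chip_sim.consensus_peaks,
            chip_sim.target, Normalization.spike_in, pairs, ctrl,
        )
        scaled_pair = SpikeInPair("kd1", pairs[0].primary_reads, pairs[0].reference_reads * 2)
        _, mean2 = occupancy_fold_change(
            [cases[0].scaled(2.0)], chip_sim.tracks["control"],
            chip_sim.consensus_peaks, chip_sim.target,
            Normalization.spike_in, [scaled_pair], ctrl,
        )
        assert mean1 == pytest.approx(mean2)

    def test_planted_redistribution_recovered(self):
        """Mean proportional fold at the target ~ phi over seeded replicates."""
        folds = []
        for seed in range(20):
            sim = simulate_chip(ChipSimConfig(gamma=0.7, phi=1.3, seed=seed))
            cases = [sim.tracks[f"kd{i}"] for i in (1, 2, 3)]
            _, mean = occupancy_fold_change(
                cases, sim.tracks["control"], sim.consensus_peaks, sim.target
            )
            folds.append(mean)
        assert np.mean(folds) == pytest.approx(1.3, rel=0.05)

    def test_planted_target_down_fold_below_one(self):
        # a positively regulated target: knockdown lowers its share too
        sim = simulate_chip(ChipSimConfig(gamma=0.7, phi=0.85, seed=5))
        cases = [sim.tracks[f"kd{i}"] for i in (1, 2, 3)]
        _, mean = occupancy_fold_change(
            cases, sim.tracks["control"], sim.consensus_peaks, sim.target
        )
        assert mean < 1.0


def overlap_oracle(set_a, set_b, min_bp):
    """Quadratic all-pairs overlap check."""
    def shared(q, subj):
        return [
            any(
                s.chrom == p.chrom and min(p.end, s.end) - max(p.start, s.start) >= min_bp
                for s in subj
            )
            for p in q
        ]
    fa = shared(set_a, set_b)
    fb = shared(set_b, set_a)
    return (np.mean(fa), np.mean(fb), sum(fa) + sum(fb))


class TestPeakOverlap:
    def test_identical_sets(self):
        peaks = IntervalSet([Interval("chr1", 0, 10), Interval("chr2", 5, 25)])
        fa, fb, count = peak_overlap(peaks, peaks)
        assert fa == fb == 1.0

    def test_disjoint_sets(self):
        a = IntervalSet([Interval("chr1", 0, 10)])
        b = IntervalSet([Interval("chr1", 50, 60)])
        assert peak_overlap(a, b)[:2] == (0.0, 0.0)

    def test_random_pairs_match_all_pairs_oracle(self):
        rng = np.random.default_rng(2)

        def random_set(n):
            out = []
            for _ in range(n):
                start = int(rng.integers(0, 50_000))
                out.append(
                    Interval(f"chr{rng.integers(1, 3)}", start, start + int(rng.integers(1, 500)))
                )
            return IntervalSet(out)

        a, b = random_set(200), random_set(200)
        for min_bp in (1, 50):
            got = peak_overlap(a, b, min_overlap_bp=min_bp)
            want = overlap_oracle(a, b, min_bp)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])
            assert got[2] == want[2]


class TestAnnotatePeaks:
    def test_promoter_proximal_by_midpoint(self):
        peaks = IntervalSet([Interval("chr1", 0, 1000)])  # midpoint 500
        counts = annotate_peaks(peaks, [("chr1", 1000)], IntervalSet(), AnnotationScheme(2000))
        assert counts["promoter_proximal"] == 1

    def test_unannotated_chromosome_intergenic(self):
        peaks = IntervalSet([Interval("chrUn", 0, 100)])
        counts = annotate_peaks(peaks, [("chr1", 0)], IntervalSet([Interval("chr1", 0, 10)]))
        assert counts["intergenic"] == 1

    def test_thirty_peak_fixture_matches_nearest_distance_oracle(self):
        rng = np.random.default_rng(3)
        tss = [("chr1", int(p)) for p in rng.integers(0, 100_000, 8)]
        genes = IntervalSet(
            [
                Interval("chr1", int(s), int(s) + int(rng.integers(500, 5000)))
                for s in rng.integers(0, 100_000, 10)
            ]
        )
        peaks = IntervalSet(
            [
                Interval("chr1", int(s), int(s) + int(rng.integers(100, 1000)))
                for s in rng.integers(0, 100_000, 30)
            ]
        )
        scheme = AnnotationScheme(tss_window=2000)
        counts = annotate_peaks(peaks, tss, genes, scheme)

        expected = {"promoter_proximal": 0, "genic_nonpromoter": 0, "intergenic": 0}
        for p in peaks:
            mid = (p.start + p.end) / 2
            if min(abs(mid - pos) for _, pos in tss) <= scheme.tss_window:
                expected["promoter_proximal"] += 1
            elif any(min(p.end, g.end) - max(p.start, g.start) > 0 for g in genes):
                expected["genic_nonpromoter"] += 1
            else:
                expected["intergenic"] += 1
        assert counts == expected
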