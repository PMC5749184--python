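import math

import numpy as np
import pytest

from scduoqc.cnv_profiling import (
    CbsParams,
    CopyNumberProfile,
    arc_statistic_max,
    average_profiles,
    cbs_segment,
    cluster_profiles,
    normalize_to_log2,
    profile_correlation,
    write_segments,
)
from scduoqc.io_formats import BinnedCounts, GenomeBins
from scduoqc.synthetic_data import SimTruth, make_cn_profile, simulate_wgs_bins


def brute_force_arc_max(values, min_width):
    """Independent O(n^2) double-loop oracle for the best arc split."""
    n = len(values)
    best, best_ij = -np.inf, (-1, -1)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if not (min_width <= k <= n - min_width):
                continue
            if not (i == 0 or i >= min_width):
                continue
            if not (j == n or n - j >= min_width):
                continue
            arc = values[i:j]
            comp = np.concatenate([values[:i], values[j:]])
            stat = abs(arc.mean() - comp.mean()) / math.sqrt(1 / k + 1 / (n - k))
            if stat > best:
                best, best_ij = stat, (i, j)
    i, j = best_ij
    if j == n and i > 0:
        best_ij = (0, i)  # complementary arc: identical split
    return best, best_ij


def profile_from(values, bin_size=1_000_000, chrom="chr1"):
    bins = GenomeBins.uniform({chrom: len(values) * bin_size}, bin_size=bin_size)
    return CopyNumberProfile(bins, np.asarray(values, dtype=float))


class TestNormalizeToLog2:
    def _counts(self, counts):
        bins = GenomeBins.uniform({"chr1": len(counts) * 1_000_000})
        return BinnedCounts(bins, np.asarray(counts))

    def test_flat_profile_near_zero(self):
        prof = normalize_to_log2(self._counts([100] * 10))
        assert np.allclose(prof.log2_ratio, 0.0)

    def test_double_mean_bin_is_one(self):
        prof = normalize_to_log2(self._counts([100, 100, 100, 100, 100, 200]))
        mean = np.mean([100, 100, 100, 100, 100, 200])
        assert prof.log2_ratio[-1] == pytest.approx(math.log2(200 / mean))

    def test_exact_log2_one(self):
        # one bin at exactly 2x the usable-bin mean
        counts = [50, 150, 100, 100, 100, 100]  # mean 100; none at 200 yet
        counts[2] = 100
        prof = normalize_to_log2(self._counts([60, 140, 100, 100, 100, 200]))
        x = np.array([60, 140, 100, 100, 100, 200], dtype=float)
        assert prof.log2_ratio[-1] == pytest.approx(math.log2(200 / x.mean()))

    def test_zero_bins_masked(self):
        prof = normalize_to_log2(self._counts([0, 100, 100]))
        assert math.isnan(prof.log2_ratio[0])
        assert not np.isnan(prof.log2_ratio[1:]).any()

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            normalize_to_log2(self._counts([0, 0, 0]))

    def test_planted_gain_recovers_log2_ratio(self):
        # cn=3 region on diploid background at deep coverage
        bins, cn = make_cn_profile(2000, [(500, 1000, 3)])
        truth = SimTruth(bins=bins, cn_profile=cn, bias_sigma=0.0, seed=17)
        cells, _ = simulate_wgs_bins(truth, 1000.0, 1)
        prof = normalize_to_log2(cells[0])
        # overall mean cn = 2.25 -> region log2(3/2.25), background log2(2/2.25)
        region = np.nanmean(prof.log2_ratio[500:1000])
        background = np.nanmean(prof.log2_ratio[:500])
        assert region - background == pytest.approx(math.log2(1.5), abs=0.02)

    def test_gc_correction_removes_gc_trend(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.3, 0.6, size=1000)
        base = 500 * (1 + 2 * (gc - 0.45))  # strong linear GC effect
        counts = rng.poisson(base)
        bins = GenomeBins.uniform({"chr1": 1000 * 1_000_000})
        bc = BinnedCounts(bins, counts)
        raw = normalize_to_log2(bc)
        corrected = normalize_to_log2(bc, gc_per_bin=gc)
        r_raw = np.corrcoef(gc, raw.log2_ratio)[0, 1]
        r_cor = np.corrcoef(gc, corrected.log2_ratio)[0, 1]
        assert abs(r_cor) < abs(r_raw) / 3


class TestArcStatistic:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        values = rng.normal(size=n)
        got_stat, i, j = arc_statistic_max(values, 3)
        want_stat, (wi, wj) = brute_force_arc_max(values, 3)
        assert got_stat == pytest.approx(want_stat, rel=1e-12)
        assert (i, j) == (wi, wj)

    def test_location_shift_leaves_statistic(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=40)
        s0, i0, j0 = arc_statistic_max(values, 3)
        s1, i1, j1 = arc_statistic_max(values + 5.0, 3)
        assert s1 == pytest.approx(s0, rel=1e-9)
        assert (i0, j0) == (i1, j1)


class TestCbsSegment:
    def test_constant_single_segment(self):
        prof = cbs_segment(profile_from([0.3] * 30), CbsParams(n_perm=100, seed=1))
        assert prof.segments == [(0, 30, pytest.approx(0.3))]

    def test_noiseless_step(self):
        values = [0.0] * 50 + [1.0] * 50
        prof = cbs_segment(profile_from(values), CbsParams(n_perm=200, seed=2))
        assert len(prof.segments) == 2
        (s0, e0, m0), (s1, e1, m1) = prof.segments
        assert (s0, e0, s1, e1) == (0, 50, 50, 100)
        assert m0 == pytest.approx(0.0, abs=1e-12)
        assert m1 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_step_boundary_recovery(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            values = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.1, 100)
            prof = cbs_segment(profile_from(values), CbsParams(n_perm=200, seed=seed))
            bounds = {s for s, _, _ in prof.segments} | {e for _, e, _ in prof.segments}
            if any(abs(b - 50) <= 1 for b in bounds):
                hits += 1
        assert hits >= 38  # >= 95%

    def test_segment_means_reconstruct(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(1.2, 0.05, 40)])
        prof = cbs_segment(profile_from(values), CbsParams(n_perm=200, seed=3))
        for s, e, m in prof.segments:
            member = prof.log2_ratio[s:e]
            assert m == pytest.approx(np.nanmean(member), rel=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(1, 0.1, 30)])
        a = cbs_segment(profile_from(values), CbsParams(n_perm=200, seed=4))
        b = cbs_segment(profile_from(values + 2.5), CbsParams(n_perm=200, seed=4))
        assert [(s, e) for s, e, _ in a.segments] == [(s, e) for s, e, _ in b.segments]
        for (_, _, ma), (_, _, mb) in zip(a.segments, b.segments):
            assert mb == pytest.approx(ma + 2.5, abs=1e-9)

    def test_too_few_bins_single_segment_with_warning(self):
        with pytest.warns(UserWarning):
            prof = cbs_segment(profile_from([0.1, 0.2, 0.3]), CbsParams(n_perm=100))
        assert len(prof.segments) == 1

    def test_masked_bins_assigned_to_enclosing_segment(self):
        values = [0.0] * 20 + [float("nan")] * 2 + [0.0] * 18
        prof = cbs_segment(profile_from(values), CbsParams(n_perm=100, seed=1))
        covered = sorted((s, e) for s, e, _ in prof.segments)
        assert covered[0][0] == 0 and covered[-1][1] == 40
        ends = [e for _, e, _ in prof.segments[:-1]]
        starts = [s for s, _, _ in prof.segments[1:]]
        assert ends == starts  # partition

    def test_chromosomes_segmented_independently(self):
        bins = GenomeBins.uniform({"chr1": 30 * 1_000_000, "chr2": 30 * 1_000_000})
        values = np.concatenate([np.zeros(30), np.ones(30)])
        prof = CopyNumberProfile(bins, values)
        seg = cbs_segment(prof, CbsParams(n_perm=100, seed=0))
        # constant per chromosome -> one segment per chromosome, no cross split
        assert [(s, e) for s, e, _ in seg.segments] == [(0, 30), (30, 60)]

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CbsParams(alpha=0.0)
        with pytest.raises(ValueError):
            CbsParams(n_perm=50)
        with pytest.raises(ValueError):
            CbsParams(min_width=1)


class TestProfileCorrelation:
    def test_self_is_one(self):
        prof = profile_from(np.random.default_rng(0).normal(size=30))
        assert profile_correlation(prof, prof) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        values = np.random.default_rng(0).normal(size=30)
        a, b = profile_from(values), profile_from(-values)
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_spearman(self):
        values = np.random.default_rng(1).normal(size=30)
        a, b = profile_from(values), profile_from(np.exp(values))  # monotone map
        assert profile_correlation(a, b, method="spearman") == pytest.approx(1.0)

    def test_two_cells_same_truth_correlate(self):
        bins, cn = make_cn_profile(500, [(100, 200, 4), (300, 400, 1)])
        truth = SimTruth(bins=bins, cn_profile=cn, bias_sigma=0.05, seed=23)
        cells, _ = simulate_wgs_bins(truth, 500.0, 2)
        a, b = (normalize_to_log2(c) for c in cells)
        assert profile_correlation(a, b) > 0.9

    def test_few_shared_bins_nan(self):
        a = profile_from([1.0, 2.0, float("nan"), float("nan")])
        b = profile_from([float("nan"), 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning):
            assert math.isnan(profile_correlation(a, b))

    def test_zero_variance_nan(self):
        a = profile_from([1.0] * 10)
        b = profile_from(np.arange(10.0))
        with pytest.warns(UserWarning):
            assert math.isnan(profile_correlation(a, b))


class TestAverageProfiles:
    def test_singleton_identity(self):
        prof = profile_from([0.1, 0.2, 0.3])
        avg = average_profiles([prof])
        assert np.allclose(avg.log2_ratio, prof.log2_ratio)

    def test_opposites_cancel(self):
        values = np.random.default_rng(2).normal(size=10)
        avg = average_profiles([profile_from(values), profile_from(-values)])
        assert np.allclose(avg.log2_ratio, 0.0)

    def test_nan_skipped_in_mean(self):
        a = profile_from([1.0, float("nan")])
        b = profile_from([3.0, 2.0])
        c = profile_from([5.0, 4.0])
        avg = average_profiles([a, b, c])
        assert avg.log2_ratio[0] == pytest.approx(3.0)
        assert avg.log2_ratio[1] == pytest.approx(3.0)  # mean of remaining two

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestClusterProfiles:
    def test_identical_pair_merges_first(self):
        x = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        Z, _ = cluster_profiles(x)
        assert set(Z[0, :2].astype(int)) == {1, 2}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_pair_height_is_euclidean_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        Z, _ = cluster_profiles(x)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_three_planted_lines_perfect_ari(self):
        from sklearn.metrics import adjusted_rand_score

        profiles, labels_true = [], []
        plans = [[(20, 60, 4)], [(100, 140, 1)], [(60, 100, 5), (140, 180, 1)]]
        for line_id, plan in enumerate(plans):
            bins, cn = make_cn_profile(200, plan)
            truth = SimTruth(bins=bins, cn_profile=cn, bias_sigma=0.05, seed=31 + line_id)
            cells, _ = simulate_wgs_bins(truth, 500.0, 5)
            for bc in cells:
                profiles.append(normalize_to_log2(bc).log2_ratio)
                labels_true.append(line_id)
        _, labels = cluster_profiles(np.vstack(profiles), k=3)
        assert adjusted_rand_score(labels_true, labels) == 1.0

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.zeros((1, 5)))


def test_write_segments_format(tmp_path):
    prof = cbs_segment(profile_from([0.0] * 10 + [1.0] * 10), CbsParams(n_perm=100, seed=1))
    prof.sample_id = "s1"
    out = tmp_path / "seg.tsv"
    write_segments(prof, out)
    lines = out.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["sample", "chrom", "start", "end", "n_bins", "seg_mean"]
    assert len(lines) == 1 + len(prof.segments)
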