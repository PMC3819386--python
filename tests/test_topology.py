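import numpy as np
import pytest

from voxgraph.preprocess import GrayMatterMask
from voxgraph.topology import (
    DifferenceMap,
    OverlapMap,
    conjunction_rois,
    difference_map,
    overlap_map,
    roi_mean_metric,
    seed_connectivity,
    threshold_overlap,
    top_fraction_mask,
)


class TestTopFraction:
    def test_two_largest_of_ten_selected(self):
        values = np.array([3, 9, 1, 7, 5, 0, 2, 8, 4, 6], dtype=float)
        mask = top_fraction_mask(values, 0.2)
        assert set(np.flatnonzero(mask)) == {1, 7}

    def test_selection_size_is_rounded_fraction(self, rng):
        for n in (10, 37, 101):
            mask = top_fraction_mask(rng.normal(size=n), 0.2)
            assert mask.sum() == int(np.floor(0.2 * n + 0.5))

    def test_permutation_equivariance(self, rng):
        values = rng.normal(size=50)
        perm = rng.permutation(50)
        np.testing.assert_array_equal(
            top_fraction_mask(values)[perm], top_fraction_mask(values[perm])
        )

    def test_degenerate_map_warns_and_takes_first_indices(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask = top_fraction_mask(np.ones(10), 0.2)
        assert set(np.flatnonzero(mask)) == {0, 1}


class TestOverlap:
    def test_six_of_ten_subjects_score_sixty(self):
        masks = np.zeros((10, 4), dtype=bool)
        masks[:6, 2] = True
        om = overlap_map(masks)
        assert om.values[2] == pytest.approx(60.0)

    def test_identical_sets_give_all_or_nothing(self):
        base = np.array([True, False, True, False])
        om = overlap_map(np.tile(base, (7, 1)))
        assert set(om.values.tolist()) <= {0.0, 100.0}

    def test_disjoint_sets_give_one_over_n(self):
        n = 5
        masks = np.eye(n, dtype=bool)
        om = overlap_map(masks)
        np.testing.assert_allclose(om.values, 100.0 / n)

    def test_values_live_on_the_1_over_n_lattice(self, rng):
        n = 12
        masks = rng.random((n, 40)) < 0.3
        om = overlap_map(masks)
        steps = om.values * n / 100.0
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)


class TestThresholdOverlap:
    def test_boundary_kept_at_cutoff(self):
        om = OverlapMap(np.array([40.0, 50.0, 60.0]), "degree", "young")
        np.testing.assert_array_equal(threshold_overlap(om, 50), [0.0, 50.0, 60.0])

    def test_zero_cutoff_is_identity(self):
        om = OverlapMap(np.array([10.0, 99.0]), "degree", "young")
        np.testing.assert_array_equal(threshold_overlap(om, 0), om.values)

    def test_full_cutoff_keeps_unanimous_only(self):
        om = OverlapMap(np.array([99.0, 100.0]), "degree", "young")
        np.testing.assert_array_equal(threshold_overlap(om, 100), [0.0, 100.0])


def make_pair(a_vals, b_vals, metric="degree", s=2.5):
    a = OverlapMap(np.asarray(a_vals, float), metric, "young", s)
    b = OverlapMap(np.asarray(b_vals, float), metric, "old", s)
    return a, b


class TestDifferenceMap:
    def test_thirty_points_flagged(self):
        d = difference_map(*make_pair([80.0], [50.0]))
        assert d.values[0] == pytest.approx(30.0)
        assert d.flags_a_gt_b[0] and not d.flags_b_gt_a[0]

    def test_twenty_points_not_flagged_strict_criterion(self):
        d = difference_map(*make_pair([70.0], [50.0]))
        assert not d.flags_a_gt_b[0]
        d25 = difference_map(*make_pair([75.0], [50.0]))
        assert not d25.flags_a_gt_b[0]  # exactly 25 is not > 25

    def test_antisymmetry_and_flag_swap(self):
        a, b = make_pair([80.0, 10.0], [50.0, 60.0])
        d_ab = difference_map(a, b)
        d_ba = difference_map(b, a)
        np.testing.assert_allclose(d_ab.values, -d_ba.values)
        np.testing.assert_array_equal(d_ab.flags_a_gt_b, d_ba.flags_b_gt_a)

    def test_mismatched_metric_rejected(self):
        a, _ = make_pair([80.0], [50.0])
        _, b = make_pair([80.0], [50.0], metric="eglob")
        with pytest.raises(ValueError, match="same metric"):
            difference_map(a, b)


def diff_with_flags(flags_a, flags_b, metric, s=2.5):
    n = len(flags_a)
    return DifferenceMap(
        values=np.where(flags_a, 60.0, np.where(flags_b, -60.0, 0.0)),
        flags_a_gt_b=np.asarray(flags_a, bool),
        flags_b_gt_a=np.asarray(flags_b, bool),
        group_a="young",
        group_b="old",
        metric=metric,
        s_level=s,
    )


class TestConjunctionRois:
    grid = (4, 4, 4)

    @property
    def coords(self):
        mask = GrayMatterMask.full(self.grid)
        return mask.coordinates()

    def test_two_of_three_maps_not_enough(self):
        n = 64
        fa = np.zeros(n, bool)
        fa[:4] = True
        d1 = diff_with_flags(fa, np.zeros(n, bool), "degree")
        d2 = diff_with_flags(fa, np.zeros(n, bool), "eglob")
        d3 = diff_with_flags(np.zeros(n, bool), np.zeros(n, bool), "kcore")
        with pytest.warns(UserWarning, match="empty"):
            rois = conjunction_rois([d1, d2, d3], self.coords, self.grid)
        assert len(rois) == 0

    def test_planted_contiguous_cluster_recovered(self):
        # a 2x2x2 block: flat x-fastest indices of corner (0:2, 0:2, 0:2)
        n = 64
        block = [x + 4 * (y + 4 * z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        flags = np.zeros(n, bool)
        flags[block] = True
        diffs = [diff_with_flags(np.zeros(n, bool), flags, m)
                 for m in ("degree", "eglob", "kcore")]
        rois = conjunction_rois(diffs, self.coords, self.grid)
        assert len(rois) == 1
        roi = rois.rois[0]
        assert roi.direction == "old>young"
        assert set(roi.nodes.tolist()) == set(block)

    def test_small_clusters_dropped(self):
        n = 64
        flags = np.zeros(n, bool)
        flags[0] = True  # singleton below min_size=2
        diffs = [diff_with_flags(flags, np.zeros(n, bool), m)
                 for m in ("degree", "eglob", "kcore")]
        with pytest.warns(UserWarning, match="empty"):
            rois = conjunction_rois(diffs, self.coords, self.grid)
        assert len(rois) == 0

    def test_group_relabel_flips_direction(self):
        # same overlap values, but the subjects' group labels exchanged
        vals_hi = np.zeros(64)
        vals_hi[[0, 1]] = 90.0
        vals_lo = np.zeros(64)
        a_hi = OverlapMap(vals_hi, "degree", "young", 2.5)
        b_lo = OverlapMap(vals_lo, "degree", "old", 2.5)
        a_relabeled = OverlapMap(vals_hi, "degree", "old", 2.5)
        b_relabeled = OverlapMap(vals_lo, "degree", "young", 2.5)

        def rois_for(a, b):
            diffs = []
            for m in ("degree", "eglob", "kcore"):
                am = OverlapMap(a.values, m, a.group, 2.5)
                bm = OverlapMap(b.values, m, b.group, 2.5)
                diffs.append(difference_map(am, bm))
            return conjunction_rois(diffs, self.coords, self.grid)

        rois = rois_for(a_hi, b_lo)
        rois_sw = rois_for(a_relabeled, b_relabeled)
        assert rois.rois[0].direction == "young>old"
        assert rois_sw.rois[0].direction == "old>young"
        np.testing.assert_array_equal(rois.rois[0].nodes, rois_sw.rois[0].nodes)


class TestRoiMean:
    def test_constant_map(self):
        assert roi_mean_metric(np.full(10, 3.5), np.array([2, 4, 7])) == pytest.approx(3.5)

    def test_single_node_roi(self):
        vals = np.arange(10, dtype=float)
        assert roi_mean_metric(vals, np.array([6])) == pytest.approx(6.0)

    def test_matches_direct_mean_oracle(self, rng):
        vals = rng.normal(size=100)
        nodes = rng.choice(100, size=17, replace=False)
        assert roi_mean_metric(vals, nodes) == pytest.approx(vals[nodes].mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean_metric(np.ones(5), np.array([], dtype=int))


class TestSeedConnectivity:
    def test_single_node_seed_z_is_capped(self, rng):
        series = rng.normal(size=(5, 100))
        out = seed_connectivity(series, np.array([0]))
        assert out["z"][0] == pytest.approx(out["z_cap"])
        assert out["in_seed"][0]

    def test_null_nodes_rarely_exceed_cutoff(self, rng):
        t, n = 200, 500
        series = rng.normal(size=(n, t))
        seed = np.array([0, 1, 2])
        out = seed_connectivity(series, seed)
        below = np.abs(out["z"][~out["in_seed"]]) < 2.33
        # sub-threshold entries were zeroed; count survivors instead
        frac_null_flagged = np.count_nonzero(out["z"][~out["in_seed"]]) / (n - 3)
        assert frac_null_flagged <= 0.02

    def test_coupled_node_detected(self, rng):
        t = 150
        seed_ts = rng.normal(size=t)
        series = np.vstack([seed_ts, seed_ts + 0.3 * rng.normal(size=t),
                            rng.normal(size=(3, t))])
        out = seed_connectivity(series, np.array([0]))
        assert out["z"][1] > 2.33

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="10 time points"):
            seed_connectivity(rng.normal(size=(3, 8)), np.array([0]))
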