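"""Preprocessing: inter-subject stats, masking, occupancy, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmzdecomp import (
    ElementMap,
    build_valid_mask,
    compute_occupancy,
    define_clusters,
    fwhm_to_sigma,
    intersubject_stats,
    make_geometry,
    pool_occupancy,
    smooth_map,
)
from fmzdecomp.preprocess import OccupancyDataset


@pytest.fixture(scope="module")
def geo():
    return make_geometry((16, 16, 16), seed=2)


def emap(geo, value):
    return ElementMap(geo, np.full(geo.shape, float(value)))


class TestIntersubjectStats:
    def test_min_and_mean_of_two_maps(self, geo):
        mn, mean = intersubject_stats([emap(geo, 1.0), emap(geo, 3.0)])
        assert (mn.data == 1.0).all() and (mean.data == 2.0).all()

    def test_identical_maps_are_fixed_point(self, geo):
        maps = [emap(geo, 2.5)] * 3
        mn, mean = intersubject_stats(maps)
        np.testing.assert_array_equal(mn.data, maps[0].data)
        np.testing.assert_array_equal(mean.data, maps[0].data)

    def test_mean_matches_direct_recomputation(self, noiseless_study):
        stack = np.stack([m.data for m in noiseless_study["baselines"]])
        _, mean = intersubject_stats(noiseless_study["baselines"])
        assert np.abs(mean.data - stack.mean(0)).max() < 1e-12

    def test_single_map_rejected(self, geo):
        with pytest.raises(ValueError):
            intersubject_stats([emap(geo, 1.0)])


class TestValidMask:
    def test_threshold_is_inclusive(self, geo):
        data = np.full(geo.shape, 0.5)
        data[0, 0, 0], data[0, 0, 1] = 0.05, 0.10
        mask = build_valid_mask(ElementMap(geo, data), threshold=0.1)
        assert not mask.mask[0, 0, 0]
        assert mask.mask[0, 0, 1]
        assert mask.mask[1, 1, 1]

    def test_zero_threshold_keeps_everything(self, geo):
        mask = build_valid_mask(emap(geo, 0.0), threshold=0.0)
        assert mask.mask.all()

    def test_empty_mask_rejected(self, geo):
        with pytest.raises(ValueError, match="empty"):
            build_valid_mask(emap(geo, 1.0), anatomical_mask=np.zeros(geo.shape, bool))


class TestOccupancy:
    def test_no_displacement_gives_zero(self, geo):
        occ = compute_occupancy(emap(geo, 3.0), emap(geo, 3.0))
        assert (occ.data == 0).all()

    def test_full_displacement_gives_one(self, geo):
        occ = compute_occupancy(emap(geo, 3.0), emap(geo, 0.0))
        assert (occ.data == 1).all()

    def test_quarter_binding_left(self, geo):
        occ = compute_occupancy(emap(geo, 4.0), emap(geo, 1.0))
        np.testing.assert_allclose(occ.valid_values, 0.75)

    def test_nonpositive_baseline_rejected(self, geo):
        bad = np.full(geo.shape, 2.0)
        bad[:2] = 0.0
        with pytest.raises(ValueError, match="element"):
            compute_occupancy(ElementMap(geo, bad), emap(geo, 1.0))

    @given(bp_post=st.floats(0.0, 10.0), bp_base=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_antitone_in_post_binding(self, bp_post, bp_base):
        geo = make_geometry((8, 8, 8), seed=0)
        lo = compute_occupancy(emap(geo, bp_base), emap(geo, bp_post)).valid_values[0]
        hi = compute_occupancy(emap(geo, bp_base), emap(geo, bp_post + 0.5)).valid_values[0]
        assert hi <= lo


class TestClusters:
    def test_block_partition_of_full_grid(self, geo):
        cs = define_clusters(geo, (4, 4, 4))
        assert cs.n_clusters == 64
        assert (cs.sizes == 64).all()
        assert geo.n_valid / cs.n_clusters == 64

    def test_unit_block_one_cluster_per_voxel(self):
        geo = make_geometry((8, 8, 8), seed=0)
        cs = define_clusters(geo, (1, 1, 1))
        assert cs.n_clusters == geo.n_valid

    def test_eight_cube_gives_eight_clusters(self):
        geo = make_geometry((8, 8, 8), seed=0)
        assert define_clusters(geo, (4, 4, 4)).n_clusters == 8

    def test_assignment_is_partition(self, geo):
        cs = define_clusters(geo, (4, 4, 4))
        assert (cs.labels[geo.mask] >= 0).all()
        assert cs.sizes.sum() == geo.n_valid

    def test_deterministic(self, geo):
        a, b = define_clusters(geo, (4, 4, 4)), define_clusters(geo, (4, 4, 4))
        assert np.array_equal(a.labels, b.labels)


class TestPooling:
    def test_constant_map_pools_to_constant(self, geo, design_pair):
        design, occ_maps = design_pair
        cs = define_clusters(geo, (4, 4, 4))
        ds = pool_occupancy(occ_maps, cs, design)
        np.testing.assert_allclose(ds.occupancy[:, 0], 0.3)

    def test_mean_of_two_member_values(self):
        geo = make_geometry((8, 8, 8), seed=0)
        cs = define_clusters(geo, (8, 8, 4))
        data = np.zeros(geo.shape)
        data[:, :, :4] = 0.2
        data[:, :, 4:] = 0.4
        from fmzdecomp import make_design

        design = make_design(2, 2, seed=0)
        maps = [ElementMap(geo, data)] * 4
        ds = pool_occupancy(maps, cs, design)
        np.testing.assert_allclose(sorted(ds.occupancy[:, 0]), [0.2, 0.4])

    def test_noiseless_pooling_matches_analytic_cluster_means(
        self, noiseless_study, truth, cluster_truth_fractions
    ):
        """Pooled occupancy equals the cluster-mean of the analytic
        mixture occupancy, the generative oracle."""
        ds = noiseless_study["dataset"]
        a_cols = []
        for row in ds.design.table.itertuples():
            occ = np.zeros(3)
            for k in truth.config.displaceable[row.drug]:
                ki = truth.ki[row.drug][k]
                occ[k - 1] = row.exposure / (row.exposure + ki)
            a_cols.append(occ)
        expected = cluster_truth_fractions @ np.array(a_cols).T
        assert np.abs(ds.occupancy - expected).max() < 1e-12

    def test_pooled_value_within_member_range(self, noiseless_study, geometry):
        geo = geometry
        ds = noiseless_study["dataset"]
        cs = noiseless_study["clusters"]
        b, p = noiseless_study["baselines"][0], noiseless_study["posts"][0]
        mask = cs.labels >= 0
        occ0 = compute_occupancy(
            ElementMap(geo, b.data, mask.copy()), ElementMap(geo, p.data, mask.copy())
        )
        for cluster in range(cs.n_clusters):
            members = occ0.data[cs.labels == cluster]
            assert members.min() - 1e-12 <= ds.occupancy[cluster, 0] <= members.max() + 1e-12

    def test_occasion_count_mismatch_rejected(self, geo, design_pair):
        design, occ_maps = design_pair
        cs = define_clusters(geo, (4, 4, 4))
        with pytest.raises(ValueError):
            pool_occupancy(occ_maps[:-1], cs, design)


@pytest.fixture(scope="module")
def design_pair(geo):
    from fmzdecomp import make_design

    design = make_design(2, 2, seed=1)
    occ_maps = [ElementMap(geo, np.full(geo.shape, 0.3)) for _ in range(4)]
    return design, occ_maps


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, geo):
        m = ElementMap(geo, np.random.default_rng(0).random(geo.shape))
        out = smooth_map(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_constant_map_unchanged_under_mask_normalization(self, geo):
        mask = np.zeros(geo.shape, bool)
        mask[4:12, 4:12, 4:12] = True
        m = ElementMap(geo, np.full(geo.shape, 2.0), mask)
        out = smooth_map(m, 5.0)
        np.testing.assert_allclose(out.data[mask], 2.0, rtol=1e-10)

    def test_sigma_conversion(self):
        assert abs(fwhm_to_sigma(5.0) - 2.1233) < 5e-4

    def test_smoothing_reduces_variance(self, geo):
        m = ElementMap(geo, np.random.default_rng(1).random(geo.shape))
        out = smooth_map(m, 5.0)
        assert out.valid_values.std() < m.valid_values.std()
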