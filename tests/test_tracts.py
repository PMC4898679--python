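"""Tensor metrics, deterministic tracking, ROI voxelization, dissection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gyriconn.synth import BundleSpec, generate_tensor_volume
from gyriconn.tracts import (
    StreamlineSet,
    VoxelMask,
    dissect_by_endpoints,
    streamline_mean_metrics,
    tensor_metrics,
    track_whole_volume,
    voxelize_surface_roi,
)


class TestTensorMetrics:
    def test_isotropic(self):
        fa, md, ad, rd = tensor_metrics(np.array([1e-3, 1e-3, 1e-3]))
        assert fa == 0.0
        assert md == ad == rd == 1e-3

    def test_prolate_closed_form(self):
        ev = np.array([1.7e-3, 0.2e-3, 0.2e-3])
        fa, md, ad, rd = tensor_metrics(ev)
        assert md == pytest.approx(0.7e-3, rel=1e-12)
        assert ad == pytest.approx(1.7e-3, rel=1e-12)
        assert rd == pytest.approx(0.2e-3, rel=1e-12)
        expected_fa = np.sqrt(1.5) * np.sqrt(np.sum((ev - ev.mean()) ** 2)) / np.sqrt(
            np.sum(ev**2)
        )
        assert fa == pytest.approx(expected_fa, rel=1e-12)
        assert fa == pytest.approx(0.8703882797784892, rel=1e-9)

    def test_stick_limit(self):
        fa, _, _, _ = tensor_metrics(np.array([1e-3, 0.0, 0.0]))
        assert fa == pytest.approx(1.0, rel=1e-12)

    def test_zero_tensor_flagged(self):
        fa, _, _, _ = tensor_metrics(np.zeros(3))
        assert np.isnan(fa)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            tensor_metrics(np.array([0.2e-3, 1.7e-3, 0.2e-3]))

    @given(
        st.tuples(
            st.floats(min_value=1e-5, max_value=3e-3),
            st.floats(min_value=1e-5, max_value=3e-3),
            st.floats(min_value=1e-5, max_value=3e-3),
        )
    )
    def test_ordering_invariant(self, ev):
        """AD >= MD >= RD and FA in [0, 1] for any valid eigenvalues."""
        ev = np.sort(np.array(ev))[::-1]
        fa, md, ad, rd = tensor_metrics(ev)
        eps = 1e-12 * ev[0]  # float rounding headroom for degenerate tensors
        assert ad >= md - eps >= rd - 2 * eps
        assert -1e-12 <= fa <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def straight60():
    b = BundleSpec(kind="straight", start=(0, 0, -30), end=(0, 0, 30),
                   cross_section_radius=4.0)
    vol = generate_tensor_volume((40, 40, 40), 2.0, [b])
    return vol, track_whole_volume(vol)


class TestTracking:
    def test_planted_length_recovery(self, straight60):
        _, streams = straight60
        L = streams.lengths()
        assert streams.count > 100
        assert np.all(np.abs(L - 60.0) <= 2.0)

    def test_sharp_corner_terminates_tracking(self):
        b1 = BundleSpec(kind="straight", start=(-30, 0, 0), end=(0, 0, 0),
                        cross_section_radius=3.0)
        b2 = BundleSpec(kind="straight", start=(0, 0, 0), end=(0, 0, 30),
                        cross_section_radius=3.0)
        vol = generate_tensor_volume((40, 40, 40), 2.0, [b1, b2])
        streams = track_whole_volume(vol)
        assert streams.count > 0
        for line in streams.lines:
            spans_both = line[:, 0].min() < -15 and line[:, 2].max() > 15
            assert not spans_both

    def test_isotropic_volume_no_streamlines(self):
        vol = generate_tensor_volume((12, 12, 12), 2.0, [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            streams = track_whole_volume(vol)
        assert streams.count == 0

    def test_deterministic(self, straight60):
        vol, streams = straight60
        again = track_whole_volume(vol)
        assert again.count == streams.count
        assert all(np.array_equal(a, b) for a, b in zip(again.lines, streams.lines))

    def test_log_euclidean_option_recovers_same_bundle(self, straight60):
        """Log-Euclidean tensor interpolation recovers the planted bundle
        with the same lengths (the field is homogeneous inside the tube)."""
        vol, streams = straight60
        le = track_whole_volume(vol, log_euclidean=True)
        assert le.count > 100
        assert np.all(np.abs(le.lengths() - 60.0) <= 2.0)

    def test_multiple_seeds_per_voxel(self, straight60):
        vol, streams = straight60
        multi = track_whole_volume(vol, seeds_per_voxel=2)
        assert multi.count > 1.5 * streams.count


class TestVoxelizeRoi:
    class FakeSurface:
        def __init__(self, vertices):
            self.vertices = np.asarray(vertices, float)

    def test_identity_affine_vertex_at_voxel_center(self):
        surf = self.FakeSurface([[3.0, 4.0, 5.0]])
        mask = voxelize_surface_roi([0], surf, np.eye(4), (10, 10, 10), band_voxels=0)
        assert mask.mask[3, 4, 5]
        assert mask.count() == 1

    def test_translation_equivariance(self):
        surf = self.FakeSurface([[3.0, 4.0, 5.0]])
        aff = np.eye(4)
        aff[:3, 3] = [1.0, 1.0, 1.0]
        mask = voxelize_surface_roi([0], surf, aff, (10, 10, 10), band_voxels=0)
        assert mask.mask[2, 3, 4]

    def test_patch_mask_size_tracks_area(self, sphere4):
        """Voxel count of a patch ROI is proportional to its area (within
        20%), comparing a small and a doubled patch."""
        from conftest import patch_angles

        th = patch_angles(sphere4)
        aff = np.eye(4) * 2.0
        aff[3, 3] = 1.0
        aff[:3, 3] = -64.0
        small = np.flatnonzero(th < 0.25)
        large = np.flatnonzero(th < 0.25 * np.sqrt(2))  # twice the cap area
        m_small = voxelize_surface_roi(small, sphere4, aff, (64, 64, 64), band_voxels=1)
        m_large = voxelize_surface_roi(large, sphere4, aff, (64, 64, 64), band_voxels=1)
        ratio = m_large.count() / m_small.count()
        assert ratio == pytest.approx(2.0, rel=0.20)

    def test_roi_outside_grid_warns_empty(self):
        surf = self.FakeSurface([[500.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="outside"):
            mask = voxelize_surface_roi([0], surf, np.eye(4), (10, 10, 10))
        assert mask.count() == 0


def three_streamline_fixture():
    """Both-endpoints-in, pass-through, and fully-outside streamlines for a
    mask occupying the slab x in [0, 4]."""
    mask = np.zeros((20, 20, 20), bool)
    mask[0:5, :, :] = True
    vm = VoxelMask(mask, np.eye(4))
    inside = np.array([[1.0, 10, 10], [2, 10, 10], [3, 10, 10]])
    through = np.array([[10.0, 2, 10], [2, 2, 10], [10, 5, 10]])  # mid-point dips in
    outside = np.array([[10.0, 10, 10], [12, 10, 10], [15, 10, 10]])
    return vm, StreamlineSet([inside, through, outside], affine=np.eye(4))


class TestDissection:
    def test_endpoint_semantics(self):
        vm, streams = three_streamline_fixture()
        kept = dissect_by_endpoints(streams, vm)
        assert kept.count == 1
        assert np.array_equal(kept.lines[0], streams.lines[0])

    def test_pass_through_excluded(self):
        vm, streams = three_streamline_fixture()
        kept = dissect_by_endpoints(streams, vm)
        # the pass-through line touches the mask mid-course yet is excluded
        mid_voxel = np.round(streams.lines[1][1]).astype(int)
        assert vm.mask[tuple(mid_voxel)]
        assert all(not np.array_equal(l, streams.lines[1]) for l in kept.lines)

    def test_idempotent_and_subset(self):
        vm, streams = three_streamline_fixture()
        once = dissect_by_endpoints(streams, vm)
        twice = dissect_by_endpoints(once, vm)
        assert twice.count == once.count
        assert once.count <= streams.count

    def test_empty_mask_empty_output(self):
        _, streams = three_streamline_fixture()
        vm = VoxelMask(np.zeros((20, 20, 20), bool), np.eye(4))
        assert dissect_by_endpoints(streams, vm).count == 0


class TestStreamlineMetrics:
    def test_constant_field_oracle(self, straight60):
        vol, streams = straight60
        out = streamline_mean_metrics(streams, vol)
        assert out["mean_ad"] == pytest.approx(1.7e-3, rel=0.01)
        assert out["mean_rd"] == pytest.approx(0.2e-3, rel=0.05)

    def test_two_bundle_average(self):
        b1 = BundleSpec(kind="straight", start=(-10, 0, -25), end=(-10, 0, 25),
                        eigenvalues=(1.6e-3, 0.2e-3, 0.2e-3), cross_section_radius=3.0)
        b2 = BundleSpec(kind="straight", start=(10, 0, -25), end=(10, 0, 25),
                        eigenvalues=(1.2e-3, 0.2e-3, 0.2e-3), cross_section_radius=3.0)
        vol = generate_tensor_volume((40, 40, 40), 2.0, [b1, b2])
        streams = track_whole_volume(vol)
        out = streamline_mean_metrics(streams, vol)
        # equal seed counts per bundle -> set mean ~ (a + b)/2
        assert out["mean_ad"] == pytest.approx(1.4e-3, rel=0.03)

    def test_empty_set_missing_values(self):
        vol = generate_tensor_volume((8, 8, 8), 2.0, [])
        out = streamline_mean_metrics(StreamlineSet([], affine=vol.affine), vol)
        assert np.isnan(out["mean_fa"])
        assert out["n_streamlines"] == 0
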