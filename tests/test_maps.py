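"""Voxelwise map pipeline: ΔS/ΔZ/TCF, masking, ROI aggregation."""

import numpy as np
import pytest

from misl.maps import (
    ExchangeMaps,
    MaskSet,
    QCError,
    VolumeSeries,
    compute_delta_s,
    compute_delta_z,
    compute_tcf_map,
    dilate_and_intersect_rois,
    make_csf_mask,
    make_pvs_mask,
    quantify_series,
    roi_statistics,
)
from misl.signal_model import MISLModelParams, tcf_from_delta_z

SHAPE = (12, 12, 8)


def _series(control_value=100.0, label_value=97.0, n=3, shape=SHAPE):
    control = np.full((n,) + shape, control_value)
    label = np.full((n,) + shape, label_value)
    return VolumeSeries(control=control, label=label)


def _full_masks(shape=SHAPE):
    ones = np.ones(shape, dtype=bool)
    return MaskSet(brain_mask=ones, csf_mask=ones.copy())


class TestDeltaS:
    def test_constant_volumes(self):
        ds, mc = compute_delta_s(_series(100.0, 97.0))
        assert np.allclose(ds, 3.0)
        assert np.allclose(mc, 100.0)

    def test_identical_control_label(self):
        ds, _ = compute_delta_s(_series(50.0, 50.0))
        assert np.allclose(ds, 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch|repeat"):
            VolumeSeries(
                control=np.zeros((2, 4, 4, 4)), label=np.zeros((2, 4, 4, 5))
            )

    def test_unequal_repeats_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            VolumeSeries(control=np.zeros((2, 4, 4, 4)), label=np.zeros((3, 4, 4, 4)))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            VolumeSeries(control=np.full((1, 2, 2, 2), -1.0), label=np.zeros((1, 2, 2, 2)))


class TestDeltaZ:
    def test_simple_ratio(self):
        ds, mc = compute_delta_s(_series(100.0, 97.0))
        dz, low = compute_delta_z(ds, mc, _full_masks(), noise_level=0.0)
        assert np.allclose(dz, 0.03)
        assert not low.any()

    def test_low_signal_guard_excludes_voxels(self):
        ds = np.full(SHAPE, 3.0)
        mc = np.full(SHAPE, 100.0)
        mc[0, 0, 0] = 2.0  # below 5x noise guard
        dz, low = compute_delta_z(ds, mc, _full_masks(), noise_level=1.0)
        assert np.isnan(dz[0, 0, 0])
        assert low[0, 0, 0]
        assert np.isfinite(dz[1, 1, 1])

    def test_outside_mask_undefined_not_zero(self):
        ds = np.full(SHAPE, 3.0)
        mc = np.full(SHAPE, 100.0)
        masks = _full_masks()
        masks.csf_mask[:, :6] = False
        dz, _ = compute_delta_z(ds, mc, masks, noise_level=0.0)
        assert np.isnan(dz[0, 0, 0])
        assert np.isfinite(dz[0, 7, 0])


def test_tcf_map_matches_scalar_inversion_and_propagates_nan(params):
    dz = np.full(SHAPE, 0.0447)
    dz[0, 0, 0] = np.nan
    tcf = compute_tcf_map(dz, params, 3.725)
    assert tcf[1, 1, 1] == pytest.approx(tcf_from_delta_z(params, 0.0447, 3.725))
    assert tcf[1, 1, 1] == pytest.approx(288.0, rel=0.01)
    assert np.isnan(tcf[0, 0, 0])
    # linearity carries through the map
    tcf2 = compute_tcf_map(2 * dz, params, 3.725)
    assert tcf2[1, 1, 1] == pytest.approx(2 * tcf[1, 1, 1], rel=1e-12)


class TestCsfMask:
    def _bimodal(self):
        img = np.full(SHAPE, 50.0)
        img[4:8, 4:8, 2:6] = 1000.0
        return img, np.ones(SHAPE, dtype=bool)

    def test_absolute_threshold_isolates_csf(self):
        img, brain = self._bimodal()
        mask = make_csf_mask(img, brain, threshold=500.0)
        assert np.array_equal(mask, img > 500)

    def test_otsu_matches_absolute_on_two_level_image(self):
        img, brain = self._bimodal()
        assert np.array_equal(
            make_csf_mask(img, brain, "otsu"), make_csf_mask(img, brain, 500.0)
        )

    def test_all_tissue_raises_qc_error(self):
        img = np.full(SHAPE, 50.0)
        with pytest.raises(QCError, match="empty"):
            make_csf_mask(img, np.ones(SHAPE, dtype=bool), threshold=500.0)


class TestPvsMask:
    def test_large_components_removed_tubes_kept(self):
        """A 5000-voxel ventricle blob is dropped; three thin tubes survive."""
        shape = (40, 40, 40)
        img = np.zeros(shape)
        img[12:29, 12:22, 12:17] = 1000.0  # ventricle: 17*10*5 = 850 voxels
        tubes = [(30, slice(5, 25), 30), (34, slice(5, 25), 30), (30, slice(5, 25), 35)]
        for x, ys, z in tubes:
            img[x, ys, z] = 1000.0  # 20-voxel tubes
        brain = np.ones(shape, dtype=bool)
        mask = make_pvs_mask(img, brain, 500.0, max_component_size=300)
        assert mask.sum() == 60
        assert not mask[12:29, 12:22, 12:17].any()

    def test_empty_result_warns(self):
        img = np.zeros(SHAPE)
        with pytest.warns(UserWarning, match="empty"):
            mask = make_pvs_mask(img, np.ones(SHAPE, dtype=bool), 500.0)
        assert not mask.any()

    def test_connectivity_dependence_of_touching_tubes(self):
        """Diagonally touching tubes merge under 26- but not 6-connectivity."""
        shape = (24, 60, 24)
        img = np.zeros(shape)
        img[10, 5:56, 10] = 1000.0  # 51 voxels
        img[11, 5:56, 11] = 1000.0  # diagonal neighbor in the x-z plane
        brain = np.ones(shape, dtype=bool)
        with pytest.warns(UserWarning):
            merged = make_pvs_mask(img, brain, 500.0, max_component_size=80, connectivity=3)
        assert merged.sum() == 0  # 102-voxel merged component dropped
        separate = make_pvs_mask(img, brain, 500.0, max_component_size=80, connectivity=1)
        assert separate.sum() == 102


class TestDilateIntersect:
    def test_radius_zero_is_plain_intersection(self):
        rois = np.zeros(SHAPE, dtype=int)
        rois[2:5, 2:5, 2:5] = 3
        csf = np.zeros(SHAPE, dtype=bool)
        csf[4:7, 2:5, 2:5] = True
        out = dilate_and_intersect_rois(rois, csf, 0)
        assert np.array_equal(out != 0, (rois == 3) & csf)

    def test_radius_one_gains_touching_csf(self):
        rois = np.zeros(SHAPE, dtype=int)
        rois[2:4, 2:6, 2:6] = 1
        csf = np.zeros(SHAPE, dtype=bool)
        csf[4, 2:6, 2:6] = True  # CSF sheet adjacent to the ROI
        out = dilate_and_intersect_rois(rois, csf, 1)
        assert np.all(out[4, 2:6, 2:6] == 1)

    def test_nearest_label_wins_and_ties_break_low(self):
        shape = (9, 3, 3)
        rois = np.zeros(shape, dtype=int)
        rois[2, 1, 1] = 1
        rois[6, 1, 1] = 2
        csf = np.zeros(shape, dtype=bool)
        csf[3, 1, 1] = True  # distance 1 from roi 1, 3 from roi 2
        csf[4, 1, 1] = True  # equidistant -> lower label id
        out = dilate_and_intersect_rois(rois, csf, 2)
        assert out[3, 1, 1] == 1
        assert out[4, 1, 1] == 1


def _uniform_maps(dz_value, rois, params):
    shape = rois.shape
    dz = np.full(shape, np.nan)
    dz[rois > 0] = dz_value
    tcf = compute_tcf_map(dz, params, 3.725)
    return ExchangeMaps(
        delta_s=np.zeros(shape),
        delta_z=dz,
        tcf=tcf,
        mean_control=np.full(shape, 100.0),
        low_signal=np.zeros(shape, dtype=bool),
        negative=np.zeros(shape, dtype=bool),
    )


class TestRoiStatistics:
    def _masks(self):
        rois = np.zeros(SHAPE, dtype=int)
        rois[2:5, 2:5, 2:5] = 1
        rois[6:9, 6:9, 2:5] = 2
        ones = np.ones(SHAPE, dtype=bool)
        return MaskSet(
            brain_mask=ones,
            csf_mask=ones.copy(),
            roi_labels=rois,
            roi_names={1: "a", 2: "b"},
        )

    def test_uniform_roi(self, params):
        masks = self._masks()
        maps = _uniform_maps(0.03, masks.roi_labels, params)
        tab = roi_statistics(maps, masks)
        row = tab[tab.roi_name == "a"].iloc[0]
        assert row.mean_dz == pytest.approx(0.03)
        assert row.sd_dz == pytest.approx(0.0, abs=1e-15)
        assert row.n_voxels == 27

    def test_composite_is_voxel_weighted_mean(self, params):
        masks = self._masks()
        maps = _uniform_maps(0.03, masks.roi_labels, params)
        maps.delta_z[masks.roi_labels == 2] = 0.06
        maps.tcf = compute_tcf_map(maps.delta_z, params, 3.725)
        tab = roi_statistics(maps, masks, composite_spec={"both": [1, 2]})
        comp = tab[(tab.roi_id == -1) & (tab.roi_name == "both")].iloc[0]
        a = tab[tab.roi_name == "a"].iloc[0]
        b = tab[tab.roi_name == "b"].iloc[0]
        expected = (a.mean_dz * a.n_voxels + b.mean_dz * b.n_voxels) / (
            a.n_voxels + b.n_voxels
        )
        assert comp.mean_dz == pytest.approx(expected)

    def test_empty_roi_reported_missing_not_zero(self, params):
        masks = self._masks()
        maps = _uniform_maps(0.03, masks.roi_labels, params)
        maps.delta_z[masks.roi_labels == 2] = np.nan  # all invalid
        tab = roi_statistics(maps, masks)
        row = tab[tab.roi_name == "b"].iloc[0]
        assert row.n_voxels == 0
        assert np.isnan(row.mean_dz)


def test_pipeline_permutation_invariant_and_nondestructive(params):
    rng = np.random.default_rng(3)
    control = rng.uniform(500, 1500, (4,) + SHAPE)
    label = control * 0.96
    masks = _full_masks()
    series = VolumeSeries(control=control, label=label)
    before = series.control.copy()
    out1 = quantify_series(series, masks, params, 3.725, noise_level=0.0)
    perm = [2, 0, 3, 1]
    series_perm = VolumeSeries(control=control[perm], label=label[perm])
    out2 = quantify_series(series_perm, masks, params, 3.725, noise_level=0.0)
    np.testing.assert_allclose(out1.delta_z, out2.delta_z, rtol=1e-12)
    np.testing.assert_array_equal(series.control, before)  # masks never mutate data


def test_maskset_requires_csf_inside_brain():
    brain = np.zeros(SHAPE, dtype=bool)
    brain[2:8] = True
    csf = np.ones(SHAPE, dtype=bool)
    with pytest.raises(ValueError, match="subset"):
        MaskSet(brain_mask=brain, csf_mask=csf)
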