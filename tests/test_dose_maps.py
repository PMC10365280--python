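import numpy as np
import pytest

from doseatlas.volume_io import MaskVolume, Volume
from doseatlas.dose_maps import (
    DoseRangeSpec,
    build_high_dose_rois,
    dose_range_summary,
    group_mean_dose,
    roi_dose_table,
    roi_mean_dose,
)
from doseatlas.synthetic_cohort import (
    PhantomParams,
    SubjectRecord,
    simulate_dose,
)


def _vol(data, affine=None):
    return Volume(data=np.asarray(data, float),
                  affine=np.eye(4) if affine is None else affine)


def _full_mask(shape, affine=None):
    return MaskVolume(data=np.ones(shape, dtype=np.uint8),
                      affine=np.eye(4) if affine is None else affine)


class TestGroupMeanDose:
    def test_identical_volumes(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.uniform(0, 70, (6, 6, 6)))
        mask = _full_mask((6, 6, 6))
        out = group_mean_dose([v, v.copy()], mask)
        np.testing.assert_allclose(out.data, v.data)

    def test_constants(self):
        mask = _full_mask((4, 4, 4))
        out = group_mean_dose([_vol(np.full((4, 4, 4), 60.0)),
                               _vol(np.full((4, 4, 4), 80.0))], mask)
        np.testing.assert_allclose(out.data, 70.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        vols = [_vol(rng.uniform(0, 74, (8, 8, 8))) for _ in range(5)]
        mask = _full_mask((8, 8, 8))
        out = group_mean_dose(vols, mask)
        for idx in [(0, 0, 0), (3, 4, 5), (7, 7, 7)]:
            expected = sum(v.data[idx] for v in vols) / 5.0
            assert out.data[idx] == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        vols = [_vol(rng.uniform(0, 74, (5, 5, 5))) for _ in range(4)]
        mask = _full_mask((5, 5, 5))
        a = group_mean_dose(vols, mask)
        b = group_mean_dose(vols[::-1], mask)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_outside_mask(self):
        mask = MaskVolume(data=np.zeros((3, 3, 3), dtype=np.uint8),
                          affine=np.eye(4))
        mask.data[1, 1, 1] = 1
        out = group_mean_dose([_vol(np.full((3, 3, 3), 50.0))], mask)
        assert out.data.sum() == 50.0

    def test_errors(self):
        mask = _full_mask((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            group_mean_dose([], mask)
        with pytest.raises(ValueError, match="grid"):
            group_mean_dose([_vol(np.zeros((3, 3, 3))),
                             _vol(np.zeros((4, 4, 4)),
                                  affine=np.eye(4) * 2 - np.diag([0,0,0,1]))],
                            mask)


class TestDoseRangeSpec:
    def test_default_bins(self):
        spec = DoseRangeSpec()
        assert spec.labels == ["1-1.5 Gy", "1.5-10 Gy", "10-30 Gy",
                               "30-50 Gy", ">50 Gy"]

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            DoseRangeSpec(boundaries=(10.0, 5.0))

    def test_edges_half_open_last_strict(self):
        spec = DoseRangeSpec(boundaries=(1.0, 50.0))
        dose = np.array([[[0.5, 1.0, 49.999, 50.0, 50.001]]])
        masks = spec.bin_masks(dose, np.ones_like(dose, dtype=bool))
        np.testing.assert_array_equal(masks[0][0, 0],
                                      [False, True, True, False, False])
        np.testing.assert_array_equal(masks[1][0, 0],
                                      [False, False, False, False, True])


class TestDoseRangeSummary:
    def test_constant_70_all_in_open_bin(self):
        mask = _full_mask((5, 5, 5))
        summary, bins = dose_range_summary(_vol(np.full((5, 5, 5), 70.0)),
                                           mask)
        assert summary.counts["all"] == [0, 0, 0, 0, 125]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        dose = _vol(rng.uniform(0, 80, (10, 10, 10)))
        mask = MaskVolume(data=(rng.random((10, 10, 10)) > 0.3)
                          .astype(np.uint8), affine=np.eye(4))
        summary, _ = dose_range_summary(dose, mask)
        below = int(((dose.data < 1.0) & mask.data.astype(bool)).sum())
        # the open bin is dose > 50 strictly; dose == 50 exactly has
        # probability zero for continuous draws
        assert sum(summary.counts["all"]) + below == mask.n_voxels

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(4)
        dose = rng.uniform(0, 80, (8, 8, 8))
        mask = _full_mask((8, 8, 8))
        s1, _ = dose_range_summary(_vol(dose), mask)
        c = 2.5
        spec_scaled = DoseRangeSpec(
            boundaries=tuple(c * b for b in DoseRangeSpec().boundaries))
        s2, _ = dose_range_summary(_vol(c * dose), mask, spec_scaled)
        assert s1.counts["all"] == s2.counts["all"]

    def test_volumes_are_count_times_voxel_volume(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        mask = _full_mask((4, 4, 4), aff)
        summary, _ = dose_range_summary(_vol(np.full((4, 4, 4), 20.0), aff),
                                        mask)
        assert summary.volumes_mm3("all")[2] == pytest.approx(64 * 8.0)

    def test_analytic_shell_volumes(self, reg_grid):
        # noise-free falloff: compare voxel counts against a Monte Carlo
        # integration of the analytic dose model (independent discretization)
        from doseatlas.synthetic_cohort import (_target_radii,
                                                make_template_phantom)
        template, truth = make_template_phantom(reg_grid, seed=1)
        params = PhantomParams(noise_sigma_gy=0.0, effect_size_gy=0.0)
        rec = SubjectRecord(id="a", age=50.0, gender="male", t_stage="T3",
                            technique="IMRT", prescription_dose=70.4)
        dose = simulate_dose(rec, truth.head_support_mask,
                             truth.target_center, params, seed=0)
        spec = DoseRangeSpec(boundaries=(30.0, 50.0))
        summary, _ = dose_range_summary(dose, truth.head_support_mask, spec)

        rng = np.random.default_rng(99)
        n_mc = 2_000_000
        lo = np.asarray(reg_grid.origin)
        ext = reg_grid.extent_mm
        pts = lo + rng.random((n_mc, 3)) * ext
        box_vol = float(np.prod(ext))
        # analytic dose at sample points
        c = truth.target_center
        radii = _target_radii(rec, params, reg_grid)
        d = pts - c
        dist = np.linalg.norm(d, axis=1)
        rnorm = np.sqrt(((d / radii) ** 2).sum(axis=1))
        dval = np.where(rnorm <= 1, 70.4,
                        70.4 * np.exp(-dist * (1 - 1 / np.maximum(rnorm,
                                                                  1e-9))
                                      / params.falloff_mm))
        hc = reg_grid.center_mm
        head_r = 0.8 * ext / 2
        inside = (((pts - hc) / head_r) ** 2).sum(axis=1) <= 1.0
        dval = np.where(inside, dval, 0.0)
        for i, (blo, bhi) in enumerate([(30.0, 50.0), (50.0, np.inf)]):
            frac = np.mean((dval >= blo) & (dval < bhi)) if i == 0 else \
                np.mean(dval > blo)
            analytic_vox = frac * box_vol / dose.voxel_volume_mm3
            assert summary.counts["all"][i] == pytest.approx(analytic_vox,
                                                             rel=0.03)


@pytest.fixture(scope="module")
def mean_dose(phantom):
    template, truth = phantom
    params = PhantomParams(noise_sigma_gy=0.0, effect_size_gy=0.0)
    rec = SubjectRecord(id="a", age=50.0, gender="male", t_stage="T4",
                        technique="IMRT", prescription_dose=74.0)
    return simulate_dose(rec, truth.head_support_mask,
                         truth.target_center, params, seed=0)


class TestHighDoseRois:
    def test_matches_brute_force(self, mean_dose, atlas):
        rois = build_high_dose_rois(mean_dose, atlas, threshold=50.0,
                                    lobes=("temporal", "limbic"))
        assert len(rois) > 0
        hot = mean_dose.data > 50.0
        nx = mean_dose.shape[0]
        xw = np.arange(nx)[:, None, None] * mean_dose.affine[0, 0] \
            + mean_dose.affine[0, 3]
        xw = np.broadcast_to(xw, mean_dose.shape)
        for name, roi in rois:
            side, lobe = name.split(" ", 1)
            labels = atlas.labels_for_lobe(lobe)
            expected = hot & np.isin(atlas.data, labels) \
                & ((xw < 0) if side == "left" else (xw > 0))
            np.testing.assert_array_equal(roi.data.astype(bool), expected)

    def test_threshold_above_max_warns_empty(self, mean_dose, atlas):
        with pytest.warns(UserWarning, match="empty"):
            rois = build_high_dose_rois(mean_dose, atlas, threshold=500.0)
        assert len(rois) == 0

    def test_hemispheres_disjoint(self, mean_dose, atlas):
        rois = build_high_dose_rois(mean_dose, atlas, threshold=40.0)
        for lobe in ("temporal", "limbic"):
            left = rois.rois.get(f"left {lobe}")
            right = rois.rois.get(f"right {lobe}")
            if left is not None and right is not None:
                assert not (left.data & right.data).any()

    def test_unknown_lobe_raises(self, mean_dose, atlas):
        with pytest.raises(KeyError):
            build_high_dose_rois(mean_dose, atlas, lobes=("brainstemzzz",))


class TestRoiMeanDose:
    def test_constant_field(self):
        roi = MaskVolume(data=np.ones((4, 4, 4), dtype=np.uint8),
                         affine=np.eye(4))
        assert roi_mean_dose(_vol(np.full((4, 4, 4), 55.0)), roi) == 55.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        dose = _vol(rng.uniform(0, 74, (8, 8, 8)))
        sel = rng.random((8, 8, 8)) > 0.5
        roi = MaskVolume(data=sel.astype(np.uint8), affine=np.eye(4))
        expected = dose.data[sel].sum() / sel.sum()
        assert roi_mean_dose(dose, roi) == pytest.approx(expected, rel=1e-12)

    def test_single_voxel(self):
        dose = _vol(np.arange(27, dtype=float).reshape(3, 3, 3))
        roi = MaskVolume(data=np.zeros((3, 3, 3), dtype=np.uint8),
                         affine=np.eye(4))
        roi.data[1, 2, 0] = 1
        assert roi_mean_dose(dose, roi) == dose.data[1, 2, 0]

    def test_empty_roi_raises(self):
        roi = MaskVolume(data=np.zeros((3, 3, 3), dtype=np.uint8),
                         affine=np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            roi_mean_dose(_vol(np.zeros((3, 3, 3))), roi)

    def test_roi_technique_test_matches_scipy(self):
        import pandas as pd
        from scipy import stats

        from doseatlas.dose_maps import roi_technique_test

        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(12)]
        roi_table = pd.DataFrame(
            [{"id": i, "roi": "left temporal",
              "mean_Gy": float(rng.uniform(45, 60))} for i in ids])
        cohort = pd.DataFrame(
            [{"id": i, "technique": "IMRT" if k < 6 else "VMAT"}
             for k, i in enumerate(ids)])
        out = roi_technique_test(roi_table, cohort)
        a = roi_table["mean_Gy"][:6].to_numpy()
        b = roi_table["mean_Gy"][6:].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert out.iloc[0]["t"] == pytest.approx(float(t))
        assert out.iloc[0]["p"] == pytest.approx(float(p))

    def test_roi_dose_table_layout(self):
        from doseatlas.dose_maps import RoiSet
        rng = np.random.default_rng(6)
        doses = {f"s{i}": _vol(rng.uniform(40, 70, (4, 4, 4)))
                 for i in range(3)}
        roi = MaskVolume(data=np.ones((4, 4, 4), dtype=np.uint8),
                         affine=np.eye(4))
        rois = RoiSet(rois={"left temporal": roi})
        table = roi_dose_table(doses, rois)
        assert list(table.columns) == ["id", "roi", "mean_Gy"]
        assert len(table) == 3
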