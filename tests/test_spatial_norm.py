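import numpy as np
import pytest

from doseatlas.volume_io import GridSpec, MaskVolume, Volume, resample_to
from doseatlas.synthetic_cohort import (
    PhantomParams,
    make_template_phantom,
    _smooth_vector_field,
)
from doseatlas.spatial_norm import (
    AffineTransform,
    DeformationField,
    RigidTransform,
    TransformChain,
    apply_chain,
    crop_head,
    invert_displacement,
    load_chain,
    register_nonlinear,
    register_rigid,
    save_chain,
    ssd,
)


@pytest.fixture(scope="module")
def mid_phantom():
    """32^3 at 4 mm: big enough for meaningful rigid registration tests."""
    grid = GridSpec.centered(32, 4.0)
    return make_template_phantom(grid, seed=6), grid


class TestSsd:
    def test_zero_for_identical(self):
        a = np.random.default_rng(0).standard_normal((5, 5, 5))
        assert ssd(a, a) == 0.0

    def test_closed_form_offset(self):
        a = np.zeros((4, 4, 4))
        assert ssd(a + 1.0, a) == 64.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((5, 5, 5))
        b = rng.standard_normal((5, 5, 5))
        expected = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    expected += (a[i, j, k] - b[i, j, k]) ** 2
        assert ssd(a, b) == pytest.approx(expected, rel=1e-12)

    def test_masked(self):
        a = np.zeros((3, 3, 3))
        b = a + 2.0
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        assert ssd(a, b, mask) == 4.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ssd(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestTransforms:
    def test_rigid_matrix_orthonormal(self):
        t = RigidTransform(rotation=[0.1, -0.2, 0.3], translation=[5, -3, 2])
        R = t.matrix[:3, :3]
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_zero_field_is_identity(self, small_grid):
        fld = DeformationField.zero(small_grid)
        pts = np.random.default_rng(0).uniform(-50, 50, (10, 3))
        np.testing.assert_allclose(fld.map_points(pts), pts)

    def test_empty_chain_identity(self):
        pts = np.random.default_rng(1).uniform(-50, 50, (10, 3))
        chain = TransformChain()
        assert chain.is_identity
        np.testing.assert_allclose(chain.map_points(pts), pts)

    def test_singular_affine_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(matrix=np.zeros((4, 4)))

    def test_nonfinite_field_rejected(self, small_grid):
        disp = np.zeros(tuple(small_grid.shape) + (3,))
        disp[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            DeformationField(disp=disp, affine=small_grid.affine)


class TestCropHead:
    def test_phantom_crop_box(self, phantom, small_grid):
        template, truth = phantom
        dose = Volume(data=np.ones(small_grid.shape),
                      affine=small_grid.affine)
        ct_c, dose_c = crop_head(template, dose, pad_mm=10.0)
        idx = np.argwhere(truth.head_support_mask.data)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        pad = int(np.ceil(10.0 / 6.0))
        expected_lo = np.maximum(lo - pad, 0)
        expected_hi = np.minimum(hi + pad, np.array(small_grid.shape) - 1)
        expected_lo[2] = lo[2]  # inferior face is not padded
        assert ct_c.shape == tuple(expected_hi - expected_lo + 1)

    def test_world_coordinates_preserved(self, phantom, small_grid):
        template, _ = phantom
        dose = Volume(data=np.zeros(small_grid.shape),
                      affine=small_grid.affine)
        ct_c, _ = crop_head(template, dose)
        # voxel (0,0,0) of the crop must map to the same world point and value
        w0 = ct_c.affine[:3, 3]
        inv = np.linalg.inv(template.affine)
        orig_idx = np.rint(inv[:3, :3] @ w0 + inv[:3, 3]).astype(int)
        assert template.data[tuple(orig_idx)] == ct_c.data[0, 0, 0]

    def test_ct_dose_share_grid(self, phantom, small_grid):
        template, _ = phantom
        dose = Volume(data=np.random.default_rng(0).random(small_grid.shape),
                      affine=small_grid.affine)
        ct_c, dose_c = crop_head(template, dose)
        assert ct_c.shape == dose_c.shape
        np.testing.assert_array_equal(ct_c.affine, dose_c.affine)

    def test_empty_support_raises(self, small_grid):
        flat = Volume(data=np.full(small_grid.shape, -1000.0),
                      affine=small_grid.affine)
        with pytest.raises(ValueError, match="crop"):
            crop_head(flat, flat.copy())


class TestRegisterRigid:
    def test_identity(self, mid_phantom):
        (template, _), _ = mid_phantom
        est = register_rigid(template.copy(), template)
        assert np.abs(est.translation).max() < 0.5
        assert np.abs(np.rad2deg(est.rotation)).max() < 0.3

    def test_translation_recovery(self, mid_phantom):
        (template, _), grid = mid_phantom
        W = RigidTransform(rotation=np.zeros(3), translation=[6.0, -4.0, 8.0],
                           center=grid.center_mm)
        moving = Volume(data=apply_chain(TransformChain(rigid=W), template,
                                         template, cval=-1000.0).data,
                        affine=template.affine)
        est = register_rigid(moving, template)
        # the estimated chain maps template points into the moving volume,
        # i.e. it recovers the inverse of the generating warp
        np.testing.assert_allclose(est.translation, [-6.0, 4.0, -8.0],
                                   atol=1.0)
        assert np.abs(np.rad2deg(est.rotation)).max() < 0.5

    def test_ssd_not_increased(self, mid_phantom):
        (template, _), grid = mid_phantom
        W = RigidTransform(rotation=np.deg2rad([2.0, 0.0, -3.0]),
                           translation=[5.0, 3.0, -6.0], center=grid.center_mm)
        moving = Volume(data=apply_chain(TransformChain(rigid=W), template,
                                         template, cval=-1000.0).data,
                        affine=template.affine)
        est = register_rigid(moving, template)
        before = ssd(resample_to(moving, template, cval=-1000.0).data,
                     template.data)
        after = ssd(apply_chain(TransformChain(rigid=est), moving, template,
                                cval=-1000.0).data, template.data)
        assert after <= before


class TestRegisterNonlinear:
    def test_identical_inputs_zero_field(self, mid_phantom):
        (template, _), _ = mid_phantom
        fld = register_nonlinear(template.copy(), template, iters=10)
        assert fld.rms_mm < 0.1

    def test_iters_validated(self, mid_phantom):
        (template, _), _ = mid_phantom
        with pytest.raises(ValueError):
            register_nonlinear(template, template, iters=0)


class TestApplyChain:
    def test_empty_chain_equals_resample(self, phantom, small_grid):
        template, _ = phantom
        shifted = GridSpec(shape=(20, 20, 20), spacing=(6.0, 6.0, 6.0),
                           origin=(-55.0, -52.0, -58.0))
        ref = Volume(data=np.zeros(shifted.shape), affine=shifted.affine)
        a = apply_chain(TransformChain(), template, ref, cval=-1000.0)
        b = resample_to(template, ref, "linear", cval=-1000.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_mask_nearest_stays_binary(self, phantom):
        template, truth = phantom
        chain = TransformChain(rigid=RigidTransform(
            rotation=np.deg2rad([1.0, 2.0, -1.0]), translation=[3.0, -2.0, 4.0]))
        out = apply_chain(chain, truth.head_support_mask, template,
                          interpolation="nearest")
        assert isinstance(out, MaskVolume)

    def test_synchronization_same_mapping(self, phantom):
        # warping the same fiducial volume as "CT" and as "dose" through one
        # chain must give identical voxel values
        template, truth = phantom
        rng = np.random.default_rng(3)
        fiducial = Volume(data=rng.random(template.shape),
                          affine=template.affine)
        disp = _smooth_vector_field(
            GridSpec(shape=template.shape, spacing=tuple(template.spacing),
                     origin=tuple(template.affine[:3, 3])),
            rng, 20.0, 3.0, np.ones(template.shape, dtype=bool))
        chain = TransformChain(
            rigid=RigidTransform(rotation=np.deg2rad([2.0, -1.0, 1.0]),
                                 translation=[4.0, 2.0, -3.0]),
            deformation=DeformationField(disp=disp, affine=template.affine))
        as_ct = apply_chain(chain, fiducial, template, "linear", cval=-1024.0)
        as_dose = apply_chain(chain, fiducial, template, "linear", cval=0.0)
        inside = as_ct.data != -1024.0
        np.testing.assert_array_equal(as_ct.data[inside],
                                      as_dose.data[inside])

    def test_dose_mass_approximately_conserved(self, reg_grid):
        from doseatlas.synthetic_cohort import (SubjectRecord, sample_subject,
                                                simulate_dose)
        template, truth = make_template_phantom(reg_grid, seed=11)
        params = PhantomParams(noise_sigma_gy=0.0, hu_noise=0.0)
        rec = SubjectRecord(id="m", age=50.0, gender="male", t_stage="T3",
                            technique="IMRT", prescription_dose=70.4)
        rec_dose = simulate_dose(rec, truth.head_support_mask,
                                 truth.target_center, params, seed=0)
        extra = {"dose": rec_dose}
        subj, chain = sample_subject(template, rec, seed=9, deform_scale=3.0,
                                     rigid_max_mm=5.0, rigid_max_deg=4.0,
                                     params=params, extra_volumes=extra)
        warped_back = apply_chain(chain, extra["dose"], template, cval=0.0)
        m0 = rec_dose.data.sum() * rec_dose.voxel_volume_mm3
        m1 = warped_back.data.sum() * warped_back.voxel_volume_mm3
        assert abs(m1 - m0) <= 0.05 * m0


class TestInvertDisplacement:
    def test_fixed_point_inverse(self, small_grid):
        rng = np.random.default_rng(4)
        disp = _smooth_vector_field(small_grid, rng, 20.0, 3.0,
                                    np.ones(small_grid.shape, dtype=bool))
        fld = DeformationField(disp=disp, affine=small_grid.affine)

        def fwd(pts):
            return pts + fld.sample(pts)

        inv = invert_displacement(fwd, small_grid)
        xs, ys, zs = small_grid.world_coords()
        pts = np.stack(np.broadcast_arrays(xs, ys, zs),
                       axis=-1).reshape(-1, 3)
        # interior points only (the field extrapolates at the border)
        sel = np.all(np.abs(pts) < 40, axis=1)
        err = fwd(pts[sel] + inv.sample(pts[sel])) - pts[sel]
        assert np.abs(err).max() < 0.05


class TestChainSerialization:
    def test_round_trip(self, tmp_path, small_grid):
        rng = np.random.default_rng(5)
        disp = _smooth_vector_field(small_grid, rng, 15.0, 2.0,
                                    np.ones(small_grid.shape, dtype=bool))
        chain = TransformChain(
            rigid=RigidTransform(rotation=[0.01, -0.02, 0.03],
                                 translation=[1.0, 2.0, 3.0],
                                 center=[0.0, 5.0, -4.0]),
            affine=AffineTransform(matrix=np.diag([1.05, 0.98, 1.0, 1.0])),
            deformation=DeformationField(disp=disp, affine=small_grid.affine,
                                         smoothing_mm=8.0))
        save_chain(chain, tmp_path, stem="test")
        back = load_chain(tmp_path / "test.json")
        pts = rng.uniform(-40, 40, (20, 3))
        np.testing.assert_allclose(back.map_points(pts),
                                   chain.map_points(pts), atol=1e-4)
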