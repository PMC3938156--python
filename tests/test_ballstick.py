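import numpy as np
import pytest

from conftest import angle_deg
from stickflow.ballstick import (
    StickField,
    WindowDegenerateError,
    build_window,
    canonical,
    decompose_sources,
    fit_single_stick,
    fit_stick_field,
    fit_voxel_icabsm,
    window_offsets,
)
from stickflow.io import DWIVolume, GradientTable, RunConfig
from stickflow.phantom import (
    FiberBundleSpec,
    ball_stick_signal,
    make_crossing_phantom,
    simulate_subject,
)


def single_stick_profile(table, v, d=1.7e-3):
    b = table.bvals[table.dwi_mask]
    g = table.bvecs[table.dwi_mask]
    return np.exp(-b * d * (g @ np.asarray(v, float)) ** 2)


def stick_volume(table, v, fracs_by_voxel, shape=(5, 5, 5), d=1.7e-3, S0=1000.0):
    """Noise-free volume where every voxel holds one stick along v with a
    spatially varying fraction (callable of the voxel index)."""
    data = np.zeros(shape + (len(table),))
    for vox in np.ndindex(shape):
        f = fracs_by_voxel(vox)
        for i, (b, g) in enumerate(zip(table.bvals, table.bvecs)):
            data[vox][i] = ball_stick_signal(S0, b, g, [(v, f)], d)
    return DWIVolume(data, np.eye(4), [1, 1, 1])


class TestWindow:
    def test_layout_sizes(self):
        assert len(window_offsets("face7")) == 7
        assert len(window_offsets("inplane11")) == 11
        assert len(window_offsets("cube27")) == 27
        with pytest.raises(ValueError):
            window_offsets("donut")

    def test_interior_window_shape(self, gtab):
        vol = stick_volume(gtab, [1, 0, 0], lambda v: 0.5)
        w = build_window(vol, np.ones((5, 5, 5), bool), (2, 2, 2), gtab)
        assert w.data.shape == (11, 55)

    def test_edge_window_shrinks(self, gtab):
        vol = stick_volume(gtab, [1, 0, 0], lambda v: 0.5)
        w = build_window(vol, np.ones((5, 5, 5), bool), (0, 0, 0), gtab)
        assert 3 <= len(w.members) < 11

    def test_mask_restriction_and_degeneracy(self, gtab):
        vol = stick_volume(gtab, [1, 0, 0], lambda v: 0.5)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(WindowDegenerateError):
            build_window(vol, mask, (2, 2, 2), gtab)

    def test_zero_s0_row_dropped(self, gtab):
        vol = stick_volume(gtab, [1, 0, 0], lambda v: 0.5)
        vol.data[3, 2, 2] = 0.0
        w = build_window(vol, np.ones((5, 5, 5), bool), (2, 2, 2), gtab)
        assert len(w.members) == 10


class TestDecomposition:
    def test_rank_one_window_single_component(self, gtab):
        # all rows proportional to one stick population
        vol = stick_volume(gtab, [0, 1, 0], lambda v: 0.3 + 0.05 * v[0])
        w = build_window(vol, np.ones((5, 5, 5), bool), (2, 2, 2), gtab)
        profs = decompose_sources(w, 3)
        assert len(profs) == 1

    def test_crossing_window_two_components_span_truth(self, gtab, crossing90):
        vol, truth = crossing90
        w = build_window(vol, truth.analysis_mask, (8, 8, 4), gtab)
        profs = decompose_sources(w, 3)
        assert len(profs) == 2
        S = np.array([p - p.mean() for p in profs]).T  # span, centered
        for v in ([1, 0, 0], [0, 1, 0]):
            t = single_stick_profile(gtab, v)
            t = t - t.mean()
            coef, *_ = np.linalg.lstsq(S, t, rcond=None)
            resid = t - S @ coef
            cosdist = np.linalg.norm(resid) / np.linalg.norm(t)
            assert cosdist < 0.05

    def test_cap_by_rank(self, gtab, crossing90):
        vol, truth = crossing90
        w = build_window(vol, truth.analysis_mask, (8, 8, 4), gtab)
        profs = decompose_sources(w, 3)
        assert len(profs) <= 2  # rank-2 data keeps at most 2 components


class TestSingleStickFit:
    def test_round_trip_orientation(self, gtab):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            vr, dr = fit_single_stick(single_stick_profile(gtab, v), gtab)
            assert angle_deg(vr, v) < 0.5
            assert dr == pytest.approx(1.7e-3, rel=0.1)

    def test_flat_profile_isotropic(self, gtab):
        v, d = fit_single_stick(np.full(55, 0.4), gtab)
        assert v is None and d is None

    def test_scale_invariance(self, gtab):
        p = single_stick_profile(gtab, [0.6, 0.8, 0.0])
        v1, _ = fit_single_stick(p, gtab)
        v2, _ = fit_single_stick(3.7 * p, gtab)
        assert angle_deg(v1, v2) < 1e-3

    def test_canonical_representative(self):
        v = np.array([-0.6, 0.8, 0.0])
        assert canonical(v)[0] > 0
        np.testing.assert_allclose(canonical(v), -v)
        np.testing.assert_allclose(canonical(-v), -v)


class TestVoxelFit:
    def test_single_bundle_noise_free(self, gtab, config):
        v = np.array([0.48, 0.64, 0.6])
        v /= np.linalg.norm(v)
        vol = stick_volume(gtab, v,
                           lambda vox: 0.5 + 0.04 * (vox[0] - 2) + 0.02 * (vox[1] - 2))
        sv = fit_voxel_icabsm(vol, np.ones((5, 5, 5), bool), gtab, (2, 2, 2),
                              config)
        assert len(sv.fractions) == 1
        assert angle_deg(sv.orientations[0], v) < 1.0
        assert sv.fractions[0] == pytest.approx(0.5, abs=0.02)
        assert sv.fractions.sum() + sv.ball_fraction == pytest.approx(1.0, abs=1e-6)

    def test_background_ball_only(self, gtab, crossing90, config):
        vol, truth = crossing90
        mask = np.ones(truth.fractions.shape[:3], bool)
        corner = (1, 14, 7)
        assert truth.fractions[corner].sum() == 0
        sv = fit_voxel_icabsm(vol, mask, gtab, corner, config)
        assert len(sv.fractions) == 0
        assert sv.ball_fraction == pytest.approx(1.0)

    def test_crossing_noise_free(self, gtab, crossing90, config):
        vol, truth = crossing90
        sv = fit_voxel_icabsm(vol, truth.analysis_mask, gtab, (8, 8, 4), config)
        assert len(sv.fractions) == 2
        np.testing.assert_allclose(np.sort(sv.fractions), [0.4, 0.4], atol=0.01)
        errs = sorted(
            min(angle_deg(o, t) for o in sv.orientations)
            for t in ([1, 0, 0], [0, 1, 0])
        )
        assert errs[-1] < 1.0

    def test_antipodal_input_invariance(self, gtab, config):
        # (g.v)^2 makes +v and -v the same physical stick; outputs are
        # canonical representatives either way
        v = np.array([0.0, 0.6, 0.8])
        vol = stick_volume(gtab, v, lambda vox: 0.4 + 0.03 * vox[0])
        vol_neg = stick_volume(gtab, -v, lambda vox: 0.4 + 0.03 * vox[0])
        np.testing.assert_allclose(vol.data, vol_neg.data)
        sv = fit_voxel_icabsm(vol, np.ones((5, 5, 5), bool), gtab, (2, 2, 2),
                              config)
        assert canonical(sv.orientations[0])[np.flatnonzero(sv.orientations[0])[0]] > 0

    def test_rotation_equivariance(self, gtab, config):
        vol, truth = make_crossing_phantom(60.0, (0.4, 0.4),
                                           grid_shape=(14, 14, 9), table=gtab,
                                           snr=np.inf)
        c = (7, 7, 4)
        sv = fit_voxel_icabsm(vol, truth.analysis_mask, gtab, c, config)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rot_vol = DWIVolume(np.rot90(vol.data, k=1, axes=(0, 1)), vol.affine,
                            vol.voxel_dims)
        rot_mask = np.rot90(truth.analysis_mask, k=1, axes=(0, 1))
        rot_tab = GradientTable(gtab.bvals, gtab.bvecs @ Rz.T)
        c_rot = (14 - 1 - c[1], c[0], c[2])
        sv_rot = fit_voxel_icabsm(rot_vol, rot_mask, rot_tab, c_rot, config)
        assert len(sv_rot.fractions) == len(sv.fractions) == 2
        for o in sv.orientations:
            assert min(angle_deg(Rz @ o, o2) for o2 in sv_rot.orientations) < 2.0


class TestFieldFit:
    def test_no_stick_density_counting(self):
        shape = (10, 10, 10)
        fr = np.zeros(shape + (3,))
        flat = fr.reshape(-1, 3)
        flat[: 1000 - 130, 0] = 0.5  # 130 stickless voxels out of 1000
        field = StickField(np.zeros(shape + (3, 3)), fr, np.zeros(shape),
                           np.zeros(shape), np.ones(shape, bool))
        assert field.no_stick_density() == pytest.approx(0.130)
        assert field.no_stick_density(np.zeros(shape, bool)) == 1.0

    def test_all_background_density_one(self, gtab_small, config):
        data = np.full((6, 6, 4, len(gtab_small)), 1000.0)
        dwi = gtab_small.dwi_mask
        data[..., dwi] = 1000.0 * np.exp(-1.7)  # pure isotropic attenuation
        vol = DWIVolume(data, np.eye(4), [1, 1, 1])
        field, density = fit_stick_field(vol, np.ones((6, 6, 4), bool),
                                         gtab_small, config)
        assert density == 1.0

    def test_field_round_trip(self, tmp_path, gtab, crossing90, config):
        vol, truth = crossing90
        mask = np.zeros(truth.analysis_mask.shape, bool)
        mask[6:11, 6:11, 3:6] = truth.analysis_mask[6:11, 6:11, 3:6]
        field, density = fit_stick_field(vol, mask, gtab, config)
        field.save(tmp_path / "f")
        back = StickField.load(tmp_path / "f")
        np.testing.assert_allclose(back.fractions, field.fractions, atol=1e-6)
        np.testing.assert_allclose(back.orientations, field.orientations,
                                   atol=1e-6)
        np.testing.assert_array_equal(back.mask, field.mask)

    def test_fraction_simplex_invariant(self, gtab, crossing90, config):
        vol, truth = crossing90
        mask = np.zeros(truth.analysis_mask.shape, bool)
        mask[7:10, 7:10, 4] = truth.analysis_mask[7:10, 7:10, 4]
        field, _ = fit_stick_field(vol, mask, gtab, config)
        for vox in zip(*np.nonzero(mask)):
            total = field.fractions[vox].sum() + field.ball_fraction[vox]
            assert total == pytest.approx(1.0, abs=1e-6)
            assert np.all(field.fractions[vox] >= 0)
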