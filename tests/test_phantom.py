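import numpy as np
import pytest

from conftest import angle_deg
from stickflow.phantom import (
    DEFAULT_S0,
    FiberBundleSpec,
    ball_stick_signal,
    cerebellum_bundles,
    default_gradient_table,
    dispersed_directions,
    make_crossing_phantom,
    rasterize_bundles,
    simulate_cohort,
    simulate_metric_records,
    simulate_subject,
)
from stickflow.phantom import _motion_walk


class TestForwardModel:
    def test_pure_ball(self):
        s = ball_stick_signal(1000.0, 1000.0, [0, 0, 1], [], 1e-3)
        assert s == pytest.approx(1000.0 * np.exp(-1.0), rel=1e-12)

    def test_stick_perpendicular_no_attenuation(self):
        s = ball_stick_signal(1000.0, 1000.0, [0, 1, 0], [([1, 0, 0], 1.0)], 1.7e-3)
        assert s == pytest.approx(1000.0)

    def test_stick_parallel(self):
        s = ball_stick_signal(1000.0, 1000.0, [1, 0, 0], [([1, 0, 0], 1.0)], 1.7e-3)
        assert s == pytest.approx(1000.0 * np.exp(-1.7), rel=1e-12)

    def test_b0_returns_s0(self):
        s = ball_stick_signal(850.0, 0.0, [1, 0, 0],
                              [([0, 1, 0], 0.4), ([1, 0, 0], 0.3)], 1.7e-3)
        assert s == pytest.approx(850.0)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            ball_stick_signal(1000, 1000, [1, 0, 0],
                              [([1, 0, 0], 0.7), ([0, 1, 0], 0.5)], 1.7e-3)

    def test_monotone_in_projection(self):
        # signal decreases as the gradient aligns with the stick
        v = np.array([0.0, 0.0, 1.0])
        prev = np.inf
        for t in np.linspace(0, np.pi / 2, 12):
            g = [np.sin(np.pi / 2 - t), 0.0, np.cos(np.pi / 2 - t)]
            s = ball_stick_signal(1000, 1000, g, [(v, 0.8)], 1.7e-3)
            assert s <= prev + 1e-9
            prev = s


class TestDirections:
    def test_unit_and_dispersed(self):
        d = dispersed_directions(55)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 0.995  # no near-duplicate axes


class TestSimulateSubject:
    def test_noise_free_matches_forward_model(self, gtab):
        bu = FiberBundleSpec([[2, 5, 4], [10, 5, 4]], 1.5, 0.5)
        vol, truth = simulate_subject([bu], (12, 10, 8), gtab, snr=np.inf)
        vox = (6, 5, 4)
        sticks = [(truth.orientations[vox][k], truth.fractions[vox][k])
                  for k in range(3) if truth.fractions[vox][k] > 0]
        for i, (b, g) in enumerate(zip(gtab.bvals, gtab.bvecs)):
            expected = ball_stick_signal(truth.S0_map[vox], b, g, sticks, truth.d)
            assert vol.data[vox][i] == pytest.approx(expected, rel=1e-10)

    def test_same_seed_bit_identical(self, gtab):
        bu = FiberBundleSpec([[2, 5, 4], [10, 5, 4]], 1.5, 0.5)
        kw = dict(snr=25, motion_amplitude=1.0, outlier_rate=0.1, rng_seed=42)
        v1, t1 = simulate_subject([bu], (12, 10, 8), gtab, **kw)
        v2, t2 = simulate_subject([bu], (12, 10, 8), gtab, **kw)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(t1.motion_params, t2.motion_params)
        np.testing.assert_array_equal(t1.outlier_frames, t2.outlier_frames)

    def test_outlier_injection_recorded_and_real(self, gtab):
        bu = FiberBundleSpec([[2, 5, 4], [10, 5, 4]], 1.5, 0.5)
        clean, _ = simulate_subject([bu], (12, 10, 8), gtab, snr=np.inf,
                                    outlier_rate=0.0, rng_seed=3)
        noisy, truth = simulate_subject([bu], (12, 10, 8), gtab, snr=np.inf,
                                        outlier_rate=0.1, rng_seed=3)
        assert len(truth.outlier_frames) > 0
        for fi in truth.outlier_frames:
            ratio = noisy.data[..., fi] / np.clip(clean.data[..., fi], 1e-9, None)
            r = np.median(ratio)
            assert 0.2 <= r <= 0.6  # dropout scale inside the declared range
        untouched = sorted(set(range(len(gtab))) - set(truth.outlier_frames.tolist()))
        np.testing.assert_allclose(noisy.data[..., untouched],
                                   clean.data[..., untouched])

    def test_rician_pure_noise_mean(self):
        # signal ~0 relative to sigma: magnitude is Rayleigh with
        # mean sigma*sqrt(pi/2)
        tab = default_gradient_table(25)
        vol, _ = simulate_subject([], (20, 20, 10), tab, snr=1e-3, S0=1.0,
                                  rng_seed=0)
        sigma = 1.0 / 1e-3
        samples = vol.data.ravel()
        assert len(samples) >= 1e5
        assert np.mean(samples) == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                                 rel=0.02)

    def test_overlapping_overfull_bundles_rejected(self, gtab_small):
        b1 = FiberBundleSpec([[2, 5.5, 4.5], [10, 5.5, 4.5]], 1.5, 0.6)
        b2 = FiberBundleSpec([[2, 5.5, 4.5], [10, 5.5, 4.5]], 1.5, 0.6)
        with pytest.raises(ValueError):
            rasterize_bundles([b1, b2], (12, 10, 8))


class TestMotionWalk:
    def test_expected_index_calibration(self):
        rng = np.random.default_rng(0)
        p = _motion_walk(4000, 2.0, rng)
        index = np.sum(np.mean(np.abs(np.diff(p, axis=0)), axis=0))
        assert index == pytest.approx(2.0, rel=0.1)

    def test_zero_amplitude_is_static(self):
        p = _motion_walk(10, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(p, 0.0)


class TestCrossingPhantom:
    def test_center_geometry(self, crossing90):
        _, truth = crossing90
        c = (8, 8, 4)
        fr = truth.fractions[c]
        assert (fr > 0).sum() == 2
        v1, v2 = truth.orientations[c][0], truth.orientations[c][1]
        assert angle_deg(v1, v2) == pytest.approx(90.0, abs=0.5)
        assert 1.0 - fr.sum() == pytest.approx(0.2, abs=1e-9)

    def test_end_caps_disjoint_nonempty(self, crossing90):
        _, truth = crossing90
        caps = list(truth.target_masks.values())
        assert len(caps) == 4
        for m in caps:
            assert m.sum() >= 1
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.any(caps[i] & caps[j])

    def test_angle_bounds(self, gtab_small):
        with pytest.raises(ValueError):
            make_crossing_phantom(0.0, table=gtab_small)
        with pytest.raises(ValueError):
            make_crossing_phantom(95.0, table=gtab_small)


class TestCohort:
    def test_cohort_sizes_and_degradation(self, gtab):
        subs, cov = simulate_cohort(n_per_group=(2, 3), snr=np.inf,
                                    effect=0.3, degraded_pathway="R_VDN",
                                    grid_shape=(32, 32, 12), table=gtab,
                                    rng_seed=0)
        assert len(subs) == 5 and len(cov) == 5
        assert [c["group"] for c in cov] == ["A", "A", "B", "B", "B"]
        # group B carries reduced core fraction only along the degraded bundle
        a_fr = subs[0]["truth"].fractions
        b_fr = subs[2]["truth"].fractions
        assert a_fr.max() == pytest.approx(0.55, abs=1e-9)
        degraded_region = subs[2]["truth"].target_masks["R_VDN"]
        assert b_fr.max() == pytest.approx(0.55, abs=1e-9)  # intact bundles
        near = np.argwhere(degraded_region)
        vals = [b_fr[tuple(v)].max() for v in near if b_fr[tuple(v)].max() > 0]
        assert max(vals) == pytest.approx(0.55 * 0.7, abs=1e-9)

    def test_mask_contracts(self):
        _, seed, targets = cerebellum_bundles((32, 32, 12))
        masks = [seed] + list(targets.values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i] & masks[j])

    def test_study_sample_sizes(self):
        recs = simulate_metric_records(n_per_group=(14, 15), rng=0)
        assert len(recs) == 29
        assert sum(r["group"] == "A" for r in recs) == 14

    def test_metric_records_effect_shift(self):
        rng = np.random.default_rng(1)
        recs = simulate_metric_records((500, 500), effect_sd=2.0,
                                       affected=("R_VDN",), rng=rng)
        import pandas as pd

        df = pd.DataFrame(recs)
        a = df[df.group == "A"]
        b = df[df.group == "B"]
        shift = a["FA_R_VDN"].mean() - b["FA_R_VDN"].mean()
        assert shift == pytest.approx(2.0 * 0.03, abs=0.01)
        assert abs(a["FA_L_DDN"].mean() - b["FA_L_DDN"].mean()) < 0.01
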