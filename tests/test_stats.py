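import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stickflow.phantom import simulate_metric_records
from stickflow.stats import (
    PATHWAYS,
    age_regression,
    empirical_cdf,
    flag_table,
    glm_group_test,
    partial_correlation,
)


def null_records(rng, n=(14, 15), **kw):
    return simulate_metric_records(n_per_group=n, effect_sd=0.0, rng=rng, **kw)


class TestGroupGLM:
    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(0)
        recs_a = null_records(rng, n=(14, 14))
        # group B is a value-for-value copy of group A
        for i, r in enumerate(recs_a):
            r["group"] = "A" if i < 14 else "B"
            if i >= 14:
                src = recs_a[i - 14]
                for k in list(r):
                    if k not in ("group", "subject_id"):
                        r[k] = src[k]
        res = glm_group_test(recs_a, "FA")
        for r in res:
            assert r.p_value == pytest.approx(1.0, abs=1e-10)
            assert r.estimate == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_covariates_reduce_to_t_test(self):
        rng = np.random.default_rng(1)
        recs = null_records(rng)
        for r in recs:
            r["age"] = 5.0  # constant -> dropped
            r["motion"] = 1.0
        res = glm_group_test(recs, "FA")
        df = pd.DataFrame(recs)
        for r in res:
            a = df[df.group == "A"][f"FA_{r.pathway}"]
            b = df[df.group == "B"][f"FA_{r.pathway}"]
            t, p = sps.ttest_ind(a, b)
            assert r.p_value == pytest.approx(p, abs=1e-10)
            assert r.estimate == pytest.approx(b.mean() - a.mean(), abs=1e-12)

    def test_effect_detected_with_covariates(self):
        rng = np.random.default_rng(2)
        recs = simulate_metric_records((14, 15), effect_sd=3.0,
                                       affected=("R_VDN",), rng=rng,
                                       age_slope=0.002, motion_slope=-0.005)
        res = {r.pathway: r for r in glm_group_test(recs, "FA")}
        assert res["R_VDN"].p_value < 0.01
        assert res["R_VDN"].estimate < 0

    def test_too_small_group_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            glm_group_test(null_records(rng, n=(2, 15)), "FA")

    def test_wilks_omnibus_reported(self):
        rng = np.random.default_rng(4)
        res = glm_group_test(null_records(rng), "FA")
        assert res[0].wilks_lambda is not None
        assert 0 < res[0].wilks_lambda <= 1.0 + 1e-9
        assert 0 <= res[0].wilks_p <= 1


class TestPartialCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(12):
            m = rng.normal()
            recs.append({"group": "B", "age": rng.uniform(3, 14),
                         "motion": rng.uniform(0.5, 3), "met": m,
                         "beh": 3.0 * m - 1.0})
        r, p = partial_correlation(recs, "met", "beh")
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-9

    def test_sign_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(15):
            age = rng.uniform(3, 14)
            mot = rng.uniform(0.5, 3)
            m = rng.normal() + 0.1 * age
            recs.append({"group": "B", "age": age, "motion": mot, "met": m,
                         "beh": 0.5 * m + rng.normal()})
        r1, _ = partial_correlation(recs, "met", "beh")
        for rec in recs:
            rec["age"] *= 12.0  # years -> months
        r2, _ = partial_correlation(recs, "met", "beh")
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_degrees_of_freedom_in_p(self):
        rng = np.random.default_rng(2)
        recs = [{"group": "B", "age": rng.uniform(3, 14),
                 "motion": rng.uniform(0.5, 3), "met": rng.normal(),
                 "beh": rng.normal()} for _ in range(10)]
        r, p = partial_correlation(recs, "met", "beh")
        t = r * np.sqrt((10 - 4) / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 6), abs=1e-12)


class TestEmpiricalCDF:
    def test_quarter_steps(self):
        t = empirical_cdf([3.0, 1.0, 2.0, 4.0])
        np.testing.assert_allclose(t["cdf"], [0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(t["value"], [1, 2, 3, 4])

    def test_max_reaches_one(self):
        assert empirical_cdf([5.0, 1.0])["cdf"].iloc[-1] == 1.0

    def test_stochastic_dominance_of_shifted_sample(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        cx = empirical_cdf(x)
        cy = empirical_cdf(x + 1.0)
        grid = np.linspace(-3, 3, 25)
        fx = np.interp(grid, cx["value"], cx["cdf"], left=0, right=1)
        fy = np.interp(grid, cy["value"], cy["cdf"], left=0, right=1)
        assert np.all(fy <= fx + 1e-12)


class TestFlagTable:
    def test_copy_group_self_consistency_three_se(self):
        # with B a value-for-value copy of A, the three-SE criterion flags
        # the same members of A that fall below mean - (3/sqrt(14)) SD,
        # i.e. about Phi(-0.80) ~ 21% of a Gaussian group
        rng = np.random.default_rng(0)
        recs = null_records(rng, n=(14, 14))
        for i in range(14, 28):
            src = recs[i - 14]
            for k in src:
                if k not in ("group", "subject_id"):
                    recs[i][k] = src[k]
        t = flag_table(recs, ["FA"])
        expected = 100 * sps.norm.cdf(-3.0 / np.sqrt(14))
        assert (t["three_se"] - expected).abs().max() <= 15

    def test_constructed_eleven_of_fifteen(self):
        # reference group tightly at 0.27; 11 of 15 B subjects well below the
        # three-SE threshold
        recs = []
        for i in range(14):
            recs.append({"subject_id": f"a{i}", "group": "A", "age": 5.0 + i,
                         "motion": 1.0, "FA_R_VDN": 0.27 + 0.001 * (i % 3)})
        for i in range(15):
            val = 0.20 if i < 11 else 0.40
            recs.append({"subject_id": f"b{i}", "group": "B", "age": 5.0 + i,
                         "motion": 1.0, "FA_R_VDN": val})
        t = flag_table(recs, ["FA"], pathways=("R_VDN",))
        row = t[(t.pathway == "R_VDN") & (t.metric == "FA")].iloc[0]
        assert row["three_se"] == 73  # round(100 * 11 / 15)

    def test_leave_one_out_decile_calibration(self):
        rng = np.random.default_rng(5)
        recs = null_records(rng, n=(200, 2))
        t = flag_table(recs, ["FA"], leave_one_out=True)
        # each A subject scored against the remaining 199: ~10% flagged
        assert (t["lower_decile"] - 10).abs().max() <= 5


class TestAgeRegression:
    def test_exact_linear_relation(self):
        recs = [{"group": "A", "age": a, "resp": 2.0 - 0.05 * a}
                for a in np.linspace(3, 14, 10)]
        r2, p, slope = age_regression(recs, "resp")
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-0.05, abs=1e-12)

    def test_negated_response_symmetry(self):
        rng = np.random.default_rng(0)
        recs = [{"group": "A", "age": rng.uniform(3, 14), "resp": rng.normal()}
                for _ in range(14)]
        r2a, pa, sa = age_regression(recs, "resp")
        for r in recs:
            r["resp"] *= -1
        r2b, pb, sb = age_regression(recs, "resp")
        assert r2b == pytest.approx(r2a, abs=1e-12)
        assert sb == pytest.approx(-sa, abs=1e-12)

    def test_constant_age_rejected(self):
        recs = [{"group": "A", "age": 5.0, "resp": i} for i in range(5)]
        with pytest.raises(ValueError):
            age_regression(recs, "resp")
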