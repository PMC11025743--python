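"""Evaluation statistics: RMSE/r, CCC, MSEP decomposition, equivalence test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import silcal as sc
from silcal.modeleval import evaluate_property

pair_arrays = st.integers(5, 40).flatmap(
    lambda n: st.tuples(
        hnp.arrays(float, n, elements=st.floats(-100, 100, allow_nan=False, width=32)),
        hnp.arrays(float, n, elements=st.floats(-100, 100, allow_nan=False, width=32)),
    )
)


class TestErrorMetrics:
    def test_rmse_hand_value(self):
        rmse, _ = sc.error_metrics([0.0, 0.0], [3.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(25 / 2))
        assert rmse == pytest.approx(3.5355, abs=1e-4)

    def test_perfect_prediction(self):
        rmse, r = sc.error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        _, r = sc.error_metrics([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert r == pytest.approx(-1.0)

    def test_constant_vector_flags_r_undefined(self):
        rmse, r = sc.error_metrics([1.0, 2.0], [5.0, 5.0])
        assert np.isnan(r) and rmse > 0


class TestCCC:
    def test_identity_gives_one(self, rng):
        x = rng.normal(size=20)
        assert sc.ccc(x, x) == pytest.approx(1.0)

    def test_shifted_line_hand_value(self):
        assert sc.ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(4 / 7)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 15))
            obs = rng.normal(size=n)
            pred = rng.normal(size=n)
            if np.std(obs) == 0 or np.std(pred) == 0:
                continue
            _, r = sc.error_metrics(obs, pred)
            assert abs(sc.ccc(obs, pred)) <= abs(r) + 1e-12

    def test_both_constant_is_undefined(self):
        assert np.isnan(sc.ccc([2.0, 2.0], [2.0, 2.0]))

    def test_ccc_one_iff_identical(self, rng):
        obs = rng.normal(size=15)
        pred = obs + 1e-3
        assert sc.ccc(obs, pred) < 1.0
        assert sc.ccc(obs, obs.copy()) == pytest.approx(1.0, abs=1e-15)


class TestMSEP:
    def test_perfect_prediction_all_zero(self, rng):
        x = rng.normal(size=10)
        d = sc.msep_decompose(x, x)
        assert (d.msep, d.sb, d.maf, d.mof) == (0, 0, 0, 0)

    def test_pure_bias(self, rng):
        x = rng.normal(size=10)
        d = sc.msep_decompose(x, x + 1.0)
        assert d.msep == pytest.approx(1.0)
        assert d.sb == pytest.approx(1.0)
        assert d.maf == pytest.approx(0.0, abs=1e-12)
        assert d.mof == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_decomposition(self):
        d = sc.msep_decompose([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert d.msep == pytest.approx(1.0)
        assert (d.sb, d.maf, d.mof) == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)
        assert d.r == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(pair_arrays)
    def test_additivity_property(self, pair):
        obs, pred = pair
        d = sc.msep_decompose(obs, pred)
        assert abs(d.msep - (d.sb + d.maf + d.mof)) < 1e-10
        assert min(d.sb, d.maf, d.mof) >= 0

    def test_reordering_invariance(self, rng):
        obs, pred = rng.normal(size=15), rng.normal(size=15)
        perm = rng.permutation(15)
        d1, d2 = sc.msep_decompose(obs, pred), sc.msep_decompose(obs[perm], pred[perm])
        assert (d1.msep, d1.sb, d1.maf, d1.mof) == pytest.approx((d2.msep, d2.sb, d2.maf, d2.mof))


class TestEquivalenceTest:
    def test_perfect_non_identity_line_rejected(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        res = sc.equivalence_test(2.0 * pred, pred)
        assert res.degenerate and res.reject
        assert res.beta1 == pytest.approx(2.0)
        assert res.p_joint == 0.0

    def test_exact_identity_cannot_be_rejected(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        res = sc.equivalence_test(pred, pred)
        assert res.degenerate and not res.reject
        assert res.p_joint == 1.0

    def test_unbiased_noise_usually_accepted(self, rng):
        pred = rng.normal(30, 3, size=25)
        obs = pred + rng.normal(0, 1, size=25)
        res = sc.equivalence_test(obs, pred)
        assert res.p_joint > 0.0
        assert res.se0 > 0 and res.se1 > 0

    def test_constant_predictions_rejected_as_input(self):
        with pytest.raises(ValueError, match="constant"):
            sc.equivalence_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_agrees_with_direct_f_computation(self, rng):
        pred = rng.normal(size=30)
        obs = pred + rng.normal(0, 0.5, size=30)
        res = sc.equivalence_test(obs, pred)
        # independent oracle: textbook F statistic for the joint hypothesis
        import scipy.stats as st_
        A = np.column_stack([np.ones(30), pred])
        beta, *_ = np.linalg.lstsq(A, obs, rcond=None)
        resid = obs - A @ beta
        s2 = resid @ resid / (30 - 2)
        delta = beta - np.array([0.0, 1.0])
        F = delta @ (A.T @ A) @ delta / (2 * s2)
        p = st_.f.sf(F, 2, 28)
        assert res.p_joint == pytest.approx(p, rel=1e-8)


class TestReport:
    def _rows(self, rng, with_pred=True):
        rows = []
        for name in ("CP", "NDF", "starch"):
            obs_c = rng.normal(30, 3, 40)
            pred_c = obs_c + rng.normal(0, 0.5, 40)
            kw = dict(nvars=50, nlv=4, obs_cal=obs_c, pred_cal=pred_c,
                      rmsecv=0.6, r_cv=0.9)
            if with_pred:
                obs_p = rng.normal(30, 3, 15)
                kw.update(obs_pred=obs_p, pred_pred=obs_p + rng.normal(0, 0.5, 15))
            rows.append(evaluate_property(name, **kw))
        return rows

    def test_three_property_report_satisfies_invariants(self, rng):
        report = sc.build_report(self._rows(rng))
        assert len(report) == 3
        assert (report["RMSE_C"] >= 0).all() and (report["RMSE_P"] >= 0).all()
        assert report["R_P"].abs().le(1).all()
        assert np.allclose(report["MSEP"], report["SB"] + report["MaF"] + report["MoF"])

    def test_cv_only_report_lacks_prediction_columns(self, rng):
        report = sc.build_report(self._rows(rng, with_pred=False), mode="cv_only")
        assert "RMSE_P" not in report.columns and "R_P" not in report.columns
        assert "RMSE_CV" in report.columns

    def test_report_round_trips_through_csv(self, rng, tmp_path):
        report = sc.build_report(self._rows(rng))
        p = tmp_path / "report.csv"
        report.to_csv(p, index=False)
        import pandas as pd
        back = pd.read_csv(p)
        assert list(back.columns) == list(report.columns)
        assert np.allclose(back["RMSE_P"], report["RMSE_P"])
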