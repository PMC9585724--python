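import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bpmeth import bp, synthetic as syn


class TestIndicators:
    def test_representative_median_worked_example(self):
        m, _ = bp.compute_indicators(115.0, 64.9)
        assert round(float(m), 1) == 81.6

    def test_simple_values(self):
        m, p = bp.compute_indicators(120.0, 60.0)
        assert m == pytest.approx(80.0)
        assert p == pytest.approx(60.0)

    def test_rejects_inverted_pressures(self):
        with pytest.raises(ValueError):
            bp.compute_indicators(80.0, 90.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(60, 250), st.floats(30, 190))
    def test_map_minus_dbp_equals_pp_over_three(self, sbp, dbp):
        if sbp <= dbp:
            sbp = dbp + 1.0
        m, p = bp.compute_indicators(sbp, dbp)
        assert m - dbp == pytest.approx(p / 3, rel=1e-12)


class TestWindow:
    @pytest.mark.parametrize("week,expected", [(26.9, "early"),
                                               (27.0, "early"),
                                               (27.1, "late")])
    def test_boundary_assignment(self, week, expected):
        assert bp.assign_window([week])[0] == expected

    def test_rejects_nonpositive_week(self):
        with pytest.raises(ValueError):
            bp.assign_window([0.0])


def _flat_records(n_subjects=20, level=110.0, seed=0):
    trends = {"sbp": lambda w: np.full_like(np.asarray(w, float), level),
              "dbp": lambda w: np.full_like(np.asarray(w, float), level - 45)}
    rec, _ = syn.generate_bp_records(n_subjects, (3, 6), 0.0, 0.0, 0.0,
                                     seed=seed, trends=trends)
    return bp.add_indicators(rec)


class TestTrend:
    def test_flat_trend_recovered_exactly(self):
        rec = _flat_records()
        trend = bp.estimate_trend(rec, "sbp")
        grid = np.linspace(9, 40, 100)
        assert np.abs(trend(grid) - 110.0).max() < 1e-6
        assert trend.grand_mean == pytest.approx(110.0, abs=1e-6)

    def test_cubic_trend_recovered_within_1mmhg(self):
        rec, _ = syn.generate_bp_records(500, (5, 13), 6.0, 8.0, 0.5, seed=4)
        rec = bp.add_indicators(rec)
        trend = bp.estimate_trend(rec, "sbp")
        grid = np.linspace(10, 40, 200)
        truth = syn.default_trends()["sbp"](grid)
        assert np.abs(trend(grid) - truth).max() < 1.0

    def test_insufficient_span_raises(self):
        rec = pd.DataFrame({"subject_id": ["a"] * 10,
                            "week": np.linspace(20, 23, 10),
                            "sbp": np.full(10, 115.0),
                            "dbp": np.full(10, 65.0)})
        with pytest.raises(ValueError):
            bp.estimate_trend(bp.add_indicators(rec), "sbp")


class TestDetrend:
    def test_flat_trend_detrend_is_identity(self):
        rec = _flat_records()
        trend = bp.estimate_trend(rec, "sbp")
        det = bp.detrend(rec, trend, "sbp")
        assert np.allclose(det["sbp"], rec["sbp"], atol=1e-6)

    def test_detrended_slope_vanishes(self):
        rec, _ = syn.generate_bp_records(500, (5, 13), 6.0, 8.0, 0.5, seed=5)
        rec = bp.add_indicators(rec)
        trend = bp.estimate_trend(rec, "sbp")
        det = bp.detrend(rec, trend, "sbp")
        slope = np.polyfit(det["week"], det["sbp"], 1)[0]
        assert abs(slope) < 0.02

    def test_detrend_is_idempotent(self):
        # the refitted trend on detrended data is flat up to the smoother's
        # statistical wiggle, so a second pass moves values by < 0.001 mmHg
        rec, _ = syn.generate_bp_records(300, (5, 10), 6.0, 8.0, 0.3, seed=6)
        rec = bp.add_indicators(rec)
        det1 = bp.detrend(rec, bp.estimate_trend(rec, "sbp"), "sbp")
        det2 = bp.detrend(det1, bp.estimate_trend(det1, "sbp"), "sbp")
        assert np.abs(det2["sbp"] - det1["sbp"]).max() < 1e-3

    def test_on_curve_measurement_maps_to_grand_mean(self):
        rec = _flat_records()
        trend = bp.estimate_trend(rec, "sbp")
        single = pd.DataFrame({"subject_id": ["x"], "week": [30.0],
                               "sbp": [110.0], "dbp": [65.0]})
        det = bp.detrend(single, trend, "sbp")
        assert det["sbp"].iloc[0] == pytest.approx(trend.grand_mean, abs=1e-6)


class TestTwoStage:
    def test_noise_free_balanced_returns_subject_means(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(15):
            b = rng.normal(0, 6)
            for w in (10.0, 20.0, 30.0, 40.0):
                rows.append((f"S{i}", w, 110.0 + b))
        rec = pd.DataFrame(rows, columns=["subject_id", "week", "sbp"])
        fit = bp.fit_two_stage(rec, "sbp")
        est = fit.summaries.set_index("subject_id")["bp_hat"]
        truth = rec.groupby("subject_id")["sbp"].mean()
        assert np.abs(est - truth).max() < 1e-10

    def test_all_identical_values_degenerate(self):
        rec = pd.DataFrame({"subject_id": ["a", "a", "b", "b"],
                            "week": [10.0, 20.0, 12.0, 25.0],
                            "sbp": [110.0] * 4})
        fit = bp.fit_two_stage(rec, "sbp")
        assert fit.sigma_b == 0.0 and fit.sigma_e == 0.0
        assert (fit.summaries["bp_hat"] == 110.0).all()

    def test_shrinkage_is_monotone_in_information(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            n_obs = 1 if i % 2 == 0 else 10
            b = rng.normal(0, 6)
            for w in np.linspace(10, 40, n_obs):
                rows.append((f"S{i:02d}", float(w),
                             112.0 + b + rng.normal(0, 8)))
        # two focal subjects with identical raw means but 1 vs 10 readings
        rows.append(("lone", 25.0, 130.0))
        for w in np.linspace(10, 40, 10):
            rows.append(("rich", float(w), 130.0))
        rec = pd.DataFrame(rows, columns=["subject_id", "week", "sbp"])
        fit = bp.fit_two_stage(rec, "sbp")
        est = fit.summaries.set_index("subject_id")["bp_hat"]
        assert abs(est["lone"] - fit.mu) < abs(est["rich"] - fit.mu)

    def test_bp_hat_shrinks_toward_grand_mean_from_gls_subject_mean(self):
        # exact BLUP algebra: bp_hat - mu = lambda_i (ytilde_i - mu) with
        # 0 <= lambda_i < 1, where ytilde is the GLS-weighted subject mean
        rec, _ = syn.generate_bp_records(80, (3, 8), 6.0, 8.0, 0.5, seed=7)
        rec = bp.add_indicators(rec)
        fit = bp.fit_two_stage(rec, "sbp")
        est = fit.summaries.set_index("subject_id")["bp_hat"]
        for sid, sub in rec.groupby("subject_id"):
            t = sub["week"].to_numpy()
            y = sub["sbp"].to_numpy()
            V = fit.sigma_b ** 2 + fit.sigma_e ** 2 * \
                fit.rho ** np.abs(t[:, None] - t[None, :])
            vi1 = np.linalg.solve(V, np.ones(len(t)))
            ytilde = (vi1 @ y) / vi1.sum()
            lo = min(ytilde, fit.mu) - 1e-8
            hi = max(ytilde, fit.mu) + 1e-8
            assert lo <= est[sid] <= hi

    def test_variance_components_recovered(self):
        rec, off = syn.generate_bp_records(600, (5, 13), 6.0, 8.0, 0.5,
                                           seed=8)
        rec = bp.add_indicators(rec)
        det = bp.detrend(rec, bp.estimate_trend(rec, "sbp"), "sbp")
        fit = bp.fit_two_stage(det, "sbp")
        assert 4.5 < fit.sigma_b < 7.5
        assert 7.0 < fit.sigma_e < 9.0
        assert 0.3 < fit.rho < 0.7
        est = fit.summaries.set_index("subject_id")["bp_hat"]
        assert np.corrcoef(est.loc[off.index], off)[0, 1] > 0.8


class TestPlausibility:
    def test_out_of_range_readings_dropped(self):
        rec = pd.DataFrame({
            "subject_id": ["a", "a", "a", "a"],
            "week": [10.0, 20.0, 30.0, 44.0],
            "sbp": [115.0, 270.0, 115.0, 115.0],
            "dbp": [65.0, 60.0, 65.0, 65.0]})
        kept, n_dropped = bp.apply_plausibility_filter(rec)
        assert n_dropped == 2
        assert len(kept) == 2


def test_summarize_bp_end_to_end(small_cohort):
    out = bp.summarize_bp(small_cohort.bp_records, "map", "early")
    assert set(out.columns) == {"subject_id", "window", "indicator",
                                "bp_hat", "n_obs"}
    assert (out["window"] == "early").all()
    assert out["bp_hat"].notna().all()
    assert (out["n_obs"] >= 1).all()
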