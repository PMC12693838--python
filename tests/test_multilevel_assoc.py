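"""Within/between correlation decomposition, adjustment, ICC and biserial estimates."""

import numpy as np
import pandas as pd
import pytest

from resthrv.multilevel_assoc import (
    EstimationError, adjust_between, align_lag, biserial_corr,
    correlation_report, daily_average, label_effect, multilevel_corr,
    variance_components,
)
from resthrv.synthetic_data import PanelDataset, PanelGenConfig, generate_panel


def make_panel(rows, persons=None):
    data = pd.DataFrame(rows, columns=["person_id", "day_index",
                                       "variable", "value"])
    if persons is None:
        persons = pd.DataFrame({"person_id": data["person_id"].unique()})
    return PanelDataset(data=data, persons=persons)


class TestDailyAverage:
    def test_multiple_administrations_averaged(self):
        panel = make_panel([("p1", 0, "stress", v) for v in (2, 4, 4, 6)])
        out = daily_average(panel, "stress")
        assert len(out.data) == 1
        assert out.data["value"].iloc[0] == 4.0

    def test_single_administration_unchanged(self):
        panel = make_panel([("p1", 0, "stress", 3.0), ("p1", 1, "stress", 5.0)])
        out = daily_average(panel, "stress")
        assert sorted(out.data["value"]) == [3.0, 5.0]

    def test_other_variables_untouched(self):
        panel = make_panel([("p1", 0, "stress", 2.0), ("p1", 0, "stress", 4.0),
                            ("p1", 0, "mood", 7.0)])
        out = daily_average(panel, "stress")
        assert (out.data["variable"] == "mood").sum() == 1


class TestAlignLag:
    def _panel(self):
        rows = []
        for d in range(5):
            rows.append(("p1", d, "hrv", 100.0 + d))
            rows.append(("p1", d, "stress", 10.0 + d))
        return make_panel(rows)

    def test_same_day_is_identity_join(self):
        paired = align_lag(self._panel(), ("hrv", "stress"), "same_day")
        assert len(paired) == 5
        assert (paired["hrv"] - paired["stress"]).eq(90.0).all()

    def test_next_night_pairs_health_day_t_with_hrv_day_t_plus_1(self):
        paired = align_lag(self._panel(), ("hrv", "stress"),
                           "health_day_to_next_night")
        row = paired[paired["day_index"] == 3].iloc[0]
        assert row["stress"] == 13.0
        assert row["hrv"] == 104.0  # the night after day 3

    def test_last_day_dropped_under_lag(self):
        paired = align_lag(self._panel(), ("hrv", "stress"),
                           "health_day_to_next_night")
        assert len(paired) == 4
        assert 4 not in paired["day_index"].values

    def test_unknown_lag_token_is_config_error(self):
        with pytest.raises(EstimationError, match="lag"):
            align_lag(self._panel(), ("hrv", "stress"), "yesterday")


class TestVarianceComponents:
    def test_equal_generating_variances_give_half(self):
        panel, _ = generate_panel(PanelGenConfig(n_persons=1200,
                                                 n_obs_per_person=8,
                                                 icc=(0.5, 0.5), seed=3))
        assert variance_components(panel, "x").icc == pytest.approx(0.5,
                                                                    abs=0.03)

    def test_no_between_variance_gives_icc_near_zero(self):
        rng = np.random.default_rng(0)
        rows = [(f"p{i}", d, "x", float(rng.normal()))
                for i in range(200) for d in range(6)]
        d = variance_components(make_panel(rows), "x")
        assert d.icc < 0.05
        assert d.var_bp >= 0.0

    def test_all_single_observation_is_an_error(self):
        panel = make_panel([(f"p{i}", 0, "x", float(i)) for i in range(5)])
        with pytest.raises(EstimationError, match="single"):
            variance_components(panel, "x")

    def test_missing_variable_is_an_error(self):
        panel = make_panel([("p1", 0, "x", 1.0), ("p1", 1, "x", 2.0),
                            ("p2", 0, "x", 1.5)])
        with pytest.raises(EstimationError):
            variance_components(panel, "nope")


class TestMultilevelCorr:
    def test_identity_pair_has_unit_correlations(self, identity_panel):
        est = multilevel_corr(identity_panel, ("x", "y"))
        assert est.within_r == pytest.approx(1.0, abs=1e-3)
        assert est.between_r == pytest.approx(1.0, abs=1e-3)

    def test_recovers_opposite_sign_levels(self):
        cfg = PanelGenConfig(n_persons=1000, n_obs_per_person=10,
                             between_corr=[[1, 0.5], [0.5, 1]],
                             within_corr=[[1, -0.2], [-0.2, 1]],
                             icc=(0.5, 0.5), seed=17)
        panel, _ = generate_panel(cfg)
        est = multilevel_corr(panel, ("x", "y"))
        assert abs(est.between_r - 0.5) <= 3 * est.between_se
        assert abs(est.within_r - (-0.2)) <= 3 * est.within_se

    def test_no_level_leakage(self):
        # pure between-level association leaves the within estimate null
        cfg = PanelGenConfig(n_persons=1000, n_obs_per_person=10,
                             between_corr=[[1, 0.3], [0.3, 1]],
                             icc=(0.5, 0.5), seed=23)
        panel, _ = generate_panel(cfg)
        est = multilevel_corr(panel, ("x", "y"))
        assert abs(est.within_r) <= 3 * est.within_se

    def test_moments_and_ml_agree_with_many_observations(self):
        cfg = PanelGenConfig(n_persons=300, n_obs_per_person=25,
                             between_corr=[[1, 0.4], [0.4, 1]],
                             within_corr=[[1, 0.15], [0.15, 1]],
                             icc=(0.6, 0.6), seed=31)
        panel, _ = generate_panel(cfg)
        ml_est = multilevel_corr(panel, ("x", "y"), estimator="ml_latent")
        mo_est = multilevel_corr(panel, ("x", "y"),
                                 estimator="moments_observed")
        assert abs(ml_est.within_r - mo_est.within_r) < 0.02
        assert abs(ml_est.between_r - mo_est.between_r) < 0.02

    def test_too_few_paired_observations_is_an_error(self):
        panel = make_panel([("p1", 0, "x", 1.0), ("p1", 0, "y", 2.0)])
        with pytest.raises(EstimationError):
            multilevel_corr(panel, ("x", "y"))

    def test_person_level_binary_guarded(self):
        panel, _ = generate_panel(PanelGenConfig(
            n_persons=50, n_obs_per_person=4, variables=("x", "diag"),
            binary_specs={"diag": 0.4}, seed=0))
        with pytest.raises(EstimationError, match="biserial"):
            multilevel_corr(panel, ("x", "diag"))


class TestAdjustment:
    def test_independent_covariates_leave_estimate_unchanged(self):
        cfg = PanelGenConfig(n_persons=600, n_obs_per_person=8,
                             between_corr=[[1, 0.4], [0.4, 1]],
                             icc=(0.5, 0.5), seed=5)
        panel, _ = generate_panel(cfg)
        raw = multilevel_corr(panel, ("x", "y"))
        adj = multilevel_corr(panel, ("x", "y"), covariates=("age", "gender"))
        assert adj.adjusted_for == ("age", "gender")
        assert abs(adj.between_r - raw.between_r) < 0.03
        assert adj.within_r == pytest.approx(raw.within_r, abs=1e-3)

    def test_perfect_confounding_residualizes_to_zero(self):
        persons = pd.DataFrame({"person_id": [f"p{i}" for i in range(50)],
                                "age": np.linspace(20, 60, 50),
                                "gender": np.tile([0, 1], 25)})
        values = pd.Series(2.0 * persons["age"].to_numpy() + 1.0,
                           index=persons["person_id"])
        resid = adjust_between(values, persons, covariates=("age", "gender"))
        assert np.max(np.abs(resid)) < 1e-8

    def test_adjustment_recovers_partial_correlation(self):
        # both variables loaded on age: marginal between-r is inflated,
        # the adjusted estimate recovers the generating latent correlation
        cfg = PanelGenConfig(n_persons=1500, n_obs_per_person=6,
                             between_corr=[[1, 0.3], [0.3, 1]],
                             icc=(0.5, 0.5),
                             covariate_effects={"x": (0.8, 0.0),
                                                "y": (0.8, 0.0)},
                             seed=19)
        panel, _ = generate_panel(cfg)
        raw = multilevel_corr(panel, ("x", "y"))
        adj = multilevel_corr(panel, ("x", "y"), covariates=("age", "gender"))
        assert raw.between_r > adj.between_r  # confounding inflates
        assert abs(adj.between_r - 0.3) <= 3 * adj.between_se

    def test_constant_covariate_dropped_with_warning(self):
        persons = pd.DataFrame({"person_id": ["p1", "p2", "p3"],
                                "age": [30.0, 30.0, 30.0],
                                "gender": [0, 1, 0]})
        values = pd.Series([1.0, 2.0, 3.0], index=persons["person_id"])
        resid = adjust_between(values, persons)
        assert len(resid) == 3  # age dropped, gender used; no crash


class TestBiserial:
    def test_equal_class_means_give_zero(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        assert biserial_corr(y, g).between_r == pytest.approx(0.0, abs=1e-12)

    def test_recovers_latent_correlation_at_median_split(self):
        rng = np.random.default_rng(42)
        n, rho = 20000, 0.4
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        g = (z[:, 1] > 0).astype(int)  # dichotomized at its median
        est = biserial_corr(z[:, 0], g)
        assert est.between_r == pytest.approx(rho, abs=0.03)
        assert est.type == "biserial"

    def test_small_sample_clipped_and_flagged(self):
        y = np.array([0.0, 0.001, 1.0, 1.001])
        g = np.array([0, 0, 1, 1])
        est = biserial_corr(y, g)
        assert abs(est.between_r) <= 1.0
        assert "clipped" in est.flags

    def test_single_class_is_an_error(self):
        with pytest.raises(EstimationError, match="dichotomy"):
            biserial_corr(np.arange(5.0), np.ones(5))


class TestEffectLabelsAndReport:
    @pytest.mark.parametrize("r,label", [
        (-0.32, "medium"), (0.10, "small"), (0.0, "below_small"),
        (0.50, "large"), (-0.09, "below_small"), (0.30, "medium"),
    ])
    def test_label_thresholds(self, r, label):
        assert label_effect(r) == label

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(EstimationError):
            label_effect(1.5)

    def test_report_has_one_row_per_level(self, identity_panel):
        est = multilevel_corr(identity_panel, ("x", "y"))
        report = correlation_report([est])
        assert set(report["level"]) == {"within", "between"}
        assert len(report) == 2
        assert (report["effect"] == "large").all()

    def test_biserial_rows_distinguished_and_between_only(self):
        rng = np.random.default_rng(1)
        est = biserial_corr(rng.normal(size=100),
                            rng.integers(0, 2, size=100))
        report = correlation_report([est])
        assert len(report) == 1
        assert report["type"].iloc[0] == "biserial"
        assert report["level"].iloc[0] == "between"

    def test_empty_input_gives_header_only(self):
        report = correlation_report([])
        assert len(report) == 0
        assert "r" in report.columns
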