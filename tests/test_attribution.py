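"""Counterfactual, fire-day selection, labelling and transition prediction."""

import numpy as np
import pandas as pd
import pytest

import smokeburden as sb
from smokeburden.attribution import (
    SeasonScheme,
    classify_days,
    compute_counterfactual,
    identify_fire_days,
    label_seasonal,
    predict_transition_sources,
    summarize_day_types,
    train_transition_classifier,
)

SUMMER = frozenset({11, 12, 1, 2})


def series(values, start="2015-01-01", area="A0"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({"area_id": area, "date": dates, "pm25": values})


class TestFireDays:
    def test_constant_series_has_no_fire_days(self):
        s = series([2.0] * 60, start="2014-12-01")
        assert identify_fire_days(s) == set()

    def test_extreme_summer_outlier_selected(self):
        values = [1.0] * 100
        values[30] = 100.0  # 2015-01-31, a summer day
        s = series(values)
        assert identify_fire_days(s) == {pd.Timestamp("2015-01-31")}

    def test_matches_brute_force_percentile(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0.5, 20, 40).round(3)
        s = series(values, start="2014-12-15")
        pct = 90.0
        # brute-force linear-interpolation percentile: sort, index h=(n-1)q
        v = np.sort(values)
        h = (len(v) - 1) * pct / 100.0
        lo = int(np.floor(h))
        threshold = v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])
        dates = pd.to_datetime(s["date"])
        expected = set(
            dates[(dates.dt.month.isin(list(SUMMER))) & (s["pm25"] > threshold)]
        )
        assert identify_fire_days(s, percentile=pct) == expected

    def test_insufficient_history_raises(self):
        with pytest.raises(ValueError, match="A0"):
            identify_fire_days(series([1.0] * 10))

    def test_raising_percentile_is_monotone(self, small_area_days):
        one_area = small_area_days[small_area_days["area_id"] == "A000"]
        counts = [
            len(identify_fire_days(one_area, percentile=p)) for p in (75, 90, 95, 99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCounterfactual:
    def test_constant_summer(self):
        s = series([1.4] * 90, start="2014-11-15")
        assert compute_counterfactual(s, set()) == pytest.approx(1.4)

    def test_fire_day_excluded(self):
        s = series([2.0, 2.0, 2.0, 200.0], start="2015-01-01")
        fire = {pd.Timestamp("2015-01-04")}
        assert compute_counterfactual(s, fire) == pytest.approx(2.0)

    def test_no_qualifying_days_raises(self):
        s = series([5.0] * 30, start="2015-06-01")  # winter only
        with pytest.raises(ValueError, match="summer"):
            compute_counterfactual(s, set())

    def test_never_exceeds_summer_maximum(self, small_area_days):
        table = sb.counterfactual_table(small_area_days.dropna(subset=["pm25"]))
        months = pd.to_datetime(small_area_days["date"]).dt.month
        summer_max = (
            small_area_days[months.isin(list(SUMMER))].groupby("area_id")["pm25"].max()
        )
        for _, row in table.iterrows():
            assert row["counterfactual"] <= summer_max[row["area_id"]]


class TestAttributePM:
    def test_equal_is_unpolluted(self):
        assert sb.attribute_pm(1.4, 1.4) == (False, 0.0)

    def test_excess_is_attributable(self):
        polluted, attr = sb.attribute_pm(7.7, 1.4)
        assert polluted and attr == pytest.approx(6.3)

    def test_below_counterfactual_clamped(self):
        assert sb.attribute_pm(0.5, 1.4) == (False, 0.0)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            sb.attribute_pm(float("nan"), 1.4)


class TestSeasonalLabels:
    def make(self, date, attributable):
        return pd.DataFrame(
            {"area_id": ["A0"], "date": [pd.Timestamp(date)],
             "pm25_attributable": [attributable]}
        )

    @pytest.mark.parametrize(
        "date,attr,expected,origin",
        [
            ("2015-06-10", 5.0, "WHS", "rule_season"),
            ("2015-01-10", 5.0, "LFS", "rule_season"),
            ("2015-04-10", 5.0, None, "predicted"),
            ("2015-04-10", 0.0, "unpolluted", "rule_unpolluted"),
        ],
    )
    def test_rules(self, date, attr, expected, origin):
        out = label_seasonal(self.make(date, attr), SeasonScheme())
        assert out.loc[0, "label_origin"] == origin
        if expected is None:
            assert pd.isna(out.loc[0, "day_type"])
        else:
            assert out.loc[0, "day_type"] == expected

    def test_scheme_overlap_rejected(self):
        with pytest.raises(ValueError):
            SeasonScheme(winter_months=frozenset({5, 6}), summer_months=frozenset({6, 7}))

    def test_transition_months_complete_the_year(self):
        scheme = SeasonScheme(frozenset({5, 6, 7}), frozenset({11, 12, 1, 2}))
        assert scheme.transition_months == frozenset({3, 4, 8, 9, 10})


class TestClassifier:
    def test_holdout_accuracy_on_separated_regimes(self, small_result):
        assert small_result.holdout_accuracy >= 0.9

    def test_permuted_labels_break_the_signal(self, small_result):
        labeled = small_result.classified
        labeled = labeled[labeled["label_origin"] == "rule_season"]
        labeled = labeled[labeled["day_type"].isin(["WHS", "LFS"])]
        # balance classes so chance level is 0.5, then destroy the signal
        n = labeled["day_type"].value_counts().min()
        balanced = pd.concat(
            [g.sample(n, random_state=0) for _, g in labeled.groupby("day_type")]
        )
        rng = np.random.default_rng(0)
        balanced["day_type"] = rng.permutation(balanced["day_type"].to_numpy())
        _, accuracy = train_transition_classifier(balanced, seed=0, n_estimators=100)
        assert abs(accuracy - 0.5) < 0.15

    def test_single_class_training_rejected(self, small_result):
        labeled = small_result.classified
        whs_only = labeled[labeled["day_type"] == "WHS"]
        with pytest.raises(ValueError, match="both WHS and LFS"):
            train_transition_classifier(whs_only, seed=0, n_estimators=10)

    def test_no_transition_days_yields_empty_prediction(self, small_result):
        labeled = small_result.classified
        labeled = labeled[labeled["day_type"].isin(["WHS", "LFS"])]
        model, _ = train_transition_classifier(labeled, seed=0, n_estimators=10)
        empty = labeled.iloc[0:0]
        assert len(predict_transition_sources(model, empty)) == 0

    def test_predictions_agree_with_truth_on_clear_days(self, truth_merged):
        months = truth_merged["date"].dt.month
        trans = truth_merged[
            months.isin([3, 4, 9, 10])
            & truth_merged["day_type"].isin(["WHS", "LFS"])
            & (truth_merged["day_type_true"] != "unpolluted")
        ]
        # cold high-HDD transition days generated as WHS, warm spikes as LFS
        clear_whs = trans[(trans["hdd"] > 10) & (trans["day_type_true"] == "WHS")]
        clear_lfs = trans[
            (trans["hdd"] < 4)
            & (trans["day_type_true"] == "LFS")
            & (trans["pm25_attributable_true"] > 20)
        ]
        assert len(clear_whs) and (clear_whs["day_type"] == "WHS").mean() > 0.9
        assert len(clear_lfs) and (clear_lfs["day_type"] == "LFS").mean() > 0.9

    def test_rule_labels_never_predicted(self, small_result):
        cl = small_result.classified
        months = pd.to_datetime(cl["date"]).dt.month
        assert (cl.loc[~months.isin([3, 4, 9, 10]), "label_origin"] != "predicted").all()
        polluted_transition = months.isin([3, 4, 9, 10]) & (cl["pm25_attributable"] > 0)
        assert (cl.loc[polluted_transition, "label_origin"] == "predicted").all()


class TestClassification:
    def test_day_types_partition_valid_days(self, small_result):
        cl = small_result.classified
        assert set(cl["day_type"].unique()) <= {"unpolluted", "WHS", "LFS"}
        assert cl["day_type"].notna().all()
        unpolluted = cl["day_type"] == "unpolluted"
        assert (cl.loc[unpolluted, "pm25_attributable"] == 0.0).all()
        assert (cl.loc[~unpolluted, "pm25_attributable"] > 0.0).all()
        assert (cl["pm25_attributable"] >= 0).all()

    def test_attributable_pm_recovers_truth(self, truth_merged):
        err = (
            truth_merged["pm25_attributable"] - truth_merged["pm25_attributable_true"]
        ).abs()
        assert err.mean() < 1.0

    def test_summary_shares_sum_to_100(self, small_result):
        assert small_result.day_type_summary["share_pct"].sum() == pytest.approx(100.0)

    def test_summary_shares_match_truth(self, truth_merged):
        """Day-type shares agree with truth for materially polluted days.

        The polluted/unpolluted boundary sits at the noise scale (a day a
        few hundredths of a ug/m3 above the counterfactual counts as
        polluted), so shares are compared above a materiality threshold
        well clear of daily noise yet below any injected smoke signal.
        """
        eps = 0.5  # ug/m3
        est = np.where(
            truth_merged["pm25_attributable"] > eps, truth_merged["day_type"], "unpolluted"
        )
        true = np.where(
            truth_merged["pm25_attributable_true"] > eps,
            truth_merged["day_type_true"],
            "unpolluted",
        )
        est_shares = pd.Series(est).value_counts(normalize=True) * 100
        true_shares = pd.Series(true).value_counts(normalize=True) * 100
        for day_type in ("unpolluted", "WHS", "LFS"):
            assert abs(est_shares[day_type] - true_shares[day_type]) < 5.0

    def test_all_unpolluted_world_summarised(self):
        cfg = sb.GeneratorConfig(
            n_areas=2, n_pm_stations=2, n_met_stations=2,
            start="2015-01-01", end="2015-12-31",
            whs_winter_amplitude=0.0, lfs_event_rate=0.0, noise_sd=0.0, seed=5,
        )
        world = sb.generate_world(cfg)
        area_days = sb.area_days_from_world(world)
        classified = classify_days(area_days, seed=5)
        summary = summarize_day_types(classified)
        assert summary.loc[summary["day_type"] == "unpolluted", "share_pct"].iloc[
            0
        ] == pytest.approx(100.0)
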