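import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trunkgait.group_stats import (
    build_longitudinal_report,
    build_t0_report,
    chi_square_2x2,
    dunn_holm,
    holm_adjust,
    kruskal_wallis_eta,
    mann_whitney,
    rank_repeated_measures,
)

SEPARATED = (np.array([1, 2, 3, 4, 5, 6, 7, 8, 9.0]),
             np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3))


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p, eta2 = kruskal_wallis_eta(*SEPARATED)
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(0.0273, abs=0.001)
        assert eta2 == pytest.approx((7.2 - 2) / 6)

    def test_identical_groups(self):
        values = np.array([1.0, 2, 3] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        h, _, eta2 = kruskal_wallis_eta(values, np.sort(groups))
        # three identical groups (each {1,2,3}) -> H = 0 after tie correction
        values = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3])
        h, _, eta2 = kruskal_wallis_eta(values, np.repeat(["a", "b", "c"], 3))
        assert h == pytest.approx(0.0, abs=1e-12)
        assert eta2 == 0.0

    def test_monotone_transform_invariance(self):
        values, groups = SEPARATED
        h1, _, _ = kruskal_wallis_eta(values, groups)
        h2, _, _ = kruskal_wallis_eta(np.exp(values), groups)
        assert h1 == pytest.approx(h2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_eta(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))


class TestDunnHolm:
    def test_frozen_oracle_values(self):
        # hand computation: mean ranks 2/5/8, SE = sqrt(7.5 * 2/3)
        df = dunn_holm(*SEPARATED).set_index(["group_a", "group_b"])
        assert df.loc[("a", "b"), "z"] == pytest.approx(-1.341641, abs=1e-5)
        assert df.loc[("a", "c"), "z"] == pytest.approx(-2.683282, abs=1e-5)
        assert df.loc[("a", "c"), "p_raw"] == pytest.approx(0.007290, abs=1e-5)
        assert df.loc[("a", "c"), "p_holm"] == pytest.approx(3 * 0.007290, abs=1e-4)
        assert df.loc[("a", "b"), "p_holm"] == pytest.approx(0.359424, abs=1e-4)

    def test_identical_groups_all_one(self):
        values = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3])
        groups = np.repeat(["a", "b", "c"], 3)
        df = dunn_holm(values, groups)
        assert np.allclose(df["p_holm"], 1.0)

    def test_holm_smallest_is_three_times_min_raw(self):
        df = dunn_holm(*SEPARATED)
        assert df["p_holm"].min() == pytest.approx(min(3 * df["p_raw"].min(), 1.0))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_holm_monotone_and_dominates_raw(self, pvals):
        raw = np.asarray(pvals)
        adj = holm_adjust(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestChiSquare:
    def test_sex_table(self):
        chi2, p = chi_square_2x2([[12, 20], [6, 8]])
        assert p == pytest.approx(0.73, abs=0.005)

    def test_dysphagia_table(self):
        chi2, p = chi_square_2x2([[3, 29], [6, 8]])
        assert p == pytest.approx(0.01, abs=0.005)

    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[5, 5], [5, 5]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_equals_squared_two_proportion_z(self):
        a, b, c, d = 13.0, 19, 7, 9
        chi2, _ = chi_square_2x2([[a, b], [c, d]])
        p1, p2 = a / (a + b), c / (c + d)
        pp = (a + c) / (a + b + c + d)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / (a + b) + 1 / (c + d)))
        assert chi2 == pytest.approx(z ** 2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_exact_enumeration(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_u_identity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(size=15)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _longitudinal_frame(rng, n_ic=12, n_sii=8, time_shift=0.0, group_shift=0.0,
                        interaction=0.0):
    rows = []
    for i in range(n_ic + n_sii):
        g = "IC" if i < n_ic else "SII"
        base = rng.normal() + (group_shift if g == "SII" else 0.0)
        for tp, ts in (("T0", 0.0), ("T1", time_shift)):
            val = base + ts + rng.normal(scale=0.5)
            if g == "SII" and tp == "T1":
                val += interaction
            rows.append({"subject_id": f"s{i}", "group": g, "timepoint": tp, "value": val})
    return pd.DataFrame(rows)


class TestRankRepeatedMeasures:
    def test_constant_time_shift_detected(self):
        rng = np.random.default_rng(0)
        df = _longitudinal_frame(rng, time_shift=2.0)
        res = rank_repeated_measures(df)
        assert res.time["p"] < 0.01

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        df = _longitudinal_frame(rng, group_shift=1.0)
        res1 = rank_repeated_measures(df)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"IC": "SII", "SII": "IC"})
        res2 = rank_repeated_measures(swapped)
        assert res1.group["statistic"] == pytest.approx(res2.group["statistic"], rel=1e-9)
        assert res1.interaction["p"] == pytest.approx(res2.interaction["p"], rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        df = _longitudinal_frame(rng, time_shift=1.0)
        res1 = rank_repeated_measures(df)
        df2 = df.assign(value=np.exp(df["value"]))
        res2 = rank_repeated_measures(df2)
        for eff in ("time", "group", "interaction"):
            assert getattr(res1, eff)["statistic"] == pytest.approx(
                getattr(res2, eff)["statistic"], rel=1e-9)

    def test_missing_timepoint_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        df = _longitudinal_frame(rng)
        df = df[~((df["subject_id"] == "s0") & (df["timepoint"] == "T1"))]
        res = rank_repeated_measures(df)
        assert "dropping" in caplog.text
        assert res.n_subjects["IC"] == 11

    def test_relative_effects_shape(self):
        rng = np.random.default_rng(4)
        res = rank_repeated_measures(_longitudinal_frame(rng))
        assert len(res.relative_effects) == 4
        assert res.relative_effects["relative_effect"].between(0, 1).all()

    def test_interaction_detected_when_present(self):
        rng = np.random.default_rng(5)
        df = _longitudinal_frame(rng, n_ic=30, n_sii=30, interaction=2.5)
        res = rank_repeated_measures(df)
        assert res.interaction["p"] < 0.01
        assert res.posthoc_gated


class TestReports:
    def _indexes(self, rng, n=10):
        rows = []
        for g, shift in (("HS", 0.0), ("IC", 0.6), ("SII", 1.2)):
            for i in range(n):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "hr_ml": rng.normal(1.8 - shift * 0.3, 0.1),
                             "gait_speed": rng.normal(0.75, 0.1)})
        return pd.DataFrame(rows)

    def test_t0_report_rows_and_columns(self):
        rng = np.random.default_rng(0)
        report = build_t0_report(self._indexes(rng), index_cols=("hr_ml", "gait_speed"))
        assert list(report["index"]) == ["hr_ml", "gait_speed"]
        assert {"mean_HS", "sd_SII", "H", "p", "eta2"} <= set(report.columns)
        row = report.set_index("index").loc["hr_ml"]
        assert row["p"] < 0.01
        assert row["mean_HS"] > row["mean_IC"] > row["mean_SII"]

    def test_missing_column_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError):
            build_t0_report(self._indexes(rng), index_cols=("nope",))

    def test_single_group_gives_na(self, caplog):
        rng = np.random.default_rng(0)
        df = self._indexes(rng)
        report = build_t0_report(df[df["group"] == "HS"], index_cols=("hr_ml",))
        assert np.isnan(report.loc[0, "H"])

    def test_longitudinal_report(self):
        rng = np.random.default_rng(6)
        df = _longitudinal_frame(rng, time_shift=1.5).rename(columns={"value": "hr_ml"})
        report = build_longitudinal_report(df, index_cols=("hr_ml",))
        assert report.loc[0, "time_p"] < 0.01
        assert set(report.columns) >= {"time_p", "group_p", "interaction_p", "posthoc_gated"}
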