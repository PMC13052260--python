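"""Per-sample feature tables, group contrasts, onset and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoscore as cs
from cytoscore.events import EventMatrix


def em(values, sample_id, markers=("A", "B")):
    return EventMatrix(
        values=np.asarray(values, dtype=float),
        markers=list(markers),
        sample_id=sample_id,
        transform_state="arcsinh",
    )


@pytest.fixture
def toy_table():
    m1 = em(np.arange(20).reshape(10, 2), "s1")
    m2 = em(np.ones((5, 2)), "s2")
    labels = {
        "s1": np.array([0] * 4 + [1] * 6),
        "s2": np.array([1] * 5),
    }
    meta = pd.DataFrame(
        {"sample_id": ["s1", "s2"], "group": ["non_irAE", "irAE"]}
    )
    return cs.sample_features([m1, m2], labels, meta)


class TestSampleFeatures:
    def test_frequency_arithmetic(self, toy_table):
        row = toy_table.set_index("sample_id").loc["s1"]
        assert row["freq.C01"] == pytest.approx(40.0)
        assert row["freq.C02"] == pytest.approx(60.0)

    def test_frequencies_sum_to_100(self, toy_table):
        freq_cols = [c for c in toy_table.columns if c.startswith("freq.")]
        sums = toy_table[freq_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)
        assert (toy_table[freq_cols] >= 0).all().all()

    def test_absent_cluster_zero_frequency_missing_expression(self, toy_table):
        row = toy_table.set_index("sample_id").loc["s2"]
        assert row["freq.C01"] == 0.0
        assert np.isnan(row["expr.C01.A"])

    def test_single_cluster_sample_expression_equals_holistic(self, toy_table):
        row = toy_table.set_index("sample_id").loc["s2"]
        assert row["expr.C02.A"] == row["holistic.A"]

    def test_plasma_joined_with_namespace(self):
        m = em(np.ones((4, 2)), "s1")
        plasma = pd.DataFrame(
            {"CXCL9": [123.0]}, index=pd.Index(["s1"], name="sample_id")
        )
        table = cs.sample_features(
            [m], {"s1": np.zeros(4, dtype=int)},
            pd.DataFrame({"sample_id": ["s1"], "group": ["g"]}), plasma=plasma,
        )
        assert table.loc[0, "plasma.CXCL9"] == 123.0

    def test_misaligned_labels_rejected(self):
        m = em(np.ones((4, 2)), "s1")
        with pytest.raises(ValueError, match="cover"):
            cs.sample_features(
                [m], {"s1": np.zeros(3, dtype=int)},
                pd.DataFrame({"sample_id": ["s1"]}),
            )


class TestGroupCompare:
    def table(self, x, y):
        return pd.DataFrame(
            {
                "holistic.A": np.r_[x, y],
                "group": ["ref"] * len(x) + ["case"] * len(y),
            }
        )

    def test_identical_groups_give_t0_p1(self):
        vals = [1.0, 2.0, 3.0]
        res = cs.group_compare(
            self.table(vals, vals), "group", ("ref", "case")
        )
        assert res.loc["holistic.A", "t"] == pytest.approx(0.0)
        assert res.loc["holistic.A", "p"] == pytest.approx(1.0)

    def test_matches_scipy_students_t(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        res = cs.group_compare(self.table(x, y), "group", ("ref", "case"))
        t_ref, p_ref = stats.ttest_ind(y, x, equal_var=True)
        assert res.loc["holistic.A", "t"] == pytest.approx(t_ref)
        assert res.loc["holistic.A", "p"] == pytest.approx(p_ref)
        assert res.loc["holistic.A", "df"] == 15
        expected_dir = "increased" if y.mean() > x.mean() else "decreased"
        assert res.loc["holistic.A", "direction"] == expected_dir

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(40):
            x = rng.normal(0, 1, 10)
            y = rng.normal(-3, 1, 10)  # 3-sd decrease in the case group
            res = cs.group_compare(self.table(x, y), "group", ("ref", "case"))
            hits += (
                res.loc["holistic.A", "p"] < 0.05
                and res.loc["holistic.A", "direction"] == "decreased"
            )
        assert hits >= 39

    def test_constant_feature_skipped_with_warning(self):
        df = self.table([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="skipped"):
            res = cs.group_compare(df, "group", ("ref", "case"))
        assert len(res) == 0

    def test_label_permutation_null_calibrated(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=24)
        rejections = 0
        rounds = 200
        for _ in range(rounds):
            groups = rng.permutation(["ref"] * 12 + ["case"] * 12)
            df = pd.DataFrame({"holistic.A": values, "group": groups})
            res = cs.group_compare(df, "group", ("ref", "case"))
            rejections += res.loc["holistic.A", "p"] < 0.05
        assert 0.01 <= rejections / rounds <= 0.10

    def test_missing_values_excluded_pairwise(self):
        df = self.table([1.0, 2.0, np.nan, 3.0], [4.0, 5.0, 6.0])
        res = cs.group_compare(df, "group", ("ref", "case"))
        assert res.loc["holistic.A", "df"] == 3 + 3 - 2


class TestOnset:
    @pytest.mark.parametrize(
        "day, expected",
        [(52, "early"), (90, "early"), (91, "late"), (0, "early"), (400, "late")],
    )
    def test_boundary_classification(self, day, expected):
        assert cs.classify_onset(day) == expected

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            cs.classify_onset(-1)

    def test_no_irae_is_not_applicable(self):
        assert cs.classify_onset(None) == "not_applicable"
        assert cs.classify_onset(float("nan")) == "not_applicable"


class TestCohortSummary:
    def test_printed_cohort_fractions(self):
        summary = cs.cohort_summary(cs.discovery_cohort_metadata())
        assert summary["early_onset_pct"] == 40.0
        assert summary["late_onset_pct"] == 60.0
        assert summary["grade3plus_in_early_pct"] == 50.0
        assert summary["by_type"]["cutaneous"]["early_pct"] == 25.0

    def test_scale_invariance(self):
        meta = cs.discovery_cohort_metadata()
        doubled = pd.concat([meta, meta], ignore_index=True)
        a, b = cs.cohort_summary(meta), cs.cohort_summary(doubled)
        for key in ("early_onset_pct", "late_onset_pct",
                    "grade3plus_in_early_pct", "grade3plus_in_late_pct"):
            assert a[key] == b[key]

    def test_empty_stratum_reported_as_none(self):
        meta = pd.DataFrame(
            {"grade": [2], "onset_day": [30.0], "irae_type": ["pneumonia"]}
        )
        summary = cs.cohort_summary(meta)
        assert summary["grade3plus_in_late_pct"] is None
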