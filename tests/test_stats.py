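import math

import numpy as np
import pandas as pd
import pytest

from mammometry.errors import (
    DegenerateDataError,
    IncompleteDesignError,
    InvalidParameterError,
    MissingReferenceError,
)
from mammometry.stats import (
    RepeatedMeasuresTable,
    accuracy_summary,
    bland_altman,
    classify_icc,
    cv_percent,
    effectiveness,
    icc,
    icc_variance,
    sem,
    summary_tables,
)

# Inter-observer ICC and CV columns of the published validation tables,
# reused as fixed regression inputs for variance/mean checks.
FEMALE_INTER_ICCS = [0.968, 0.968, 0.924, 0.989, 0.986, 0.909, 0.953,
                     0.858, 0.810, 0.898, 0.944, 0.987, 0.952]
MALE_INTER_ICCS = [0.943, 0.996, 0.998, 0.996, 0.997, 0.957, 0.992,
                   0.995, 0.998, 0.995, 0.967, 0.998, 0.999]


def make_table(values, reference=None):
    rows = []
    for (subject, observer, session, meas), v in values.items():
        rows.append(
            {"subject_id": subject, "observer_id": observer, "session": session,
             "measurement": meas, "value_cm": v}
        )
    ref = None
    if reference is not None:
        ref = pd.DataFrame(
            [{"subject_id": s, "measurement": m, "reference_cm": v}
             for (s, m), v in reference.items()]
        )
    return RepeatedMeasuresTable(pd.DataFrame(rows), ref)


class TestRepeatedMeasuresTable:
    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame(
            [{"subject_id": "a", "observer_id": "o", "session": 1, "measurement": "NLD",
              "value_cm": 1.0}] * 2
        )
        with pytest.raises(InvalidParameterError):
            RepeatedMeasuresTable(df)

    def test_nonfinite_rejected(self):
        df = pd.DataFrame(
            [{"subject_id": "a", "observer_id": "o", "session": 1, "measurement": "NLD",
              "value_cm": float("nan")}]
        )
        with pytest.raises(InvalidParameterError):
            RepeatedMeasuresTable(df)

    def test_csv_round_trip(self, tmp_path):
        table = make_table(
            {("s1", "o1", 1, "NLD"): 1.0, ("s1", "o1", 2, "NLD"): 1.1,
             ("s2", "o1", 1, "NLD"): 2.0, ("s2", "o1", 2, "NLD"): 2.2},
            reference={("s1", "NLD"): 1.05, ("s2", "NLD"): 2.1},
        )
        path = tmp_path / "study.csv"
        table.to_csv(path)
        back = RepeatedMeasuresTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data)
        pd.testing.assert_frame_equal(
            back.reference.reset_index(drop=True), table.reference
        )


class TestAccuracy:
    def test_perfect_agreement(self):
        table = make_table(
            {("s1", "o", 1, "NLD"): 1.0, ("s2", "o", 1, "NLD"): 2.0},
            reference={("s1", "NLD"): 1.0, ("s2", "NLD"): 2.0},
        )
        out = accuracy_summary(table)
        assert out["mad_cm"].iloc[0] == pytest.approx(0.0)
        assert out["sd_cm"].iloc[0] == pytest.approx(0.0)

    def test_plus_minus_one(self):
        table = make_table(
            {("s1", "o", 1, "NLD"): 2.0, ("s2", "o", 1, "NLD"): 1.0},
            reference={("s1", "NLD"): 1.0, ("s2", "NLD"): 2.0},
        )
        out = accuracy_summary(table)
        assert out["mad_cm"].iloc[0] == pytest.approx(1.0)  # |{+1,-1}| mean
        # signed differences {+1,-1}: mean 0, sample SD sqrt(2)
        assert out["sd_cm"].iloc[0] == pytest.approx(math.sqrt(2.0))

    def test_brute_force_oracle(self, rng):
        values, reference = {}, {}
        for s in range(6):
            for m in ("NLD", "SNN_R"):
                reference[(f"s{s}", m)] = float(rng.uniform(1, 20))
                for o in ("A", "B"):
                    for sess in (1, 2, 3):
                        values[(f"s{s}", o, sess, m)] = float(rng.uniform(1, 20))
        out = accuracy_summary(make_table(values, reference)).set_index(
            ["measurement", "observer_id"]
        )
        for m in ("NLD", "SNN_R"):
            for o in ("A", "B"):
                diffs = [
                    values[(f"s{s}", o, sess, m)] - reference[(f"s{s}", m)]
                    for s in range(6) for sess in (1, 2, 3)
                ]
                assert out.loc[(m, o), "mad_cm"] == pytest.approx(np.mean(np.abs(diffs)))
                assert out.loc[(m, o), "sd_cm"] == pytest.approx(np.std(diffs, ddof=1))

    def test_absolute_sd_option(self):
        table = make_table(
            {("s1", "o", 1, "NLD"): 2.0, ("s2", "o", 1, "NLD"): 1.0},
            reference={("s1", "NLD"): 1.0, ("s2", "NLD"): 2.0},
        )
        out = accuracy_summary(table, sd_of="absolute")
        assert out["sd_cm"].iloc[0] == pytest.approx(0.0)  # |d| constant at 1

    def test_missing_reference_named(self):
        table = make_table(
            {("s1", "o", 1, "NLD"): 1.0, ("s2", "o", 1, "NLD"): 2.0},
            reference={("s1", "NLD"): 1.0},
        )
        with pytest.raises(MissingReferenceError, match="s2"):
            accuracy_summary(table)


class TestIcc:
    def test_identical_raters_unit_icc(self):
        y = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        r = icc(y)
        assert r.icc == pytest.approx(1.0)
        assert r.ci_high == pytest.approx(1.0)

    def test_hand_computed_mean_squares(self):
        # independent brute-force two-way ANOVA on a small fixed matrix
        y = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0], [7.0, 1.0, 2.0]])
        n, k = y.shape
        grand = y.mean()
        msr = k * sum((row.mean() - grand) ** 2 for row in y) / (n - 1)
        msc = n * sum((col.mean() - grand) ** 2 for col in y.T) / (k - 1)
        sse = sum(
            (y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
            for i in range(n) for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected_icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        expected_icc31 = (msr - mse) / (msr + (k - 1) * mse)
        assert icc(y, "two-way-random-absolute").icc == pytest.approx(expected_icc21, rel=1e-12)
        assert icc(y, "two-way-mixed-consistency").icc == pytest.approx(expected_icc31, rel=1e-12)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(0, 3, (15, 1)) + rng.normal(0, 1, (15, 4)) + rng.normal(0, 0.5, 4)
        df = (
            pd.DataFrame(y, columns=list("abcd"))
            .reset_index()
            .melt("index", var_name="rater", value_name="v")
        )
        ref = pg.intraclass_corr(df, targets="index", raters="rater", ratings="v").set_index("Type")
        mine = icc(y, "two-way-random-absolute")
        assert mine.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], rel=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert mine.ci_low == pytest.approx(lo, abs=5e-3)
        assert mine.ci_high == pytest.approx(hi, abs=5e-3)
        mine3 = icc(y, "two-way-mixed-consistency")
        assert mine3.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], rel=1e-9)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 3, (200, 1)) + rng.normal(0, 1, (200, 3))
        r = icc(y)
        assert r.ci_low < 0.9 < r.ci_high
        assert r.icc == pytest.approx(0.9, abs=0.05)

    def test_ci_brackets_estimate(self, rng):
        y = rng.normal(0, 2, (10, 1)) + rng.normal(0, 1, (10, 3))
        r = icc(y)
        assert r.ci_low <= r.icc <= r.ci_high
        assert -1 < r.icc <= 1

    def test_shift_and_scale_invariance(self, rng):
        y = rng.normal(0, 2, (12, 1)) + rng.normal(0, 1, (12, 3))
        base = icc(y).icc
        assert icc(y + 100.0).icc == pytest.approx(base, rel=1e-9)
        assert icc(y * 7.0).icc == pytest.approx(base, rel=1e-9)

    def test_errors(self):
        with pytest.raises(IncompleteDesignError):
            icc(np.array([[1.0, 2.0]]))  # one subject
        with pytest.raises(IncompleteDesignError):
            icc(np.array([[1.0], [2.0]]))  # one rater
        with pytest.raises(IncompleteDesignError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(DegenerateDataError):
            icc(np.full((4, 3), 2.5))
        with pytest.raises(InvalidParameterError):
            icc(np.ones((3, 3)), model="one-way")


class TestSem:
    # printed (SD, ICC) -> SEM pairs from the published female validation table
    @pytest.mark.parametrize(
        "sd,icc_value,expected", [(0.29, 0.944, 0.07), (1.25, 0.843, 0.50)]
    )
    def test_published_rows(self, sd, icc_value, expected):
        assert round(sem(sd, icc_value), 2) == pytest.approx(expected)

    def test_perfect_icc_gives_zero(self):
        for sd in (0.0, 0.5, 3.7):
            assert sem(sd, 1.0) == 0.0

    def test_icc_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            sem(1.0, 1.01)

    def test_negative_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            sem(-0.1, 0.5)

    def test_sem_bounded_by_sd(self, rng):
        for _ in range(100):
            sd = float(rng.uniform(0, 3))
            i = float(rng.uniform(0, 1))
            s = sem(sd, i)
            assert 0 <= s <= sd + 1e-12
            if sd > 0:
                assert (s == 0) == (i == 1)


class TestCv:
    def test_constant_values(self):
        assert cv_percent(np.array([[10.0, 10.0, 10.0], [4.0, 4.0, 4.0]])) == pytest.approx(0.0)

    def test_single_subject(self):
        assert cv_percent(np.array([[9.0, 10.0, 11.0]])) == pytest.approx(10.0)

    def test_brute_force_oracle(self, rng):
        y = rng.uniform(5, 30, size=(8, 6))
        expected = np.mean(
            [100 * np.std(row, ddof=1) / np.mean(row) for row in y]
        )
        assert cv_percent(y) == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateDataError, match="subject index 1"):
            cv_percent(np.array([[1.0, 2.0], [1.0, -1.0]]))

    def test_pooled_method(self, rng):
        y = rng.uniform(5, 30, size=(8, 6))
        pooled = cv_percent(y, method="pooled")
        expected = 100 * math.sqrt(np.mean(np.std(y, axis=1, ddof=1) ** 2)) / y.mean(axis=1).mean()
        assert pooled == pytest.approx(expected, rel=1e-12)


class TestBlandAltman:
    def test_constant_offset(self):
        ref = np.array([1.0, 2.0, 3.0])
        res = bland_altman(ref, ref + 0.4)
        assert res.bias == pytest.approx(0.4)
        assert res.loa_low == pytest.approx(res.loa_high) == pytest.approx(0.4)

    def test_sign_flip_antisymmetry(self, rng):
        ref = rng.uniform(0, 10, 50)
        dig = ref + rng.normal(0, 1, 50)
        a = bland_altman(ref, dig)
        b = bland_altman(dig, ref)
        assert b.bias == pytest.approx(-a.bias)
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)

    def test_normal_limits(self):
        rng = np.random.default_rng(17)
        ref = np.zeros(100_000)
        dig = rng.normal(0, 1, 100_000)
        res = bland_altman(ref, dig)
        assert res.loa_low == pytest.approx(-1.96, abs=0.02)
        assert res.loa_high == pytest.approx(1.96, abs=0.02)

    def test_too_few_pairs(self):
        with pytest.raises(InvalidParameterError):
            bland_altman([1.0], [1.0])

    def test_invariant_ordering(self, rng):
        res = bland_altman(rng.uniform(0, 5, 20), rng.uniform(0, 5, 20))
        assert res.loa_low <= res.bias <= res.loa_high


class TestEffectiveness:
    def test_half(self):
        assert effectiveness([0.5, 1.5]) == pytest.approx(50.0)

    def test_all_below(self):
        assert effectiveness([0.1, 0.2, 0.9]) == pytest.approx(100.0)

    def test_threshold_is_strict(self):
        assert effectiveness([1.0]) == pytest.approx(0.0)

    def test_brute_force_oracle(self, rng):
        mads = rng.uniform(0, 2, 37)
        expected = 100 * sum(1 for m in mads if m < 1.0) / len(mads)
        assert effectiveness(mads) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            effectiveness([])


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.50, ("fair", "poor-to-moderate")),
            (0.90, ("excellent", "clinical")),
            (0.75, ("excellent", "good")),
            (0.87, ("excellent", "good")),
            (0.871, ("excellent", "clinical")),
            (0.60, ("good", "poor-to-moderate")),
            (0.40, ("fair", "poor-to-moderate")),
            (0.39, ("poor", "poor-to-moderate")),
            (0.0, ("poor", "poor-to-moderate")),
            (-0.2, ("poor", "poor-to-moderate")),
            (1.0, ("excellent", "clinical")),
        ],
    )
    def test_bands(self, value, expected):
        assert classify_icc(value) == expected

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            classify_icc(1.2)


class TestIccVariance:
    def test_published_female_column(self):
        assert round(icc_variance(FEMALE_INTER_ICCS), 5) == pytest.approx(0.00290)

    def test_published_male_column(self):
        assert icc_variance(MALE_INTER_ICCS) == pytest.approx(0.0003465, abs=5e-8)

    def test_constant_list(self):
        assert icc_variance([0.9, 0.9, 0.9]) == 0.0

    def test_too_few(self):
        with pytest.raises(InvalidParameterError):
            icc_variance([0.9])


class TestSummaryTables:
    def test_zero_noise_study(self):
        from mammometry.synth import ObserverModel, batch_study

        table = batch_study(
            5, master_seed=0,
            observer_models=[ObserverModel(0.0, seed=1), ObserverModel(0.0, seed=2)],
        )
        summary = summary_tables(table)
        assert np.allclose(summary.per_observer["icc"], 1.0, atol=1e-9)
        assert np.allclose(summary.per_observer["mad_cm"], 0.0, atol=1e-9)
        assert np.allclose(summary.per_observer["sem_cm"], 0.0, atol=1e-9)
        assert np.allclose(summary.inter_rater["cv_percent"], 0.0, atol=1e-9)

    def test_row_counts_for_full_panel(self):
        from mammometry.synth import batch_study

        table = batch_study(4, master_seed=1)
        summary = summary_tables(table)
        assert len(summary.inter_rater) == 13
        assert len(summary.per_observer) == 13 * 2

    def test_noisy_icc_within_ci_of_truth(self):
        # direct variance-component simulation: sigma_b^2=9, sigma_e^2=1
        rng = np.random.default_rng(5)
        rows = []
        truth = 9 / (9 + 1)
        for s in range(120):
            base = rng.normal(10, 3)
            for o in ("A",):
                for sess in (1, 2, 3):
                    rows.append(
                        {"subject_id": f"s{s}", "observer_id": o, "session": sess,
                         "measurement": "SNN_R", "value_cm": base + rng.normal(0, 1)}
                    )
        table = RepeatedMeasuresTable(pd.DataFrame(rows))
        wide = table.pivot("SNN_R", observer="A")
        r = icc(wide)
        assert r.ci_low <= truth <= r.ci_high

    def test_rounding_convention(self):
        from mammometry.synth import batch_study

        summary = summary_tables(batch_study(4, master_seed=2)).rounded()
        icc_col = summary.inter_rater["icc"]
        assert (icc_col == icc_col.round(3)).all()
        cv_col = summary.inter_rater["cv_percent"]
        assert (cv_col == cv_col.round(1)).all()
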