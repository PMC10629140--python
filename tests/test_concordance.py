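import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sctradiomics as s
from sctradiomics.concordance import (
    LEVELS,
    LevelThresholds,
    ccc_table,
    classify_level,
    lin_ccc,
    mae_ccc_correlation,
    overlap_analysis,
    paired_ttest,
    records_to_frame,
    subset_report,
    summarize_levels,
)
from sctradiomics.errors import (
    DegenerateTestError,
    InsufficientPointsError,
    LookupError_,
)

from _oracles import ccc_brute


class TestLinCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_hand_value_eight_over_twentytwo(self):
        assert lin_ccc([1, 2, 3], [2, 4, 6]) == pytest.approx(8 / 22)

    def test_location_shift_penalized_unlike_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 5.0
        assert stats.pearsonr(x, y).statistic == pytest.approx(1.0)
        assert lin_ccc(x, y) < 1.0

    def test_matches_brute_force_on_random_draws(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert lin_ccc(x, y) == pytest.approx(ccc_brute(x, y))

    def test_symmetry_and_attenuation(self, rng):
        for _ in range(20):
            x = rng.normal(2, 1, 10)
            y = 0.5 * x + rng.normal(0, 1, 10)
            assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x))
            assert abs(lin_ccc(x, y)) <= abs(stats.pearsonr(x, y).statistic) + 1e-12

    def test_constant_inputs(self):
        assert lin_ccc([2, 2, 2], [2, 2, 2]) == 1.0
        assert lin_ccc([2, 2, 2], [3, 3, 3]) == 0.0
        with pytest.raises(ValueError):
            lin_ccc([1.0], [2.0])

    def test_analytic_recovery_half(self):
        """x ~ N(mu, s^2), y = x + N(0, 2 s^2) has population CCC = 0.5."""
        estimates = []
        for rep in range(50):
            x, y, pop = s.analytic_ccc_fixture(2000, 1.0, np.sqrt(2.0), seed=rep)
            assert pop == pytest.approx(0.5)
            estimates.append(lin_ccc(x, y))
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.03)


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "ccc,expected",
        [(0.90, "excellent"), (0.95, "excellent"), (0.75, "good"), (0.89, "good"),
         (0.50, "moderate"), (0.74, "moderate"), (0.49, "poor"), (-0.2, "poor")],
    )
    def test_boundaries_inclusive_upward(self, ccc, expected):
        assert classify_level(ccc) == expected

    def test_thresholds_must_decrease(self):
        with pytest.raises(ValueError):
            LevelThresholds(0.5, 0.75, 0.9)


def _toy_feature_frame(n_subjects=4, rois=("r1", "r2"), models=("mA", "mB"),
                       features=("f1", "f2", "f3"), jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    base = {f: rng.normal(0, 1, n_subjects) for f in features}
    for i in range(n_subjects):
        for roi in rois:
            rows.append({"subject_id": f"s{i}", "roi": roi, "image": "real",
                         **{f: base[f][i] for f in features}})
            for m in models:
                rows.append({"subject_id": f"s{i}", "roi": roi, "image": m,
                             **{f: base[f][i] + jitter * rng.normal() for f in features}})
    return pd.DataFrame(rows)


class TestCccTable:
    def test_cardinality(self):
        frame = _toy_feature_frame()
        records = ccc_table(frame)
        assert len(records) == 2 * 2 * 3  # roi x model x feature

    def test_identical_tables_all_excellent(self):
        records = ccc_table(_toy_feature_frame(jitter=0.0))
        assert all(r.ccc == pytest.approx(1.0) for r in records)
        assert all(r.level == "excellent" for r in records)

    def test_subject_permutation_invariance(self):
        frame = _toy_feature_frame(jitter=0.3)
        shuffled = frame.sample(frac=1.0, random_state=1)
        a = {(r.roi_name, r.model_name, r.feature_name): r.ccc for r in ccc_table(frame)}
        b = {(r.roi_name, r.model_name, r.feature_name): r.ccc for r in ccc_table(shuffled)}
        for key in a:
            assert a[key] == pytest.approx(b[key])


class TestSummaries:
    def _records(self, levels_seq):
        rows = []
        for i, lv in enumerate(levels_seq):
            rows.append({"roi": "r", "model": "m", "feature": f"f{i}",
                         "category": "texture", "ccc": 0.95, "level": lv,
                         "degenerate": False})
        return pd.DataFrame(rows)

    def test_equal_split(self):
        out = summarize_levels(self._records(LEVELS))
        row = out.iloc[0]
        for lv in LEVELS:
            assert row[f"pct_{lv}"] == pytest.approx(25.0)

    def test_hand_count_split(self):
        seq = ["excellent"] + ["good"] * 2 + ["moderate"] * 3 + ["poor"] * 4
        row = summarize_levels(self._records(seq)).iloc[0]
        assert [row[f"pct_{lv}"] for lv in LEVELS] == [10, 20, 30, 40]

    def test_percentages_sum_to_100(self, rng):
        seq = rng.choice(LEVELS, size=37).tolist()
        row = summarize_levels(self._records(seq)).iloc[0]
        assert sum(row[f"pct_{lv}"] for lv in LEVELS) == pytest.approx(100.0, abs=1e-9)


class TestOverlap:
    def _frame(self, names, level="excellent"):
        return pd.DataFrame(
            [{"roi": "r", "model": "m", "feature": n, "category": "texture",
              "ccc": 0.95, "level": level, "degenerate": False} for n in names]
        )

    def test_partial_overlap(self):
        out = overlap_analysis(self._frame(["f1", "f2"]), self._frame(["f2", "f3"]),
                               "excellent")
        row = out.iloc[0]
        assert row["intersection"] == 1
        assert row["jaccard"] == pytest.approx(1 / 3)
        assert row["frac_of_a"] == pytest.approx(0.5)

    def test_identical_sets(self):
        out = overlap_analysis(self._frame(["f1", "f2"]), self._frame(["f1", "f2"]),
                               "excellent")
        assert out.iloc[0]["jaccard"] == 1.0

    def test_disjoint_and_empty(self):
        out = overlap_analysis(self._frame(["f1"]), self._frame(["f2"]), "excellent")
        assert out.iloc[0]["jaccard"] == 0.0
        empty = overlap_analysis(self._frame([], level="good"), self._frame([], level="good"),
                                 "excellent")
        assert empty.empty or empty.iloc[0]["empty_union"]


class TestPairedTtest:
    def test_hand_value(self):
        # diffs (-1,-1,-2): mean -4/3, sd 1/sqrt(3) -> t = -4, df = 2
        t, p, n = paired_ttest([1, 2, 3], [2, 3, 5])
        assert t == pytest.approx(-4.0)
        assert n == 3
        assert p == pytest.approx(2 * stats.t.sf(4.0, df=2))

    def test_antisymmetry(self):
        t1, p1, _ = paired_ttest([1, 2, 3], [2, 3, 5])
        t2, p2, _ = paired_ttest([2, 3, 5], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_ttest([1, 2, 3], [1, 2, 3])


class TestMaeCccCorrelation:
    def _tables(self, points):
        iqm = pd.DataFrame([
            {"roi": r, "model": "m", "metric": "mae", "mean": x, "sd": 0.0}
            for r, (x, _) in points.items()
        ])
        levels = pd.DataFrame([
            {"roi": r, "model": "m", "category": "texture", "mean_ccc": y,
             "sd_ccc": 0.0, "n_features": 75,
             **{f"pct_{lv}": 25.0 for lv in LEVELS}}
            for r, (_, y) in points.items()
        ])
        return iqm, levels

    def test_perfect_antimonotone(self):
        iqm, levels = self._tables({"a": (1, 3), "b": (2, 2), "c": (3, 1)})
        out = mae_ccc_correlation(iqm, levels)
        assert out.iloc[0]["pearson"] == pytest.approx(-1.0)
        assert out.iloc[0]["spearman"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        iqm, levels = self._tables({"a": (1, 1), "b": (2, 1), "c": (3, 1)})
        out = mae_ccc_correlation(iqm, levels)
        assert out.iloc[0]["degenerate"]
        assert out.iloc[0]["pearson"] == 0.0

    def test_nonlinear_monotone_via_rank_oracle(self):
        iqm, levels = self._tables({"a": (0, 0), "b": (1, 1), "c": (2, 4)})
        out = mae_ccc_correlation(iqm, levels)
        x, y = np.array([0, 1, 2.0]), np.array([0, 1, 4.0])
        expected_p = float(
            np.mean((x - x.mean()) * (y - y.mean()))
            / (x.std() * y.std())
        )
        assert out.iloc[0]["spearman"] == pytest.approx(1.0)
        assert out.iloc[0]["pearson"] == pytest.approx(expected_p)

    def test_too_few_points(self):
        iqm, levels = self._tables({"a": (1, 3), "b": (2, 2)})
        with pytest.raises(InsufficientPointsError):
            mae_ccc_correlation(iqm, levels)


class TestSubsetReport:
    def _records(self):
        rows = []
        levels = ["excellent"] * 5 + ["good"] * 5 + ["moderate"] * 6 + ["poor"] * 5
        for i, lv in enumerate(levels):
            rows.append({"roi": "GTVnx", "model": "m", "feature": f"f{i}",
                         "category": "texture", "ccc": 0.9, "level": lv,
                         "degenerate": False})
        return pd.DataFrame(rows)

    def test_counts_partition_subset(self):
        names = [f"f{i}" for i in range(21)]
        out = subset_report(self._records(), names)
        row = out.iloc[0]
        counts = [row[f"count_{lv}"] for lv in LEVELS]
        assert sum(counts) == 21
        assert counts == [5, 5, 6, 5]

    def test_single_feature_subset(self):
        out = subset_report(self._records(), ["f0"])
        row = out.iloc[0]
        assert row["count_excellent"] == 1
        assert row["count_poor"] == 0

    def test_unknown_name_raises_listing_it(self):
        with pytest.raises(LookupError_) as err:
            subset_report(self._records(), ["f0", "nope"])
        assert "nope" in str(err.value)
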