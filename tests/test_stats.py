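"""The statistical layer: closed-form oracles and calibration properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliavasc.stats import (
    anova2_holm_sidak,
    ddct_fold_change,
    holm_sidak,
    shapiro_normality,
    spearman_matrix,
    welch_t,
)
from oracles import welch_p_closed_form


class TestShapiro:
    def test_large_normal_sample_is_not_rejected(self):
        x = np.random.default_rng(123).normal(size=5000)
        res = shapiro_normality(x)
        assert res.p > 0.01
        assert 0.0 < res.statistic <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality(np.ones(10))

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_normality([1.0, 2.0])


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_closed_form_oracle(self, rng):
        x = rng.normal(0, 1, size=9)
        y = rng.normal(2, 3, size=14)
        res = welch_t(x, y)
        t, df, p = welch_p_closed_form(x, y)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_separated_jittered_groups_reject(self, rng):
        x = np.zeros(4) + rng.normal(0, 1e-6, 4)
        y = np.ones(4) + rng.normal(0, 1e-6, 4)
        assert welch_t(x, y).p < 0.01

    def test_swapping_groups_flips_sign_only(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 2, size=6)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_reduces_to_student_t_for_equal_variance_design(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 0.8  # same spread, equal n
        res = welch_t(x, y)
        t_student, p_student = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(t_student, abs=1e-10)
        assert res.p == pytest.approx(p_student, abs=1e-10)


class TestHolmSidak:
    def test_worked_example(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=12)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


class TestTwoWayAnova:
    @staticmethod
    def _age_effect_data(rng):
        rows = []
        for group in ("control", "hypertensive"):
            for age, shift in (("early", 0.0), ("late", 5.0)):
                for _ in range(6):
                    rows.append(
                        {"group": group, "age": age,
                         "value": shift + rng.normal(0, 0.01)}
                    )
        return pd.DataFrame(rows)

    def test_pure_age_effect_detected(self, rng):
        df = self._age_effect_data(rng)
        results = anova2_holm_sidak(df, "value", "group", "age")
        by_label = {r.comparison: r for r in results if r.test == "anova2"}
        assert by_label["age"].p < 0.01
        assert by_label["group"].p > 0.5
        assert by_label["group"].statistic == pytest.approx(0.0, abs=1.0)

    def test_main_effect_f_matches_closed_form_in_balanced_design(self, rng):
        df = self._age_effect_data(rng)
        results = anova2_holm_sidak(df, "value", "group", "age")
        f_age = next(r for r in results if r.comparison == "age").statistic
        # balanced two-way: SS_age = n_per_level_total * sum((mean_level - grand)^2)
        grand = df["value"].mean()
        means = df.groupby("age")["value"].mean()
        ss_age = sum(12 * (m - grand) ** 2 for m in means)
        cell_means = df.groupby(["group", "age"])["value"].transform("mean")
        ss_resid = ((df["value"] - cell_means) ** 2).sum()
        f_oracle = (ss_age / 1) / (ss_resid / (24 - 4))
        assert f_age == pytest.approx(f_oracle, rel=1e-6)

    def test_posthoc_adjusted_never_below_raw(self, rng):
        df = self._age_effect_data(rng)
        posthoc = [r for r in anova2_holm_sidak(df, "value", "group", "age")
                   if r.test == "holm_sidak_t"]
        assert len(posthoc) == 6  # all pairwise cell comparisons (4 choose 2)
        for r in posthoc:
            assert r.p_adjusted >= r.p - 1e-15

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 4, "age": ["e", "e", "l", "l"], "v": range(4)})
        with pytest.raises(ValueError):
            anova2_holm_sidak(df, "v", "g", "age")


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "expx": np.exp(x), "negx": -x})
        rho, p = spearman_matrix(df)
        assert rho.loc["x", "expx"] == pytest.approx(1.0)
        assert rho.loc["x", "negx"] == pytest.approx(-1.0)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 5, size=15).astype(float)
        y = rng.integers(0, 5, size=15).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:  # pragma: no cover
            x[0] += 1
            y[0] += 1
        rho, _ = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(oracle, rel=1e-12)

    def test_exact_permutation_p_at_small_n(self, rng):
        x = np.arange(6, dtype=float)
        y = np.array([0.0, 2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        # oracle: enumerate all 720 permutations directly
        import itertools

        robs = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            r = np.corrcoef(sps.rankdata(x), perm)[0, 1]
            total += 1
            count += abs(r) >= abs(robs) - 1e-12
        assert p.loc["x", "y"] == pytest.approx(count / total)

    def test_constant_column_reported_missing(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=12), "flat": np.ones(12)})
        rho, p = spearman_matrix(df)
        assert np.isnan(rho.loc["x", "flat"])


class TestDdct:
    @staticmethod
    def _table(target_shift=0.0):
        rows = []
        for group, samples in (("control", ["c1", "c2"]), ("treated", ["t1", "t2"])):
            for s in samples:
                for gene, ct in (("gapdh", 18.0), ("tnf", 25.0)):
                    shift = target_shift if (group == "treated" and gene == "tnf") else 0.0
                    for rep in range(3):
                        rows.append(
                            {"sample_id": s, "group": group, "gene": gene,
                             "ct": ct + shift}
                        )
        return pd.DataFrame(rows)

    def test_identical_ct_gives_unit_fold_change(self):
        out = ddct_fold_change(self._table(), "tnf", "gapdh", "control")
        assert np.allclose(out["fold_change"], 1.0)

    def test_one_cycle_lower_doubles_expression(self):
        out = ddct_fold_change(self._table(target_shift=-1.0), "tnf", "gapdh", "control")
        treated = out.loc[out["group"] == "treated", "fold_change"]
        assert np.allclose(treated, 2.0)
        control = out.loc[out["group"] == "control", "fold_change"]
        assert np.allclose(control, 1.0)

    def test_missing_reference_gene_rejected(self):
        table = self._table()
        with pytest.raises(ValueError):
            ddct_fold_change(table[table["gene"] != "gapdh"], "tnf", "gapdh", "control")


class TestCalibration:
    def test_welch_type_one_error_near_nominal(self):
        rng = np.random.default_rng(2026)
        reps = 10_000
        x = rng.normal(size=(reps, 10))
        y = rng.normal(size=(reps, 10))
        rejections = 0
        for i in range(reps):
            rejections += welch_t(x[i], y[i]).p < 0.05
        assert 0.04 <= rejections / reps <= 0.06
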