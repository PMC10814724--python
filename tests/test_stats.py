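"""Cohort statistics: summaries, t-tests, correlations, dose response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import kdecho as k
from kdecho.config import DEFAULT_NORMS


def _frame(groups, days, values, measurement="coronary_inner_d_mm"):
    return pd.DataFrame({"group": groups, "day": days, measurement: values})


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance two-tailed Student's t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


def _pearson_oracle(x, y):
    """Direct product-moment formula plus the t-transform p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    r = np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, 2 * sps.t.sf(abs(t), n - 2)


class TestSummarize:
    def test_cell_mean_and_sem(self):
        df = _frame(["a"] * 3, [0] * 3, [1.0, 2.0, 3.0])
        out = k.summarize(df, "coronary_inner_d_mm")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["mean"] == 2.0
        assert row["sem"] == pytest.approx(0.577, abs=0.001)

    def test_single_value_cell_sem_missing(self):
        df = _frame(["a"], [0], [1.5])
        row = k.summarize(df, "coronary_inner_d_mm").iloc[0]
        assert row["n"] == 1 and np.isnan(row["sem"])

    def test_empty_cells_absent_not_zero(self):
        df = _frame(["a", "b"], [0, 0], [1.0, np.nan])
        out = k.summarize(df, "coronary_inner_d_mm")
        assert list(out["group"]) == ["a"]

    def test_zero_noise_control_cells_equal_norms(self):
        cfg = k.default_config(
            norms={m: k.Norm(n.mean, 0.0) for m, n in DEFAULT_NORMS.items()},
            weight=k.WeightModel(20.0, 0.0, 0.15, 0.0),
            severity_rho=0.0,
            effects={g: {} for g in ("control", "low", "medium", "high")},
            noise_abs_sd={},
        )
        df = k.generate_cohort(cfg)
        out = k.summarize(df[df["group"] == "control"], "coronary_inner_d_mm")
        assert (out["mean"] == 0.217).all()

    def test_percent_column_joined_when_scored(self, population_model):
        cfg = k.default_config(seed=21)
        scored = k.score_table(
            k.derive_table(k.generate_cohort(cfg)), population_model
        )
        out = k.summarize(
            scored, "coronary_inner_d_mm", z_col="z_coronary_inner_d_mm"
        )
        high28 = out.query("group == 'high' and day == 28").iloc[0]
        assert 0.0 <= high28["percent_z_gt_cutoff"] <= 100.0


class TestTwoSampleT:
    def _df(self, a, b, day=0):
        return _frame(
            ["a"] * len(a) + ["b"] * len(b),
            [day] * (len(a) + len(b)),
            list(a) + list(b),
        )

    def test_identical_groups(self):
        res = k.two_sample_t(self._df([1, 2, 3], [1, 2, 3]), "a", "b",
                             "coronary_inner_d_mm", 0)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)
        assert res.significant is False

    def test_hand_computed_example(self):
        res = k.two_sample_t(self._df([1, 2, 3], [4, 5, 6]), "a", "b",
                             "coronary_inner_d_mm", 0)
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=0.001)
        assert res.significant is True

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            k.two_sample_t(self._df([1.0], [2.0, 3.0]), "a", "b",
                           "coronary_inner_d_mm", 0)

    def test_matches_textbook_oracle_on_integer_grid(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.integers(0, 10, na).astype(float)
            b = rng.integers(0, 10, nb).astype(float)
            if a.var() == 0 and b.var() == 0:
                continue
            res = k.two_sample_t(self._df(a, b), "a", "b",
                                 "coronary_inner_d_mm", 0)
            t, df, p = _pooled_t_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == df
            assert res.p == pytest.approx(p, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.integers(-5, 5), min_size=2, max_size=8),
        b=st.lists(st.integers(-5, 5), min_size=2, max_size=8),
    )
    def test_matches_textbook_oracle_property(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        res = k.two_sample_t(self._df(a, b), "a", "b",
                             "coronary_inner_d_mm", 0)
        t, df, p = _pooled_t_oracle(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_null_p_uniform_over_seeds(self):
        pvals = []
        for s in range(1000):
            rng = np.random.default_rng(40_000 + s)
            a = rng.normal(0.217, 0.028, 25)
            b = rng.normal(0.217, 0.028, 25)
            res = k.two_sample_t(self._df(a, b), "a", "b",
                                 "coronary_inner_d_mm", 0)
            pvals.append(res.p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_welch_flag(self):
        df = self._df([1, 2, 3, 4], [1, 2, 3, 40])
        pooled = k.two_sample_t(df, "a", "b", "coronary_inner_d_mm", 0)
        welch = k.two_sample_t(df, "a", "b", "coronary_inner_d_mm", 0,
                               welch=True)
        assert pooled.df == 6 and welch.df < 6


class TestPearson:
    def _df(self, x, y):
        return pd.DataFrame({"day": [28] * len(x), "x": x, "y": y})

    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = k.pearson_corr(self._df(x, x), "x", "y", day=28)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = k.pearson_corr(self._df(x, -2 * x + 5), "x", "y", day=28)
        assert res.r == pytest.approx(-1.0)

    def test_example_pairs_match_direct_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r_expect, p_expect = _pearson_oracle(x, y)
        assert r_expect == pytest.approx(10 / np.sqrt(148))  # 0.8220
        res = k.pearson_corr(self._df(x, y), "x", "y", day=28)
        assert res.r == pytest.approx(r_expect, abs=1e-10)
        assert res.p == pytest.approx(p_expect, abs=1e-6)
        assert res.n == 5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            k.pearson_corr(self._df([1, 1, 1], [1, 2, 3]), "x", "y", day=28)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            k.pearson_corr(self._df([1, 2], [1, 2]), "x", "y", day=28)

    @settings(derandomize=True, max_examples=40)
    @given(
        scale=st.floats(min_value=0.1, max_value=50),
        shift=st.floats(min_value=-100, max_value=100),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, scale, shift, flip):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        base = k.pearson_corr(self._df(x, y), "x", "y", day=28)
        factor = -scale if flip else scale
        trans = k.pearson_corr(self._df(x, factor * y + shift), "x", "y", day=28)
        expected = -base.r if flip else base.r
        assert trans.r == pytest.approx(expected, abs=1e-9)
        assert trans.p == pytest.approx(base.p, abs=1e-9)

    def test_carotid_coronary_association_positive(self, population_model):
        # dose-affected cohorts show the carotid-coronary association on
        # weight-adjusted day-28 values
        cfg = k.default_config(seed=15, n_per_group_per_day=30)
        d = k.derive_table(k.generate_cohort(cfg))
        treated = d[d["group"] != "control"]
        res = k.pearson_corr(
            treated, "carotid_outer_d_mm_wadj", "coronary_inner_d_mm_wadj",
            day=28,
        )
        assert res.r > 0 and res.p <= 0.05


class TestDoseResponse:
    def test_default_generator_monotone_at_day_28(self):
        cfg = k.default_config(seed=10, n_per_group_per_day=50)
        df = k.generate_cohort(cfg)
        dr = k.dose_response_table(df, "coronary_inner_d_mm", cfg.groups)
        assert list(dr.means.columns) == ["control", "low", "medium", "high"]
        assert dr.monotone[28] is True
        assert dr.monotone[21] is True
        assert dr.single_group is False

    def test_control_only_vacuously_monotone(self):
        cfg = k.default_config(seed=10, groups={"control": 0.0})
        df = k.generate_cohort(cfg)
        dr = k.dose_response_table(df, "coronary_inner_d_mm", {"control": 0.0})
        assert dr.single_group is True
        assert all(dr.monotone.values())

    def test_null_effects_flag_is_coin_flip(self):
        # two groups with no effect: monotone ~50% of seeds
        hits = 0
        for s in range(100):
            cfg = k.default_config(
                seed=60_000 + s,
                groups={"control": 0.0, "high": 4.0},
                effects={"control": {}, "high": {}},
                noise_abs_sd={},
                days=(0, 28),
                n_per_group_per_day=9,
            )
            df = k.generate_cohort(cfg)
            dr = k.dose_response_table(
                df[df["day"] == 28], "coronary_inner_d_mm", cfg.groups
            )
            hits += dr.monotone[28]
        assert 30 <= hits <= 70

    def test_ejection_fraction_drops_in_high_dose_day21(self):
        cfg = k.default_config(seed=17, n_per_group_per_day=30)
        df = k.generate_cohort(cfg)
        res = k.two_sample_t(df, "high", "control", "ejection_fraction_pct", 21)
        assert res.t < 0  # high-dose EF below control
        assert res.significant is True
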