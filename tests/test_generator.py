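"""Synthetic cohort generator: determinism, distributional fidelity,
structural invariants and the CSV round trip."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import kdecho as k
from kdecho.config import DEFAULT_NORMS


def _zero_noise_config(**overrides):
    return k.default_config(
        norms={m: k.Norm(n.mean, 0.0) for m, n in DEFAULT_NORMS.items()},
        weight=k.WeightModel(20.0, 0.0, 0.15, 0.0),
        severity_rho=0.0,
        effects={g: {} for g in ("control", "low", "medium", "high")},
        noise_abs_sd={},
        **overrides,
    )


def _csv_bytes(df):
    buf = io.StringIO()
    k.write_cohort(df, buf)
    return buf.getvalue()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = k.generate_cohort(k.default_config(seed=42))
        b = k.generate_cohort(k.default_config(seed=42))
        assert _csv_bytes(a) == _csv_bytes(b)

    def test_different_seed_differs(self):
        a = k.generate_cohort(k.default_config(seed=42))
        b = k.generate_cohort(k.default_config(seed=43))
        assert _csv_bytes(a) != _csv_bytes(b)

    def test_baseline_same_seed_identical(self):
        cfg = k.default_config(seed=9)
        pd.testing.assert_frame_equal(
            k.generate_baseline(cfg), k.generate_baseline(cfg)
        )


class TestStructure:
    def test_one_row_per_animal_day(self, default_cohort):
        assert len(default_cohort) == 4 * 9 * 5
        counts = default_cohort.groupby("animal_id")["day"].nunique()
        assert (counts == 5).all()

    def test_weights_follow_growth(self):
        cfg = k.default_config(seed=2)
        df = k.generate_cohort(cfg)
        by_day = df.groupby("day")["body_weight_g"].mean()
        # 28 days x 0.15 g/day = +4.2 g expected drift
        assert by_day[28] - by_day[0] == pytest.approx(4.2, abs=1.0)

    def test_outer_never_below_inner(self):
        for seed in range(5):
            df = k.generate_cohort(k.default_config(seed=seed))
            for inner, outer in (
                ("coronary_inner_d_mm", "coronary_outer_d_mm"),
                ("carotid_inner_d_mm", "carotid_outer_d_mm"),
                ("aorta_inner_d_mm", "aorta_outer_d_mm"),
            ):
                assert (df[outer] >= df[inner]).all()

    def test_zero_noise_limit_equals_means(self):
        df = k.generate_cohort(_zero_noise_config(seed=0))
        assert (df["coronary_inner_d_mm"] == 0.217).all()
        assert np.allclose(df["coronary_outer_d_mm"], 0.472, atol=1e-12)
        assert (df["ejection_fraction_pct"] == 65.0).all()

    def test_baseline_ns_mask(self):
        cfg = k.default_config(seed=4, baseline_ns=dict(k.STUDY_BASELINE_NS))
        base = k.generate_baseline(cfg)
        assert len(base) == 38
        assert base["coronary_inner_d_mm"].notna().sum() == 18
        assert base["coronary_outer_d_mm"].notna().sum() == 37
        assert base["carotid_outer_d_mm"].notna().sum() == 38


class TestDistributions:
    def test_day0_pooled_mean_recovers_norm(self):
        # law of large numbers on the day-0 coronary inner diameter
        pooled = np.concatenate(
            [
                k.generate_baseline(k.default_config(seed=s), n=18)[
                    "coronary_inner_d_mm"
                ].to_numpy()
                for s in range(200)
            ]
        )
        assert pooled.mean() == pytest.approx(0.217, abs=0.002)

    def test_day0_normality_ks_over_seeds(self):
        # distributional recovery: KS vs the configured normal law passes
        # at alpha = 0.01 in at least 95 of 100 seeds
        passes = 0
        for s in range(100):
            base = k.generate_baseline(k.default_config(seed=500 + s), n=100)
            x = base["coronary_inner_d_mm"].to_numpy()
            p = sps.kstest(x, "norm", args=(0.217, 0.028)).pvalue
            passes += p > 0.01
        assert passes >= 95

    def test_control_purity_p_uniform(self):
        # control day 28 vs day 0 under repetition: t-test p is uniform
        pvals = []
        for s in range(200):
            cfg = k.default_config(
                seed=3000 + s, groups={"control": 0.0},
                n_per_group_per_day=30, days=(0, 28),
            )
            df = k.generate_cohort(cfg)
            a = df.loc[df["day"] == 0, "coronary_inner_d_mm"]
            b = df.loc[df["day"] == 28, "coronary_inner_d_mm"]
            pvals.append(sps.ttest_ind(a, b).pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_severity_coupling_carotid_coronary(self):
        cfg = k.default_config(
            seed=77, groups={"high": 4.0}, n_per_group_per_day=10000,
            days=(0, 28),
        )
        d28 = k.generate_cohort(cfg).query("day == 28")
        r_outer = np.corrcoef(
            d28["carotid_outer_d_mm"], d28["coronary_inner_d_mm"]
        )[0, 1]
        r_wall = np.corrcoef(
            d28["carotid_upper_wall_mm"], d28["coronary_inner_d_mm"]
        )[0, 1]
        assert r_outer >= 0.3
        assert r_wall >= 0.3

    def test_no_coupling_in_control(self):
        cfg = k.default_config(
            seed=78, groups={"control": 0.0}, n_per_group_per_day=10000,
            days=(0, 28),
        )
        d28 = k.generate_cohort(cfg).query("day == 28")
        r = np.corrcoef(d28["carotid_outer_d_mm"], d28["coronary_inner_d_mm"])[0, 1]
        assert abs(r) < 0.05


class TestRoundTrip:
    def test_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        empty = k.records_to_frame([])
        k.write_cohort(empty, path)
        assert path.read_text().strip() == ",".join(k.COHORT_COLUMNS)
        back = k.read_cohort(path)
        assert back.empty and list(back.columns) == list(k.COHORT_COLUMNS)

    def test_single_record_missing_ef(self, tmp_path):
        rec = k.EchoRecord(
            animal_id="m1", group="control", day=0, body_weight_g=20.0,
            coronary_inner_d_mm=0.217, coronary_outer_d_mm=0.472,
        )
        path = tmp_path / "one.csv"
        k.write_cohort(k.records_to_frame([rec]), path)
        assert path.read_text().splitlines()[1].endswith(",")  # empty EF cell
        back = k.frame_to_records(k.read_cohort(path))
        assert back == [rec]

    def test_generated_cohort_round_trip(self, tmp_path):
        cfg = k.default_config(
            seed=8, missingness={"ejection_fraction_pct": 0.2}
        )
        df = k.generate_cohort(cfg)
        assert df["ejection_fraction_pct"].isna().any()
        path = tmp_path / "cohort.csv"
        k.write_cohort(df, path)
        back = k.read_cohort(path)
        pd.testing.assert_frame_equal(back, df)

    def test_read_error_names_row_and_rule(self, tmp_path):
        df = k.generate_cohort(k.default_config(seed=1))
        df.loc[4, "body_weight_g"] = -1.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(k.CohortValidationError, match="row 5.*body_weight_g"):
            k.read_cohort(path)

    def test_read_error_on_inverted_calipers(self, tmp_path):
        df = k.generate_cohort(k.default_config(seed=1))
        df.loc[0, "coronary_outer_d_mm"] = 0.1  # below the inner diameter
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(k.CohortValidationError, match="row 1.*coronary_outer"):
            k.read_cohort(path)

    def test_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "odd.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(k.CohortValidationError, match="header"):
            k.read_cohort(path)
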