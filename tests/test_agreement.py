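"""Difference scores, MAE, rm-correlation, variance components, LOA, moderators."""
import json
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respagree import (
    AnalysisConfig,
    CohortParams,
    DifferenceSeries,
    PipelineStageError,
    ZeroWithinVarianceError,
    bland_altman,
    difference_series,
    generate_cohort,
    loa_from_moments,
    mean_absolute_error,
    moderators,
    rm_correlation,
    run_agreement,
    variance_components,
)

from conftest import make_dataset


def series(subject_id, d):
    d = np.asarray(d, dtype=float)
    return DifferenceSeries(np.asarray(subject_id, dtype=object), d, np.full_like(d, 30.0))


# ---------------------------------------------------------------------------
# difference scores
# ---------------------------------------------------------------------------

class TestDifferenceSeries:
    def test_direct_arithmetic(self):
        diffs = difference_series(make_dataset([("A", 0, 30.0, 31.0)]))
        assert diffs.d[0] == pytest.approx(-1.0)
        assert diffs.avg[0] == pytest.approx(30.5)

    def test_identical_streams_give_zero(self, small_cohort):
        data, _ = small_cohort
        ep = data.epochs.copy()
        ep["bpm_test"] = ep["bpm_ref"]
        from respagree import PairedDataset

        diffs = difference_series(PairedDataset(ep, data.subjects))
        assert np.all(diffs.d == 0.0)

    def test_swapping_devices_negates_d(self, small_cohort):
        data, _ = small_cohort
        from respagree import PairedDataset

        swapped = data.epochs.rename(columns={"bpm_ref": "bpm_test", "bpm_test": "bpm_ref"})
        a = difference_series(data)
        b = difference_series(PairedDataset(swapped, data.subjects))
        np.testing.assert_allclose(a.d, -b.d)
        np.testing.assert_allclose(a.avg, b.avg)


# ---------------------------------------------------------------------------
# MAE
# ---------------------------------------------------------------------------

class TestMeanAbsoluteError:
    def test_hand_arithmetic(self):
        res = mean_absolute_error(series(["A", "A", "A"], [2.0, 0.0, -3.0]), n_boot=200, seed=1)
        assert res.mae == pytest.approx(5.0 / 3.0)
        assert np.isnan(res.ci_lower)  # single subject: CI undefined

    def test_all_zero_differences(self):
        res = mean_absolute_error(series(["A"] * 3 + ["B"] * 3, [0.0] * 6), n_boot=500, seed=1)
        assert res.mae == 0.0
        assert (res.ci_lower, res.ci_upper) == (0.0, 0.0)

    def test_seeded_ci_reproducible(self):
        data, _ = generate_cohort(
            CohortParams(n_subjects=12, nap_mean_min=25.0, nap_sd_min=5.0, seed=8)
        )
        diffs = difference_series(data)
        a = mean_absolute_error(diffs, n_boot=2000, seed=5)
        b = mean_absolute_error(diffs, n_boot=2000, seed=5)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
        c = mean_absolute_error(diffs, n_boot=2000, seed=6)
        assert (a.ci_lower, a.ci_upper) != (c.ci_lower, c.ci_upper)

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            mean_absolute_error(series(["A", "B"], [1.0, 2.0]), n_boot=50, seed=1)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40), st.integers(2, 5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mae_at_least_absolute_mean(self, values, n_subjects):
        sid = [f"S{i % n_subjects}" for i in range(len(values))]
        diffs = series(sid, values)
        res = mean_absolute_error(diffs, n_boot=0, seed=0)
        assert res.mae >= abs(np.mean(values)) - 1e-12


# ---------------------------------------------------------------------------
# repeated-measures correlation
# ---------------------------------------------------------------------------

def _ancova_brute_force(df):
    """Explicit design-matrix least squares: subject dummies + common slope."""
    subs = pd.get_dummies(df["subject_id"]).to_numpy(dtype=float)
    X = np.column_stack([subs, df["bpm_ref"].to_numpy()])
    y = df["bpm_test"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_error = float(resid @ resid)
    beta0, *_ = np.linalg.lstsq(subs, y, rcond=None)
    resid0 = y - subs @ beta0
    ss_total = float(resid0 @ resid0)
    ss_measure = ss_total - ss_error
    return float(np.sign(beta[-1]) * np.sqrt(max(ss_measure, 0.0) / ss_total))


class TestRmCorrelation:
    @pytest.mark.parametrize("slope,expected", [(0.8, 1.0), (-0.8, -1.0)])
    def test_perfect_common_slope(self, slope, expected):
        rows = []
        for s, intercept in enumerate((60.0, 70.0, 80.0)):
            for j in range(4):
                x = 28.0 + j
                rows.append((f"S{s}", s * 10 + j, x, intercept + slope * x))
        res = rm_correlation(make_dataset(rows))
        assert res.r == pytest.approx(expected)
        assert res.p_value == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_design_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(int(rng.integers(3, 6))):
            for j in range(int(rng.integers(3, 8))):
                rows.append((f"S{s}", s * 100 + j, rng.uniform(20, 50), rng.uniform(20, 50)))
        data = make_dataset(rows)
        mine = rm_correlation(data)
        oracle = _ancova_brute_force(data.epochs)
        assert mine.r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, small_cohort):
        pg = pytest.importorskip("pingouin")
        data, _ = small_cohort
        df = data.epochs.rename(columns={"bpm_ref": "x", "bpm_test": "y"})
        theirs = pg.rm_corr(data=df, x="x", y="y", subject="subject_id")
        mine = rm_correlation(data)
        assert mine.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert mine.df == int(theirs["dof"].iloc[0])
        assert mine.p_value == pytest.approx(float(theirs["pval"].iloc[0]), rel=1e-8)

    def test_invariant_to_subject_specific_shifts(self, small_cohort):
        data, _ = small_cohort
        from respagree import PairedDataset

        base = rm_correlation(data)
        ep = data.epochs.copy()
        shifts = {s: 5.0 * i for i, s in enumerate(sorted(ep["subject_id"].unique()))}
        ep["bpm_test"] = ep["bpm_test"] + ep["subject_id"].map(shifts)
        shifted = rm_correlation(PairedDataset(ep, data.subjects))
        assert shifted.r == pytest.approx(base.r, abs=1e-12)

    def test_zero_within_variance_is_an_error(self):
        rows = [("A", j, 30.0, 25.0 + j) for j in range(3)]
        rows += [("B", j, 40.0, 30.0 + j) for j in range(3)]
        with pytest.raises(ZeroWithinVarianceError):
            rm_correlation(make_dataset(rows))

    def test_single_epoch_subjects_dropped_with_warning(self):
        rows = [("A", j, 28.0 + j, 30.0 + j) for j in range(4)]
        rows += [("B", j, 30.0 + j, 28.0 + 0.5 * j) for j in range(4)]
        rows += [("C", 0, 31.0, 33.0)]
        with pytest.warns(UserWarning, match="C"):
            res = rm_correlation(make_dataset(rows))
        assert res.n_subjects == 2
        assert res.n_obs == 8
        assert res.df == 8 - 2 - 1


# ---------------------------------------------------------------------------
# variance components and LOA
# ---------------------------------------------------------------------------

def _anova_brute_force(sid, d):
    subjects = sorted(set(sid))
    n, N = len(subjects), len(d)
    dbar = {s: np.mean([d[i] for i in range(N) if sid[i] == s]) for s in subjects}
    grand = np.mean(d)
    ms_w = sum((d[i] - dbar[sid[i]]) ** 2 for i in range(N)) / (N - n)
    ms_b = sum(
        sum(1 for x in sid if x == s) * (dbar[s] - grand) ** 2 for s in subjects
    ) / (n - 1)
    m = np.array([sum(1 for x in sid if x == s) for s in subjects], dtype=float)
    divisor = (m.sum() ** 2 - (m**2).sum()) / ((n - 1) * m.sum())
    return ms_w, ms_b, divisor


class TestVarianceComponents:
    def test_balanced_divisor_reduces_to_m(self):
        rng = np.random.default_rng(3)
        sid = np.repeat([f"S{i}" for i in range(7)], 12)
        vc = variance_components(series(sid, rng.normal(0, 2, sid.size)))
        assert vc.divisor == pytest.approx(12.0, abs=1e-12)

    def test_all_equal_differences(self):
        sid = ["A"] * 4 + ["B"] * 4
        vc = variance_components(series(sid, [1.5] * 8))
        assert vc.ms_within == 0.0 and vc.ms_between == 0.0 and vc.sd_d == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sum_of_squares_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        sid, d = [], []
        for s in range(int(rng.integers(2, 7))):
            for _ in range(int(rng.integers(2, 9))):
                sid.append(f"S{s}")
                d.append(float(rng.normal(0, 3)))
        vc = variance_components(series(sid, d))
        ms_w, ms_b, divisor = _anova_brute_force(sid, np.array(d))
        assert vc.ms_within == pytest.approx(ms_w, abs=1e-10)
        assert vc.ms_between == pytest.approx(ms_b, abs=1e-10)
        assert vc.divisor == pytest.approx(divisor, abs=1e-12)
        assert vc.sd_d**2 == pytest.approx(vc.sigma2_between + vc.sigma2_within, rel=1e-12)

    def test_one_epoch_per_subject_instructs_classical_loa(self):
        sid = ["A", "B", "C"]
        with pytest.raises(ValueError, match="classical"):
            variance_components(series(sid, [1.0, 2.0, 3.0]))

    def test_parameter_recovery_two_level_model(self):
        # d_ij = b_i + e_ij with sigma_B=2, sigma_W=1.5; n=200 subjects x 60
        # epochs. Averaged over 5 generator seeds so the check sits well
        # inside the sampling noise of a single cohort.
        est_b, est_w = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, m = 200, 60
            b = np.repeat(rng.normal(0, 2.0, n), m)
            d = b + rng.normal(0, 1.5, n * m)
            sid = np.repeat([f"S{i:03d}" for i in range(n)], m)
            vc = variance_components(series(sid, d))
            est_b.append(vc.sigma2_between)
            est_w.append(vc.sigma2_within)
        assert np.mean(est_b) == pytest.approx(4.0, rel=0.10)
        assert np.mean(est_w) == pytest.approx(2.25, rel=0.05)


class TestLimitsOfAgreement:
    def test_printed_moments_reproduce_printed_limits(self):
        lo, hi = loa_from_moments(-0.91, 2.8928571428571428)
        assert round(lo, 2) == -6.58
        assert round(hi, 2) == 4.76

    def test_unit_normal_limits(self):
        assert loa_from_moments(0.0, 1.0) == pytest.approx((-1.96, 1.96))

    @given(st.floats(-10, 10), st.floats(0, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_about_the_mean(self, mean_d, sd_d):
        lo, hi = loa_from_moments(mean_d, sd_d)
        assert lo + hi == pytest.approx(2 * mean_d, abs=1e-9)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            loa_from_moments(0.0, -1.0)

    def test_all_zero_differences_degenerate_interval(self):
        sid = ["A"] * 3 + ["B"] * 3
        res = bland_altman(series(sid, [0.0] * 6))
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)
        assert res.pct_within == 100.0

    def test_negative_between_component_truncated_to_zero(self):
        # within-noise only: raw sigma2_B is negative and gets truncated
        sid = ["A"] * 4 + ["B"] * 4
        d = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
        res = bland_altman(series(sid, d))
        assert res.components.sigma2_between == 0.0  # truncated at zero
        assert res.pct_within == 100.0

    def test_loa_symmetry_invariant(self, small_cohort):
        data, _ = small_cohort
        res = bland_altman(difference_series(data))
        assert res.loa_upper - res.mean_d == pytest.approx(
            res.mean_d - res.loa_lower, rel=1e-12
        )
        assert res.loa_upper - res.mean_d == pytest.approx(
            1.96 * res.components.sd_d, rel=1e-12
        )

    def test_epoch_vs_subject_weighting(self):
        # unbalanced: subject A pulls the epoch-level mean, not the subject mean
        sid = ["A"] * 9 + ["B"]
        d = [1.0] * 9 + [-1.0]
        diffs = series(sid, d)
        assert bland_altman(diffs, weighting="epoch").mean_d == pytest.approx(0.8)
        assert bland_altman(diffs, weighting="subject").mean_d == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# moderators
# ---------------------------------------------------------------------------

class TestModerators:
    def test_constant_subject_means_flagged_degenerate(self):
        rows = [(s, j, 30.0 + j, 28.0 + j) for s in ("A", "B", "C") for j in range(3)]
        subjects = [("A", 5.0, 30.0), ("B", 10.0, 45.0), ("C", 15.0, 60.0)]
        data = make_dataset(rows, subjects)
        res = moderators(data, difference_series(data))
        assert res.degenerate
        assert res.r_age is None and res.r_nap is None
        assert res.r_nap_age == pytest.approx(1.0)

    def test_null_moderator_small_at_large_n(self):
        # d-bar_i is generated independently of age and duration; averaging
        # the sample correlation over 5 cohorts of 200 subjects puts the 0.15
        # bound several standard errors out
        r_age, r_nap = [], []
        for seed in range(1, 6):
            params = CohortParams(
                n_subjects=200, nap_mean_min=20.0, nap_sd_min=4.0, nap_min_min=10.0,
                nap_max_min=40.0, nap_age_corr_slope=0.0, p_ref_artifact=0.0,
                p_test_artifact=0.0, p_both_artifact=0.0, p_ref_outlier=0.0, seed=seed,
            )
            data, _ = generate_cohort(params)
            res = moderators(data, difference_series(data))
            r_age.append(res.r_age)
            r_nap.append(res.r_nap)
        assert abs(np.mean(r_age)) < 0.15
        assert abs(np.mean(r_nap)) < 0.15

    def test_planted_duration_age_effect_recovered(self):
        data, _ = generate_cohort(CohortParams(n_subjects=200, seed=1))
        res = moderators(data, difference_series(data))
        assert res.r_nap_age > 0.5

    def test_missing_covariates_excluded_with_warning(self):
        rows = [(s, j, 30.0 + j + (0.1 * j if s == "D" else 0), 28.0 + j)
                for s in ("A", "B", "C", "D") for j in range(3)]
        subjects = [("A", 5.0, 30.0), ("B", 10.0, 45.0), ("C", 15.0, 60.0),
                    ("D", float("nan"), 50.0)]
        data = make_dataset(rows, subjects)
        with pytest.warns(UserWarning, match="D"):
            res = moderators(data, difference_series(data))
        assert "D" not in res.subject_ids


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestRunAgreement:
    def test_identical_devices_end_to_end(self):
        params = CohortParams(
            n_subjects=4, nap_mean_min=30.0, nap_sd_min=0.0, within_subject_sd_bpm=0.0,
            between_subject_sd_bpm=0.0, bias_bpm=0.0, p_ref_artifact=0.0,
            p_test_artifact=0.0, p_both_artifact=0.0, p_ref_outlier=0.0,
            nap_age_corr_slope=0.0, seed=2,
        )
        data, _ = generate_cohort(params)
        report = run_agreement(data, n_boot=200, seed=1)
        a = report.agreement
        assert a.mae.mae == 0.0
        assert a.rm_corr.r == pytest.approx(1.0)
        assert (a.bland_altman.loa_lower, a.bland_altman.loa_upper) == (0.0, 0.0)
        assert a.bland_altman.pct_within == 100.0

    def test_smoke_all_fields_finite(self, small_cohort):
        data, _ = small_cohort
        report = run_agreement(data, n_boot=500, seed=3)
        d = report.to_dict()
        for key in ("value", "ci_lower", "ci_upper"):
            assert np.isfinite(d["mae"][key])
        ba = d["bland_altman"]
        assert np.isfinite(ba["mean_d"]) and np.isfinite(ba["sd_d"])
        assert 0 <= ba["pct_within"] <= 100
        scr = d["screening"]
        assert (
            scr["artifacts"]["n_retained"]
            == scr["artifacts"]["n_input"]
            - sum(scr["artifacts"][k] for k in scr["artifacts"] if k.startswith("n_rejected"))
        )

    def test_fixed_seed_bit_identical_report(self):
        from respagree import study_like_cohort

        a = run_agreement(study_like_cohort(seed=4), n_boot=500, seed=9).to_json()
        b = run_agreement(study_like_cohort(seed=4), n_boot=500, seed=9).to_json()
        assert a == b
        json.loads(a)  # valid JSON

    def test_stage_failure_names_the_stage(self):
        data = make_dataset([("A", j, 30.0 + j, 29.0 + j) for j in range(4)])
        with pytest.raises(PipelineStageError, match="rm_correlation"):
            run_agreement(data, n_boot=200, seed=1)

    def test_config_round_trip_yaml(self, tmp_path):
        cfg = AnalysisConfig(n_boot=123, outlier_sided="two_sided", outlier_streams=("ref", "test"))
        p = tmp_path / "cfg.yaml"
        import yaml

        p.write_text(yaml.safe_dump(cfg.to_dict()))
        back = AnalysisConfig.from_yaml(p)
        assert back == cfg
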