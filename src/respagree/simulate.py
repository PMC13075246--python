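"""Synthetic paired-device epoch cohorts for end-to-end testing.

The generator writes the device *difference* model directly,

    d_ij = bias + b_i + e_ij,   b_i ~ N(0, sigma_B^2),  e_ij ~ N(0, sigma_W^2),

and reconstructs the two device columns around a shared true respiratory
rate: the test device reads the true rate plus measurement noise, and the
reference device reads the test value plus d_ij. This makes the
between/within variance components of the differences exactly recoverable by
the analysis, which a fully mechanistic two-sensor noise model would not.

The true rate declines with age (infant respiratory rate falls over the
first two years) and drifts slowly within a nap. Nap lengths follow a
truncated normal whose *post-truncation* moments match the requested mean
and SD (the parent location/scale are solved numerically), shifted with age
so that older infants nap longer. Sparse artifact contamination and
occasional extreme reference readings are injected with known labels so
screening recall is testable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import EPOCH_COLUMNS, SUBJECT_COLUMNS, PairedDataset

#: within-nap slow drift of the true rate (bpm, sinusoid amplitude)
DRIFT_AMPLITUDE_BPM = 1.5
#: within-nap drift period range (minutes)
DRIFT_PERIOD_MIN = (40.0, 90.0)

_EPOCH0 = pd.Timestamp("2024-06-01 13:00")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generating parameters.

    Defaults emulate a nap study of 33 infants: naps of 18-191 minutes with
    mean 57.9 and SD 40.1, ages spanning 1-22 months, a small negative
    device bias (the test device reads ~0.9 bpm high), difference variance
    split into between-subject SD 2.5 and within-subject SD 1.5 bpm
    (SD_d ~ 2.9), and roughly 0.8% / 3.8% / 0.9% of epochs contaminated by
    reference-only / test-only / both-device artifacts plus 2.6% replaced by
    extreme reference outliers.
    """

    n_subjects: int = 33
    age_months_range: tuple[float, float] = (1.0, 22.0)
    nap_mean_min: float = 57.9
    nap_sd_min: float = 40.1
    nap_min_min: float = 18.0
    nap_max_min: float = 191.0
    baseline_intercept_bpm: float = 45.0
    baseline_age_slope_bpm_per_month: float = -0.8
    within_subject_sd_bpm: float = 1.5
    between_subject_sd_bpm: float = 2.5
    bias_bpm: float = -0.91
    ref_measurement_sd_bpm: float = 1.0
    p_ref_artifact: float = 0.008
    p_test_artifact: float = 0.038
    p_both_artifact: float = 0.009
    p_ref_outlier: float = 0.026
    outlier_shift_sd_units: float = 5.0
    nap_age_corr_slope: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.age_months_range
        if not 0 < lo < hi:
            raise ValueError("age_months_range must be increasing and positive")
        for name in (
            "nap_sd_min",
            "within_subject_sd_bpm",
            "between_subject_sd_bpm",
            "ref_measurement_sd_bpm",
            "outlier_shift_sd_units",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 1 <= self.nap_min_min <= self.nap_mean_min <= self.nap_max_min:
            raise ValueError("need 1 <= nap_min_min <= nap_mean_min <= nap_max_min")
        probs = (
            self.p_ref_artifact,
            self.p_test_artifact,
            self.p_both_artifact,
            self.p_ref_outlier,
        )
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1:
            raise ValueError("artifact/outlier probabilities must lie in [0,1] and sum <= 1")


@dataclass
class CohortTruth:
    """Hidden generating record, aligned with the dataset's epoch order."""

    params: CohortParams
    subject_ids: list[str]
    ages_months: np.ndarray
    nap_minutes: np.ndarray
    subject_effects: np.ndarray  # b_i
    is_ref_artifact: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    is_test_artifact: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    is_both_artifact: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    is_outlier: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def is_any_artifact(self) -> np.ndarray:
        return self.is_ref_artifact | self.is_test_artifact | self.is_both_artifact


@lru_cache(maxsize=64)
def _matched_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (loc, scale) whose truncation to [lo, hi] matches the targets.

    The post-truncation mean is always matched exactly (a naive loc=mean
    parent would overshoot it by ~10 minutes at the defaults because of the
    left truncation). The SD is matched when the family can reach it;
    otherwise the closest achievable SD is taken — on a window this
    asymmetric the truncated normal tops out below some requested SDs (its
    limiting shape is an exponential tail).
    """
    import warnings as _warnings

    def moments(loc: float, scale: float) -> tuple[float, float]:
        a = (lo - loc) / scale
        b = (hi - loc) / scale
        with _warnings.catch_warnings(), np.errstate(all="ignore"):
            _warnings.simplefilter("ignore")
            m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), float(np.sqrt(max(0.0, float(v))))

    span = hi - lo

    def loc_for_mean(scale: float) -> float:
        # the truncated mean varies slowly in loc once truncation dominates
        # (offsets ~ scale^2 matter), so expand the bracket geometrically
        off = scale + span
        lo_b, hi_b = lo - off, hi + off
        for _ in range(60):
            if (moments(lo_b, scale)[0] - mean) * (moments(hi_b, scale)[0] - mean) <= 0:
                break
            off *= 3.0
            lo_b, hi_b = lo - off, hi + off
        else:
            raise ValueError(
                f"infeasible truncation bounds: cannot reach mean={mean} on [{lo}, {hi}]"
            )
        return float(optimize.brentq(
            lambda loc: moments(loc, scale)[0] - mean, lo_b, hi_b, xtol=1e-10
        ))

    def sd_err(log_scale: float) -> float:
        s = float(np.exp(log_scale))
        return moments(loc_for_mean(s), s)[1] - sd

    # walk the mean-matched path in scale; pick the scale matching the SD,
    # or the closest achievable one
    log_grid = np.linspace(np.log(span / 2000.0), np.log(2.0 * span), 40)
    errs = np.asarray([sd_err(ls) for ls in log_grid])
    cross = np.nonzero(np.diff(np.sign(errs)) != 0)[0]
    if len(cross):
        i = int(cross[0])
        ls_star = float(optimize.brentq(sd_err, log_grid[i], log_grid[i + 1], xtol=1e-10))
    else:
        ls_star = float(log_grid[int(np.argmin(np.abs(errs)))])
    scale = float(np.exp(ls_star))
    return loc_for_mean(scale), scale


def _draw_nap_minutes(params: CohortParams, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Nap lengths: matched truncated-normal marginal, age-linked by copula.

    The marginal is the truncated normal with post-truncation moments matched
    to (nap_mean_min, nap_sd_min) on [nap_min_min, nap_max_min]. The
    age-duration dependence is planted through a Gaussian copula whose
    correlation is the latent-scale value of ``nap_age_corr_slope`` minutes
    per month, rho = slope * sd(age) / nap_sd; this keeps the marginal exact
    for every subject, which a per-subject location shift would not under
    truncation.
    """
    lo, hi = params.nap_min_min, params.nap_max_min
    age_lo, age_hi = params.age_months_range
    age_sd = (age_hi - age_lo) / np.sqrt(12.0)
    if params.nap_sd_min == 0:
        shift = params.nap_age_corr_slope * (ages - 0.5 * (age_lo + age_hi))
        return np.clip(params.nap_mean_min + shift, lo, hi)
    loc, scale = _matched_parent(params.nap_mean_min, params.nap_sd_min, lo, hi)
    rho = params.nap_age_corr_slope * age_sd / params.nap_sd_min
    rho = float(np.clip(rho, -0.99, 0.99))
    z_age = stats.norm.ppf((ages - age_lo) / (age_hi - age_lo))
    z = rho * z_age + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(ages))
    u = stats.norm.cdf(z)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def generate_cohort(params: CohortParams | None = None) -> tuple[PairedDataset, CohortTruth]:
    """Generate one cohort plus its hidden truth record.

    Identical parameters (including the seed) give byte-identical output.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    width = max(3, len(str(n)))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    ages = rng.uniform(*params.age_months_range, size=n)
    naps = _draw_nap_minutes(params, ages, rng)
    m = np.maximum(1, np.rint(naps).astype(int))
    b = rng.normal(0.0, params.between_subject_sd_bpm, size=n)
    periods = rng.uniform(*DRIFT_PERIOD_MIN, size=n)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)

    frames = []
    for i, sid in enumerate(subject_ids):
        t = np.arange(m[i], dtype=float)
        true_rate = (
            params.baseline_intercept_bpm
            + params.baseline_age_slope_bpm_per_month * ages[i]
            + DRIFT_AMPLITUDE_BPM * np.sin(2.0 * np.pi * t / periods[i] + phases[i])
        )
        e = rng.normal(0.0, params.within_subject_sd_bpm, size=m[i])
        d = params.bias_bpm + b[i] + e
        bpm_test = true_rate + rng.normal(0.0, params.ref_measurement_sd_bpm, size=m[i])
        bpm_ref = bpm_test + d
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "epoch_start": _EPOCH0 + pd.to_timedelta(t, unit="min"),
                    "bpm_ref": bpm_ref,
                    "bpm_test": bpm_test,
                }
            )
        )
    epochs = pd.concat(frames, ignore_index=True)
    N = len(epochs)

    # artifact categories: mutually exclusive per epoch
    v = rng.random(N)
    p_b, p_r, p_t = params.p_both_artifact, params.p_ref_artifact, params.p_test_artifact
    is_both = v < p_b
    is_ref = (v >= p_b) & (v < p_b + p_r)
    is_test = (v >= p_b + p_r) & (v < p_b + p_r + p_t)
    test_bad = is_both | is_test
    usable_clean = rng.integers(30, 61, size=N)
    usable_bad = rng.integers(0, 30, size=N)
    epochs["ref_artifact"] = is_both | is_ref
    epochs["test_usable_seconds"] = np.where(test_bad, usable_bad, usable_clean).astype("int64")

    # extreme reference outliers on otherwise clean epochs
    w_out = rng.random(N)
    is_outlier = (w_out < params.p_ref_outlier) & ~(is_both | is_ref | is_test)
    if is_outlier.any():
        pooled_mean = float(epochs["bpm_ref"].mean())
        pooled_sd = float(epochs["bpm_ref"].std(ddof=1))
        epochs.loc[is_outlier, "bpm_ref"] = (
            pooled_mean + params.outlier_shift_sd_units * pooled_sd
        )

    epochs = epochs[EPOCH_COLUMNS]
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age_months": ages,
            "nap_duration_min": m.astype(float),
        },
        columns=SUBJECT_COLUMNS,
    )
    data = PairedDataset(epochs, subjects).sort().validate()
    truth = CohortTruth(
        params=params,
        subject_ids=subject_ids,
        ages_months=ages,
        nap_minutes=naps,
        subject_effects=b,
        is_ref_artifact=is_ref,
        is_test_artifact=is_test,
        is_both_artifact=is_both,
        is_outlier=is_outlier,
    )
    return data, truth


def study_like_cohort(seed: int = 0) -> PairedDataset:
    """Convenience preset: 33 subjects at default parameters."""
    return generate_cohort(CohortParams(seed=seed))[0]
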