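"""Agreement statistics for paired per-minute respiratory-rate streams.

The analysis works on per-epoch difference scores

    d = bpm_ref - bpm_test        (breaths per minute)

and summarises device agreement with

* the mean absolute error (MAE) of d, with a subject-level cluster-bootstrap
  confidence interval (respects within-subject dependence);
* the repeated-measures correlation r_rm — the common within-subject
  association of the two devices, from an ANCOVA with subject-specific
  intercepts and a single common slope;
* repeated-measures Bland-Altman limits of agreement. Because each subject
  contributes many epochs, the SD of the differences combines a
  within-subject and a between-subject variance component estimated from a
  one-way ANOVA of d on subject:

      MS_W = sum_ij (d_ij - dbar_i)^2 / (N - n)         sigma2_W = MS_W
      MS_B = sum_i m_i (dbar_i - dbar)^2 / (n - 1)
      sigma2_B = (MS_B - MS_W) / divisor
      divisor  = ((sum_i m_i)^2 - sum_i m_i^2) / ((n - 1) sum_i m_i)
      SD_d     = sqrt(sigma2_B + sigma2_W)

  with limits of agreement  mean(d) +/- 1.96 * SD_d. In a balanced design
  (m_i = m for all i) the divisor reduces to m exactly.
* moderator checks: Pearson correlations of per-subject mean differences
  with age and with nap duration.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import PairedDataset
from .screening import ScreeningResult, screen_artifacts, screen_outliers

#: LOA multiplier as conventionally printed; override via AnalysisConfig.
LOA_MULTIPLIER = 1.96


class ZeroWithinVarianceError(ValueError):
    """The reference stream has no within-subject variance; r_rm undefined."""


class PipelineStageError(RuntimeError):
    """Wraps a failure inside run_agreement with the failing stage's name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


# ---------------------------------------------------------------------------
# difference scores
# ---------------------------------------------------------------------------

@dataclass
class DifferenceSeries:
    """Per-epoch difference d = bpm_ref - bpm_test and two-device average."""

    subject_id: np.ndarray
    d: np.ndarray
    avg: np.ndarray

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.d = np.asarray(self.d, dtype=float)
        self.avg = np.asarray(self.avg, dtype=float)
        if not (len(self.subject_id) == len(self.d) == len(self.avg)):
            raise ValueError("subject_id, d and avg must have equal length")
        if len(self.d) and not np.isfinite(self.d).all():
            raise ValueError("difference scores must be finite; screen missing bpm first")

    @property
    def n(self) -> int:
        return len(self.d)

    def per_subject_means(self) -> pd.Series:
        return pd.Series(self.d).groupby(pd.Series(self.subject_id)).mean()


def difference_series(data: PairedDataset) -> DifferenceSeries:
    """Compute d and the Bland-Altman abscissa for every epoch, in order."""
    ep = data.epochs
    ref = ep["bpm_ref"].to_numpy(dtype=float)
    test = ep["bpm_test"].to_numpy(dtype=float)
    return DifferenceSeries(
        subject_id=ep["subject_id"].to_numpy(dtype=object),
        d=ref - test,
        avg=(ref + test) / 2.0,
    )


# ---------------------------------------------------------------------------
# mean absolute error with cluster-bootstrap CI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaeResult:
    mae: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int


def mean_absolute_error(diffs: DifferenceSeries, n_boot: int = 10_000, seed: int = 0) -> MaeResult:
    """MAE of the difference scores with a percentile bootstrap CI.

    Subjects (clusters) are resampled with replacement so the interval
    respects within-subject dependence. With a single subject the CI is
    undefined and returned as NaN.
    """
    if diffs.n == 0:
        raise ValueError("mean_absolute_error needs a nonempty series")
    if 0 < n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable", stacklevel=2)
    absd = np.abs(diffs.d)
    mae = float(absd.mean())
    groups = pd.Series(absd).groupby(pd.Series(diffs.subject_id))
    sums = groups.sum().to_numpy()
    counts = groups.size().to_numpy().astype(float)
    n_subj = len(sums)
    if n_subj < 2 or n_boot == 0:
        return MaeResult(mae, float("nan"), float("nan"), n_boot, seed)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MaeResult(mae, float(lo), float(hi), n_boot, seed)


# ---------------------------------------------------------------------------
# repeated-measures correlation (ANCOVA definition)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmCorrResult:
    r: float
    ci_lower: float
    ci_upper: float
    df: int
    p_value: float
    slope: float
    n_subjects: int
    n_obs: int


def rm_correlation(data: PairedDataset) -> RmCorrResult:
    """Repeated-measures correlation of the two device streams.

    Fits bpm_test ~ subject intercepts + common slope * bpm_ref (equivalently
    on within-subject-centred values), and returns

        r_rm = sign(slope) * sqrt(SS_measure / (SS_measure + SS_error))

    with error degrees of freedom N - n - 1, a two-sided p-value from the t
    statistic of the common slope, and a Fisher-z confidence interval using
    those degrees of freedom. Subjects with fewer than two epochs carry no
    within-subject information and are dropped with a warning.
    """
    ep = data.epochs.dropna(subset=["bpm_ref", "bpm_test"])
    sizes = ep.groupby("subject_id")["bpm_ref"].transform("size")
    if (sizes < 2).any():
        dropped = sorted(ep.loc[sizes < 2, "subject_id"].unique())
        warnings.warn(f"rm_correlation: dropping subjects with < 2 epochs: {dropped}")
        ep = ep.loc[sizes >= 2]
    n_subj = ep["subject_id"].nunique()
    n_obs = len(ep)
    if n_subj < 2:
        raise ValueError("rm_correlation needs >= 2 subjects with >= 2 epochs each")

    g = ep.groupby("subject_id")
    x = (ep["bpm_ref"] - g["bpm_ref"].transform("mean")).to_numpy()
    y = (ep["bpm_test"] - g["bpm_test"].transform("mean")).to_numpy()
    sxx = float(x @ x)
    if sxx <= 0.0:
        raise ZeroWithinVarianceError("bpm_ref has zero within-subject variance")
    sxy = float(x @ y)
    syy = float(y @ y)
    slope = sxy / sxx
    ss_measure = sxy * sxy / sxx
    ss_error = syy - ss_measure
    df = n_obs - n_subj - 1
    if df <= 0:
        raise ValueError("not enough error degrees of freedom (N - n - 1 <= 0)")
    if syy <= 0.0:
        # test stream constant within subjects: association undefined -> 0
        r = 0.0
    else:
        r = math.copysign(math.sqrt(ss_measure / (ss_measure + ss_error)), slope)

    if ss_error <= 1e-12 * max(syy, 1.0):
        # perfect common-slope fit
        return RmCorrResult(r, r, r, df, 0.0, slope, n_subj, n_obs)
    se_slope = math.sqrt((ss_error / df) / sxx)
    tstat = slope / se_slope
    p = 2.0 * stats.t.sf(abs(tstat), df)
    if df > 1:
        zr = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
        half = stats.norm.ppf(0.975) / math.sqrt(df - 1)
        ci = (math.tanh(zr - half), math.tanh(zr + half))
    else:
        ci = (float("nan"), float("nan"))
    return RmCorrResult(float(r), ci[0], ci[1], df, float(p), float(slope), n_subj, n_obs)


# ---------------------------------------------------------------------------
# variance components and limits of agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    ms_within: float
    ms_between: float
    sigma2_within: float
    sigma2_between: float
    sigma2_between_raw: float  # before truncation at zero
    divisor: float
    sd_d: float


def variance_components(diffs: DifferenceSeries) -> VarianceComponents:
    """One-way ANOVA (d ~ subject) moment estimates of sigma2_W, sigma2_B.

    Raises when every subject contributes a single epoch (N = n): the
    within-subject mean square is then undefined and classical
    (non-repeated) limits of agreement should be used instead.
    """
    s = pd.Series(diffs.d)
    by = pd.Series(diffs.subject_id)
    groups = s.groupby(by)
    m = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    n = len(m)
    N = int(m.sum())
    if n < 2:
        raise ValueError("variance_components needs >= 2 subjects")
    if N == n:
        raise ValueError(
            "one epoch per subject (N == n): MS_W undefined; use classical "
            "(non-repeated) limits of agreement"
        )
    grand = float(s.mean())
    ss_within = float(((s - groups.transform("mean")) ** 2).sum())
    ms_within = ss_within / (N - n)
    ms_between = float((m * (means - grand) ** 2).sum()) / (n - 1)
    divisor = (N**2 - float((m**2).sum())) / ((n - 1) * N)
    sigma2_between_raw = (ms_between - ms_within) / divisor
    sigma2_between = max(0.0, sigma2_between_raw)
    sd_d = math.sqrt(sigma2_between + ms_within)
    return VarianceComponents(
        ms_within=ms_within,
        ms_between=ms_between,
        sigma2_within=ms_within,
        sigma2_between=sigma2_between,
        sigma2_between_raw=sigma2_between_raw,
        divisor=divisor,
        sd_d=sd_d,
    )


def loa_from_moments(
    mean_d: float, sd_d: float, multiplier: float = LOA_MULTIPLIER
) -> tuple[float, float]:
    """Limits of agreement mean_d -/+ multiplier * sd_d."""
    if sd_d < 0:
        raise ValueError("sd_d must be nonnegative")
    return (mean_d - multiplier * sd_d, mean_d + multiplier * sd_d)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_d: float
    components: VarianceComponents
    loa_lower: float
    loa_upper: float
    pct_within: float
    loa_multiplier: float
    weighting: str


def bland_altman(
    diffs: DifferenceSeries,
    loa_multiplier: float = LOA_MULTIPLIER,
    weighting: str = "epoch",
) -> BlandAltmanResult:
    """Repeated-measures Bland-Altman summary.

    ``mean_d`` is the grand mean over all epochs (every minute weighted
    equally, matching how every pair is plotted); ``weighting='subject'``
    averages the per-subject means instead. ``pct_within`` counts epochs in
    the closed interval [loa_lower, loa_upper].
    """
    comps = variance_components(diffs)
    if weighting == "epoch":
        mean_d = float(diffs.d.mean())
    elif weighting == "subject":
        mean_d = float(diffs.per_subject_means().mean())
    else:
        raise ValueError("weighting must be 'epoch' or 'subject'")
    lo, hi = loa_from_moments(mean_d, comps.sd_d, loa_multiplier)
    within = (diffs.d >= lo) & (diffs.d <= hi)
    return BlandAltmanResult(
        mean_d=mean_d,
        components=comps,
        loa_lower=lo,
        loa_upper=hi,
        pct_within=100.0 * float(within.mean()),
        loa_multiplier=loa_multiplier,
        weighting=weighting,
    )


# ---------------------------------------------------------------------------
# moderators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeratorResult:
    subject_ids: tuple[str, ...]
    mean_d_by_subject: tuple[float, ...]
    r_age: float | None
    r_nap: float | None
    r_nap_age: float | None
    degenerate: bool


def moderators(data: PairedDataset, diffs: DifferenceSeries) -> ModeratorResult:
    """Correlate per-subject mean differences with age and nap duration.

    Subjects missing a covariate are excluded with a warning. When the
    per-subject means (or a covariate) have zero variance the corresponding
    correlation is undefined and returned as None with ``degenerate=True``.
    """
    dbar = diffs.per_subject_means().rename("mean_d").reset_index()
    dbar.columns = ["subject_id", "mean_d"]
    merged = dbar.merge(data.subjects, on="subject_id", how="left")
    missing = merged["age_months"].isna() | merged["nap_duration_min"].isna()
    if missing.any():
        warnings.warn(
            f"moderators: excluding subjects without covariates: "
            f"{sorted(merged.loc[missing, 'subject_id'])}"
        )
        merged = merged.loc[~missing]
    if len(merged) < 3:
        raise ValueError("moderators need >= 3 subjects with covariates")

    def _safe_r(a: pd.Series, b: pd.Series) -> float | None:
        if a.nunique() < 2 or b.nunique() < 2:
            return None
        return float(stats.pearsonr(a.to_numpy(), b.to_numpy())[0])

    r_age = _safe_r(merged["mean_d"], merged["age_months"])
    r_nap = _safe_r(merged["mean_d"], merged["nap_duration_min"])
    r_nap_age = _safe_r(merged["nap_duration_min"], merged["age_months"])
    return ModeratorResult(
        subject_ids=tuple(merged["subject_id"]),
        mean_d_by_subject=tuple(float(v) for v in merged["mean_d"]),
        r_age=r_age,
        r_nap=r_nap,
        r_nap_age=r_nap_age,
        degenerate=any(v is None for v in (r_age, r_nap, r_nap_age)),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    mae: MaeResult
    rm_corr: RmCorrResult | None
    bland_altman: BlandAltmanResult
    moderators: ModeratorResult | None


@dataclass
class RunReport:
    """Machine-readable record of one full agreement run."""

    config: AnalysisConfig
    artifact_screening: ScreeningResult
    outlier_screening: ScreeningResult
    agreement: AgreementResult
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def scr(s: ScreeningResult) -> dict:
            return {
                "n_input": s.n_input,
                "n_retained": s.retained.n_epochs,
                "n_rejected_ref_artifact": s.n_rejected_ref_artifact,
                "n_rejected_test_artifact": s.n_rejected_test_artifact,
                "n_rejected_both": s.n_rejected_both,
                "n_rejected_outlier": s.n_rejected_outlier,
                "fractions": s.fractions,
                "thresholds": s.thresholds,
            }

        a = self.agreement
        out = {
            "config": self.config.to_dict(),
            "screening": {"artifacts": scr(self.artifact_screening),
                          "outliers": scr(self.outlier_screening)},
            "mae": {
                "value": a.mae.mae,
                "ci_lower": a.mae.ci_lower,
                "ci_upper": a.mae.ci_upper,
                "n_boot": a.mae.n_boot,
                "seed": a.mae.seed,
            },
            "bland_altman": {
                "mean_d": a.bland_altman.mean_d,
                "sd_d": a.bland_altman.components.sd_d,
                "loa_lower": a.bland_altman.loa_lower,
                "loa_upper": a.bland_altman.loa_upper,
                "pct_within": a.bland_altman.pct_within,
                "loa_multiplier": a.bland_altman.loa_multiplier,
                "weighting": a.bland_altman.weighting,
                "variance_components": {
                    "ms_within": a.bland_altman.components.ms_within,
                    "ms_between": a.bland_altman.components.ms_between,
                    "sigma2_within": a.bland_altman.components.sigma2_within,
                    "sigma2_between": a.bland_altman.components.sigma2_between,
                    "sigma2_between_raw": a.bland_altman.components.sigma2_between_raw,
                    "divisor": a.bland_altman.components.divisor,
                },
            },
            "warnings": list(self.warnings_),
        }
        out["rm_correlation"] = (
            None
            if a.rm_corr is None
            else {
                "r": a.rm_corr.r,
                "ci_lower": a.rm_corr.ci_lower,
                "ci_upper": a.rm_corr.ci_upper,
                "df": a.rm_corr.df,
                "p_value": a.rm_corr.p_value,
                "slope": a.rm_corr.slope,
                "n_subjects": a.rm_corr.n_subjects,
                "n_obs": a.rm_corr.n_obs,
            }
        )
        out["moderators"] = (
            None
            if a.moderators is None
            else {
                "r_age": a.moderators.r_age,
                "r_nap_duration": a.moderators.r_nap,
                "r_nap_duration_age": a.moderators.r_nap_age,
                "degenerate": a.moderators.degenerate,
                "n_subjects": len(a.moderators.subject_ids),
            }
        )
        return out

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, float) and not math.isfinite(obj):
                return None
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return json.dumps(_clean(self.to_dict()), sort_keys=True, indent=2)


def run_agreement(
    data: PairedDataset,
    config: AnalysisConfig | None = None,
    n_boot: int | None = None,
    seed: int | None = None,
) -> RunReport:
    """Screen, difference, and summarise a paired dataset end to end.

    Stages: artifact screening -> outlier screening -> difference scores ->
    {MAE, repeated-measures correlation, Bland-Altman, moderators}. Any stage
    failure aborts with the stage named. ``n_boot``/``seed`` override the
    corresponding config entries. The moderator stage is skipped (None) when
    covariates are absent rather than failing the run.
    """
    config = config or AnalysisConfig()
    if n_boot is not None or seed is not None:
        cfg = config.to_dict()
        if n_boot is not None:
            cfg["n_boot"] = n_boot
        if seed is not None:
            cfg["seed"] = seed
        config = AnalysisConfig(**cfg)

    caught: list[str] = []

    def _stage(name: str, fn, *args, **kwargs):
        try:
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                result = fn(*args, **kwargs)
            caught.extend(f"{name}: {w.message}" for w in wrec)
            return result
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    art = _stage("screen_artifacts", screen_artifacts, data, config.screening)
    out = _stage(
        "screen_outliers",
        screen_outliers,
        art.retained,
        config.screening,
        frozenset(config.outlier_streams),
    )
    diffs = _stage("difference_series", difference_series, out.retained)
    mae = _stage("mean_absolute_error", mean_absolute_error, diffs, config.n_boot, config.seed)
    try:
        rm = _stage("rm_correlation", rm_correlation, out.retained)
    except PipelineStageError as exc:
        if isinstance(exc.__cause__, ZeroWithinVarianceError):
            rm = None
            caught.append(f"rm_correlation: {exc.__cause__}")
        else:
            raise
    ba = _stage("bland_altman", bland_altman, diffs, config.loa_multiplier, config.weighting)
    have_covariates = not (
        data.subjects[["age_months", "nap_duration_min"]].isna().all().all()
    )
    mods = (
        _stage("moderators", moderators, out.retained, diffs) if have_covariates else None
    )
    return RunReport(
        config=config,
        artifact_screening=art,
        outlier_screening=out,
        agreement=AgreementResult(mae=mae, rm_corr=rm, bland_altman=ba, moderators=mods),
        warnings_=caught,
    )
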