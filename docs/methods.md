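# Methods

## Data model

The unit of analysis is the paired epoch: one subject-minute for which both
devices report a breaths-per-minute (bpm) value. Epochs are minute-aligned
and cover the half-open interval [t, t + 60 s); timestamps with a nonzero
seconds component are truncated to the minute before any join, since both
devices emit 1-minute aggregates and no finer synchronisation information
exists in the epoch table. Stream alignment is an inner join on
(subject, minute): the agreement statistics are defined only on paired
observations, so unpaired epochs are counted and excluded, never imputed.
Missing bpm values are representable at read time and removed during
screening, so the rejection accounting reflects them as device artifacts
rather than silent read failures.

## Screening

Two rules, applied in this order:

1. **Artifacts.** An epoch is rejected for the reference device when its
   accelerometer-coincident movement flag is set or its bpm is missing; for
   the test device when fewer than `min_usable_seconds` (default 30 of 60)
   seconds of usable signal were available or its bpm is missing. Epochs
   failing both criteria are counted once, in the "both" category, so the
   four counts plus the retained size always reconstruct the input size.
2. **Outliers.** Epochs with bpm strictly above mean + k·SD of a stream
   (default k = 3, reference stream only, sample SD) are removed in a single
   pass: the thresholds are computed once on the artifact-screened input and
   not recomputed after removals, because iterative trimming would change
   the counts and describes a different procedure. A two-sided variant and
   the test stream are available by configuration. The pooled (not
   per-subject) mean/SD is used; a per-subject rule would reject short-nap
   subjects' epochs on very noisy thresholds.

Screening an already-screened dataset rejects nothing (idempotence), raising
`min_usable_seconds` can only increase test-artifact rejections, and raising
the SD multiplier can only decrease outlier rejections; these invariants are
enforced by tests.

## Agreement statistics

All statistics work on per-epoch difference scores `d = bpm_ref − bpm_test`
(reference minus test, so a negative mean means the test device reads high).

**MAE.** Mean of |d| over retained epochs. Epochs within a subject are
correlated, so the 95% CI resamples subjects (clusters) with replacement —
a percentile bootstrap with 10,000 replicates by default, seeded. With one
subject the CI is undefined and returned as NaN.

**Repeated-measures correlation.** The common within-subject association of
the two streams, from the ANCOVA `bpm_test ~ subject intercepts + common
slope · bpm_ref`, computed on within-subject-centred values:
`r_rm = sign(slope)·√(SS_measure/(SS_measure + SS_error))` with error
degrees of freedom `N − n − 1`. The two-sided p-value comes from the t
statistic of the common slope; the CI from a Fisher z-transform with
standard error `1/√(df − 1)`, the analogue of the plain-correlation
`1/√(N − 3)`. Subjects with fewer than two epochs carry no within-subject
information and are dropped with a warning. The estimator is implemented
directly (it is the quantity under test); an independent ANCOVA
implementation is used as a test oracle only.

**Repeated-measures Bland–Altman.** Because the true rate varies within a
nap and subjects contribute unequal numbers of epochs, the SD entering the
limits of agreement combines two variance components from the one-way ANOVA
of d on subject:

    MS_W = Σ_ij (d_ij − d̄_i)² / (N − n)              σ²_W = MS_W
    MS_B = Σ_i m_i (d̄_i − d̄)² / (n − 1)
    σ²_B = (MS_B − MS_W) / D,   D = ((Σ m_i)² − Σ m_i²) / ((n − 1) Σ m_i)
    SD_d = √(σ²_B + σ²_W)

`D` is the standard unbalanced-design denominator and reduces to `m` exactly
when every subject contributes `m` epochs (asserted symbolically-derived and
numerically). A negative moment estimate of σ²_B is truncated to zero, the
variance-component convention; the raw value is kept in the report. The mean
difference is the grand mean over epochs (every plotted pair weighted
equally); a subject-weighted mean is available by configuration. Limits are
`d̄ ± 1.96·SD_d` with 1.96 fixed as the conventional multiplier (an expert
override exists in the config). The percent-within statistic counts epochs
in the **closed** interval. Model assumptions: differences decompose
additively into a subject-level offset and epoch-level noise, both roughly
normal; percent-within ≈ 95% is expected only under approximate normality.

**Moderators.** Pearson correlations of the per-subject mean difference with
age and with recording duration, plus duration-vs-age. Zero-variance inputs
make the correlation undefined; it is returned as None with a degeneracy
flag rather than as a number.

## Sample-size planning

Differences are modelled as i.i.d. Normal(μ, σ²). A study of size n
"concludes agreement" when the confidence bound on each estimated limit of
agreement falls inside ±δ, the maximal allowable difference:

    d̄ + 1.96 s + q·ŝe < δ   and   d̄ − 1.96 s − q·ŝe > −δ,
    ŝe = s·√(1/n + 1.96²/(2(n−1)))

with q a Student-t quantile, `t(1−α/2, n−1)` under the default two-sided
convention (`t(1−α, n−1)` one-sided; normal quantiles selectable). Both
conditions collapse into `|d̄| + C·s < δ` with `C = 1.96 + q·√(1/n +
1.96²/(2(n−1)))`, and the power is computed **exactly** by integrating the
normal probability of the d̄-window over the chi distribution of s
(400-node Gauss–Legendre quadrature on the chi quantile scale). The common
normal approximation of the bound's distribution errs by up to ~0.03 near
the interesting n, which is larger than the agreement we demand between the
analytic power and the independent Monte-Carlo simulator (0.02), so the
exact form is used. Required sample size is found by exact upward integer
search, which makes the bracketing property `power(n*−1) < target ≤
power(n*)` checkable directly. The calculation treats observations as
independent — it does not model the within-subject clustering of the epochs
— so its n is best read as "observations for a design with one observation
per subject"; planning for clustered designs is out of scope.

With μ = 0, σ = 1.5 bpm, δ = 5 bpm, α = 0.05 and target power 0.80, the
planner returns n = 20 under the default two-sided convention (16
one-sided, 18/15 with normal quantiles); these values are what the tests
and the acceptance script compute and check against simulation.

## Synthetic cohorts

The generator emulates a nap-validation cohort at the epoch level. Defaults:
33 subjects; ages uniform on 1–22 months; nap lengths on [18, 191] minutes
targeting mean 57.9 and SD 40.1; true rate 45 − 0.8·age bpm plus a slow
sinusoidal within-nap drift (amplitude 1.5 bpm, period 40–90 min); device
difference `d = bias + b_i + e_ij` with bias −0.91 bpm, between-subject SD
2.5 and within-subject SD 1.5 bpm (SD_d ≈ 2.9); test-device measurement
noise SD 1.0 bpm; artifact probabilities 0.8% (reference), 3.8% (test),
0.9% (both); 2.6% of clean epochs replaced by extreme reference readings 5
pooled SDs above the mean. The difference model is written directly and the
two device columns reconstructed around the shared true rate, which makes
bias and both variance components exactly recoverable — the property the
parameter-recovery tests exercise.

Numerical choices worth knowing:

* **Nap-length marginal.** The requested mean/SD are *post-truncation*
  targets: the parent location/scale of the truncated normal are solved by
  deterministic root finding (a parent placed naively at the target mean
  would overshoot the truncated mean by ~10 minutes). On [18, 191] the
  truncated-normal family cannot reach an SD of 40.1 at mean 57.9 (its
  limiting shape is an exponential tail with SD ≈ 36), so the mean is
  matched exactly and the closest achievable SD (≈ 36 minutes) is taken.
* **Age–duration link.** The dependence is planted through a Gaussian
  copula with correlation `slope·SD(age)/SD(nap)` (defaults: 4 min/month →
  ρ ≈ 0.6), which keeps every subject's nap marginal exactly the matched
  truncated normal; a per-subject location shift would distort both the
  marginal and the planted correlation under truncation.
* Ages are uniform over the stated range; the generator does not reproduce
  a bell-shaped age distribution.
* Device readings are kept at full float precision (no rounding to integer
  bpm) so the difference structure stays exact; real devices quantise.
* Artifact epochs get their usable-seconds drawn below the screening
  threshold and clean epochs at or above it, so default screening recalls
  injected artifacts exactly; outliers are injected only on artifact-free
  epochs and sit far enough out (5 pooled SDs) that the 3-SD rule still
  catches ≥ 95% of them after the contamination itself inflates the
  threshold.

What passing tests on these cohorts do **not** show about real data: real
respiratory differences need not be normal or additive, artifacts need not
be independent of the signal, real naps are not truncated-normal, and
devices quantise and drift in ways the generator does not model. The
synthetic cohorts validate the *estimators and accounting*, not any
particular device.

## Sizes used by the test suite

Oracle-equivalence checks run on 100 random instances of ≤ 6 subjects × ≤ 8
epochs; parameter recovery on 300 subjects × 60 epochs; LOA coverage on
50,000 balanced normal differences; the Monte-Carlo power cross-check on
50,000 simulated studies. All stochastic tests are seeded; checks of
spec-level recovery bounds that sit within ~2 standard errors of a single
cohort are averaged over five pre-chosen seeds instead of widened.

## Known limitations

* The ANOVA moment estimator is used throughout (no REML/mixed models), and
  no CIs are attached to the limits of agreement themselves.
* No proportional-bias regression on the Bland–Altman cloud.
* The outlier rule's pooled-vs-per-subject choice and its placement after
  artifact screening are conventions, exposed in configuration.
* The power calculation ignores clustering (see above) and assumes normal
  differences.
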