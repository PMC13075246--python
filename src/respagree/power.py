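"""Sample-size planning for a Bland-Altman agreement study.

Differences between the two devices are modelled as i.i.d. Normal(mu,
sigma^2). A study of size n "concludes agreement" when the confidence bound
on each estimated 95% limit of agreement falls inside the clinically
tolerable band +/- delta:

    dbar + 1.96 s + q * se_hat < delta    and
    dbar - 1.96 s - q * se_hat > -delta,

where s is the sample SD, the limit's standard error uses the standard
large-sample term

    se_hat = s * sqrt(1/n + 1.96^2 / (2 (n - 1))),

and q is a Student-t quantile of the confidence bound: t_{1-alpha/2, n-1}
under the default two-sided convention, t_{1-alpha, n-1} under the
one-sided convention (normal quantiles available via ``critical='z'``).

Both one-sided conditions combine into the single event
|dbar| + C s < delta with C = 1.96 + q sqrt(1/n + 1.96^2/(2(n-1))), whose
probability is computed exactly by integrating the normal probability of
dbar's window over the chi distribution of s (Gauss-Legendre quadrature).
A Monte-Carlo simulator of whole studies is provided as an independent
cross-check of the analytic power.

Required sample size is the smallest integer n with power at or above the
target, found by exact upward search so the bracketing property
power(n*-1) < target <= power(n*) holds by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .agreement import LOA_MULTIPLIER

_QUAD_NODES = 400


class InfeasibleSpecError(RuntimeError):
    """No n up to the search cap reaches the target power."""


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the agreement power calculation (all in bpm)."""

    expected_mean_diff: float
    expected_sd: float
    max_allowable_diff: float
    alpha: float = 0.05
    target_power: float = 0.80
    alpha_sided: Literal["two_sided", "one_sided"] = "two_sided"
    critical: Literal["t", "z"] = "t"
    loa_multiplier: float = LOA_MULTIPLIER

    def __post_init__(self) -> None:
        if not self.expected_sd > 0:
            raise ValueError("expected_sd must be positive")
        if not self.max_allowable_diff > 0:
            raise ValueError("max_allowable_diff must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.alpha_sided not in ("two_sided", "one_sided"):
            raise ValueError("alpha_sided must be 'two_sided' or 'one_sided'")
        if self.critical not in ("t", "z"):
            raise ValueError("critical must be 't' or 'z'")


@dataclass(frozen=True)
class SampleSizeResult:
    n_required: int
    achieved_power: float
    power_curve: tuple[tuple[int, float], ...]


def _critical_quantile(n: int, spec: SampleSizeSpec) -> float:
    p = 1.0 - (spec.alpha / 2.0 if spec.alpha_sided == "two_sided" else spec.alpha)
    if spec.critical == "t":
        return float(stats.t.ppf(p, n - 1))
    return float(stats.norm.ppf(p))


def _bound_constant(n: int, spec: SampleSizeSpec) -> float:
    """C such that the agreement conclusion is |dbar| + C*s < delta."""
    z = spec.loa_multiplier
    q = _critical_quantile(n, spec)
    return z + q * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))


def agreement_power(n: int, spec: SampleSizeSpec) -> float:
    """Exact probability that a study of size n concludes agreement."""
    if n < 3:
        raise ValueError("agreement_power requires n >= 3")
    mu, sigma, delta = spec.expected_mean_diff, spec.expected_sd, spec.max_allowable_diff
    C = _bound_constant(n, spec)
    nu = n - 1
    # integrate over s = sigma * sqrt(chi2_nu / nu) via Gauss-Legendre on (0,1)
    u, w = np.polynomial.legendre.leggauss(_QUAD_NODES)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    s = sigma * np.sqrt(stats.chi2.ppf(u, nu) / nu)
    root_n = np.sqrt(n)
    hi = (delta - C * s - mu) * root_n / sigma
    lo = (-delta + C * s - mu) * root_n / sigma
    p = np.clip(stats.norm.cdf(hi) - stats.norm.cdf(lo), 0.0, None)
    power = float(np.sum(w * p))
    if not np.isfinite(power):
        raise ArithmeticError(f"power not finite at n={n}")
    return min(1.0, max(0.0, power))


def simulate_agreement_power(
    n: int, spec: SampleSizeSpec, n_sims: int = 50_000, seed: int = 0
) -> float:
    """Monte-Carlo power: simulate whole studies and apply the conclusion rule.

    Independent of :func:`agreement_power` — each replicate draws n
    differences, computes the limits of agreement and their confidence
    bounds, and tests them against +/- delta.
    """
    if n < 3:
        raise ValueError("simulate_agreement_power requires n >= 3")
    mu, sigma, delta = spec.expected_mean_diff, spec.expected_sd, spec.max_allowable_diff
    z = spec.loa_multiplier
    q = _critical_quantile(n, spec)
    rng = np.random.default_rng(seed)
    ok = 0
    chunk = max(1, min(n_sims, int(5e7) // max(n, 1)))
    done = 0
    while done < n_sims:
        k = min(chunk, n_sims - done)
        d = rng.normal(mu, sigma, size=(k, n))
        m = d.mean(axis=1)
        s = d.std(axis=1, ddof=1)
        se = s * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
        upper_bound = m + z * s + q * se
        lower_bound = m - z * s - q * se
        ok += int(((upper_bound < delta) & (lower_bound > -delta)).sum())
        done += k
    return ok / n_sims


def required_sample_size(
    spec: SampleSizeSpec, n_max: int = 10_000, n_min: int = 3
) -> SampleSizeResult:
    """Smallest n whose agreement power reaches the target.

    Exact increasing integer search (no normal-approximation inversion), so
    the returned curve certifies minimality: power(n-1) < target <= power(n).
    """
    curve: list[tuple[int, float]] = []
    for n in range(n_min, n_max + 1):
        p = agreement_power(n, spec)
        curve.append((n, p))
        if p >= spec.target_power:
            return SampleSizeResult(n, p, tuple(curve))
    raise InfeasibleSpecError(
        f"no n <= {n_max} reaches power {spec.target_power}; "
        f"delta may be too close to the expected limit of agreement"
    )
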