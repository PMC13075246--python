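"""Artifact and outlier rejection of paired respiratory-rate epochs.

Two mechanisms invalidate an epoch before the agreement analysis:

* movement/technical artifacts — the reference device flags epochs whose
  apparent rate spikes coincide with accelerometer activity
  (``ref_artifact``); the test device flags epochs with fewer than
  ``min_usable_seconds`` (default 30) seconds of usable signal, e.g. when
  the patterned band is occluded. An epoch with a missing bpm on a device is
  treated as that device's technical artifact.
* statistical outliers — epochs whose bpm lies more than
  ``outlier_sd_multiplier`` (default 3) sample SDs above the stream mean.
  The rule is one-sided (upper) by default, applied in a single pass: the
  mean and SD are computed once on the input and not recomputed after
  removals. By default only the reference stream is screened.

Every rejected epoch is attributed to exactly one category, so the counts
plus the retained size always reconstruct the input size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PairedDataset

VALID_SIDES = ("upper", "two_sided")
VALID_STREAMS = ("ref", "test")


class DegenerateVarianceError(ValueError):
    """Outlier screening needs at least two epochs in a selected stream."""


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the rejection rules."""

    min_usable_seconds: int = 30
    outlier_sd_multiplier: float = 3.0
    outlier_sided: str = "upper"

    def __post_init__(self) -> None:
        if not 0 < self.min_usable_seconds <= 60:
            raise ValueError("min_usable_seconds must be in (0, 60]")
        if not self.outlier_sd_multiplier > 0:
            raise ValueError("outlier_sd_multiplier must be positive")
        if self.outlier_sided not in VALID_SIDES:
            raise ValueError(f"outlier_sided must be one of {VALID_SIDES}")


@dataclass
class ScreeningResult:
    """Retained dataset plus per-rule rejection accounting."""

    retained: PairedDataset
    n_input: int
    n_rejected_ref_artifact: int = 0
    n_rejected_test_artifact: int = 0
    n_rejected_both: int = 0
    n_rejected_outlier: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return (
            self.n_rejected_ref_artifact
            + self.n_rejected_test_artifact
            + self.n_rejected_both
            + self.n_rejected_outlier
        )

    @property
    def fractions(self) -> dict[str, float]:
        """Rejection counts as proportions of the input size."""
        n = self.n_input
        keys = (
            "n_rejected_ref_artifact",
            "n_rejected_test_artifact",
            "n_rejected_both",
            "n_rejected_outlier",
        )
        return {k: (getattr(self, k) / n if n else 0.0) for k in keys}

    def check_conservation(self) -> "ScreeningResult":
        if self.retained.n_epochs + self.n_rejected != self.n_input:
            raise AssertionError(
                f"screening accounting broken: retained {self.retained.n_epochs} "
                f"+ rejected {self.n_rejected} != input {self.n_input}"
            )
        return self


def screen_artifacts(data: PairedDataset, config: ScreeningConfig | None = None) -> ScreeningResult:
    """Reject movement/technical-artifact epochs, preserving input order.

    An epoch is reference-rejected iff its artifact flag is set or its
    reference bpm is missing; test-rejected iff ``test_usable_seconds`` is
    strictly below the threshold or its test bpm is missing; counted once
    under "both" when the two criteria fire together. An empty input yields
    an empty result with zero counts.
    """
    config = config or ScreeningConfig()
    ep = data.epochs
    ref_bad = ep["ref_artifact"].to_numpy(dtype=bool) | ep["bpm_ref"].isna().to_numpy()
    test_bad = (
        ep["test_usable_seconds"].to_numpy() < config.min_usable_seconds
    ) | ep["bpm_test"].isna().to_numpy()
    both = ref_bad & test_bad
    result = ScreeningResult(
        retained=data.subset(~(ref_bad | test_bad)),
        n_input=data.n_epochs,
        n_rejected_ref_artifact=int((ref_bad & ~both).sum()),
        n_rejected_test_artifact=int((test_bad & ~both).sum()),
        n_rejected_both=int(both.sum()),
    )
    return result.check_conservation()


def screen_outliers(
    data: PairedDataset,
    config: ScreeningConfig | None = None,
    streams: frozenset[str] | set[str] = frozenset({"ref"}),
) -> ScreeningResult:
    """Reject epochs beyond ``mean + k*SD`` of the selected bpm stream(s).

    Thresholds are computed once on the input (single pass, not recomputed
    after removals), with the sample SD (ddof=1). ``upper`` sidedness rejects
    only strictly-above-threshold epochs; ``two_sided`` also rejects below
    ``mean - k*SD``. Intended to run on artifact-screened data.
    """
    config = config or ScreeningConfig()
    bad_streams = set(streams) - set(VALID_STREAMS)
    if bad_streams:
        raise ValueError(f"unknown streams {sorted(bad_streams)}; valid: {VALID_STREAMS}")
    ep = data.epochs
    reject = np.zeros(len(ep), dtype=bool)
    thresholds: dict[str, dict[str, float]] = {}
    for stream in sorted(streams):
        col = f"bpm_{stream}"
        vals = ep[col].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < 2:
            raise DegenerateVarianceError(
                f"outlier screening on {col} needs >= 2 epochs with values"
            )
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1))
        hi = mean + config.outlier_sd_multiplier * sd
        lo = mean - config.outlier_sd_multiplier * sd
        mask = vals > hi
        if config.outlier_sided == "two_sided":
            mask |= vals < lo
        reject |= mask
        thresholds[stream] = {"mean": mean, "sd": sd, "upper": hi, "lower": lo}
    result = ScreeningResult(
        retained=data.subset(~reject),
        n_input=data.n_epochs,
        n_rejected_outlier=int(reject.sum()),
        thresholds=thresholds,
    )
    return result.check_conservation()
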