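"""Report figures: device scatter, Bland-Altman cloud, moderator panels."""
from __future__ import annotations

import numpy as np

from .agreement import BlandAltmanResult, DifferenceSeries, ModeratorResult
from .io import PairedDataset


def _subject_colors(ids):
    import matplotlib.pyplot as plt

    uniq = sorted(set(ids))
    cmap = plt.get_cmap("viridis", max(len(uniq), 2))
    lut = {s: cmap(i) for i, s in enumerate(uniq)}
    return [lut[s] for s in ids]


def scatter_devices(data: PairedDataset):
    """Per-epoch scatter of the two devices' bpm readings."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ep = data.epochs
    ax.scatter(ep["bpm_ref"], ep["bpm_test"], s=8, alpha=0.5,
               c=_subject_colors(ep["subject_id"]))
    lims = [
        np.nanmin([ep["bpm_ref"].min(), ep["bpm_test"].min()]),
        np.nanmax([ep["bpm_ref"].max(), ep["bpm_test"].max()]),
    ]
    ax.plot(lims, lims, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("reference device (breaths/min)")
    ax.set_ylabel("test device (breaths/min)")
    ax.set_title("Per-epoch respiratory rate, both devices")
    fig.tight_layout()
    return fig


def bland_altman_plot(diffs: DifferenceSeries, result: BlandAltmanResult):
    """Difference vs two-device average, solid mean line, dashed LOA lines."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(diffs.avg, diffs.d, s=8, alpha=0.5, c=_subject_colors(diffs.subject_id))
    ax.axhline(result.mean_d, color="black", lw=1.2)
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, color="black", lw=1.0, ls="--")
    ax.set_xlabel("two-device average (breaths/min)")
    ax.set_ylabel("difference, reference - test (breaths/min)")
    ax.set_title(
        f"mean d = {result.mean_d:.2f}, LOA [{result.loa_lower:.2f}, "
        f"{result.loa_upper:.2f}], {result.pct_within:.1f}% within"
    )
    fig.tight_layout()
    return fig


def moderator_plots(mods: ModeratorResult, data: PairedDataset):
    """Per-subject mean difference against age and against nap duration."""
    import matplotlib.pyplot as plt

    subj = data.subjects.set_index("subject_id")
    ages = subj.loc[list(mods.subject_ids), "age_months"]
    naps = subj.loc[list(mods.subject_ids), "nap_duration_min"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, xvals, label, r in (
        (axes[0], ages, "age (months)", mods.r_age),
        (axes[1], naps, "nap duration (min)", mods.r_nap),
    ):
        ax.scatter(xvals, mods.mean_d_by_subject, s=18)
        ax.axhline(0, color="grey", lw=0.8, ls=":")
        ax.set_xlabel(label)
        ax.set_title("r undefined" if r is None else f"r = {r:.3f}")
    axes[0].set_ylabel("subject mean difference (bpm)")
    fig.tight_layout()
    return fig
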