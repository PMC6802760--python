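"""Simple figures: span profiles with fitted curves, and span-by-cell bars."""

from __future__ import annotations

import numpy as np

from .design import SpanProfile
from .spanfit import DEFAULT_CRITERION, ProfileFit


def plot_profile(profile: SpanProfile, fit: ProfileFit | None = None,
                 criterion: float = DEFAULT_CRITERION, ax=None):
    """Accuracy-vs-position profile with optional fitted curve and criterion line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.positions, profile.accuracy, "o", color="k",
            label="observed")
    if fit is not None:
        xs = np.linspace(-9, 9, 361)
        ax.plot(xs, fit.fitted(xs), "-", color="tab:blue",
                label=f"{fit.model} fit (r$^2$={fit.r_squared:.3f})")
    ax.axhline(criterion, ls="--", color="tab:red", lw=1,
               label=f"{criterion:.0f}% criterion")
    ax.set_xlabel("character position")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 105)
    ax.set_title(f"{profile.participant_id} / {profile.complexity}")
    ax.legend(fontsize=8)
    return ax


def plot_mean_spans(spans, ax=None):
    """Group-mean span (characters) by complexity, one line per age group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    order = ["low", "medium", "high"]
    for group, marker in (("young", "o"), ("older", "s")):
        sub = spans[spans["age_group"] == group]
        m = sub.groupby("complexity")["span_chars"].mean().reindex(order)
        se = sub.groupby("complexity")["span_chars"].sem().reindex(order)
        ax.errorbar(order, m, yerr=se, marker=marker, capsize=3, label=group)
    ax.set_xlabel("pattern complexity")
    ax.set_ylabel("span size (characters)")
    ax.legend()
    return ax
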