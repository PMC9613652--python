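"""Figure helpers: the school-slope fan and the PGI variance profile."""

from __future__ import annotations

import numpy as np


def plot_school_slopes(results, tail: float = 0.025, ax=None):
    """Fan of school-specific PGI->achievement regression lines.

    Highlights the weakest and strongest ``tail`` fraction of school slopes
    (BLUPs), visualising compensation: weak-slope schools sit higher.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    re = results.random_effects("school").sort_values("slope")
    g = np.linspace(-3, 3, 2)
    k = max(int(round(tail * len(re))), 1)
    const = results.fe_params.get("const", 0.0)
    for i, (_, row) in enumerate(re.iterrows()):
        if i < k:
            color, alpha, z = "crimson", 0.8, 3
        elif i >= len(re) - k:
            color, alpha, z = "royalblue", 0.8, 3
        else:
            color, alpha, z = "0.7", 0.15, 1
        ax.plot(g, const + row["intercept"] + row["slope"] * g, color=color, alpha=alpha, zorder=z, lw=0.8)
    ax.set_xlabel("within-family EA-PGI (SD)")
    ax.set_ylabel("achievement (SD)")
    ax.set_title("School-specific PGI slopes (BLUPs)")
    return ax


def plot_variance_profile(profile, ax=None, as_share: bool = True):
    """School-level variance (or its share of the total) across PGI values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    y = profile.share * 100 if as_share else profile.variance
    ax.plot(profile.grid, y, lw=2)
    ax.set_xlabel("within-family EA-PGI (SD)")
    ax.set_ylabel(
        f"{profile.level} share of variance (%)" if as_share else f"{profile.level} variance"
    )
    ax.set_ylim(bottom=0)
    return ax
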