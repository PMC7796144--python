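"""Optional score-plot helpers (requires matplotlib).

Convenience layer only: draws residual-augmented score scatters with group
means (bold points) and covariance ellipses at a configurable number of
standard deviations (default 2).
"""

from __future__ import annotations

import numpy as np

from .subspace import AugmentedScores

__all__ = ["score_plot"]


def score_plot(aug: AugmentedScores, ax=None, n_sd: float = 2.0, title: str | None = None):
    """Scatter the first two augmented score columns per group.

    Ellipses trace ``n_sd`` standard deviations of each group's 2-D score
    covariance.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    pts = aug.points
    if pts.shape[1] < 2:
        raise ValueError("score plot needs at least two components")
    if not aug.group_means:
        ax.scatter(pts[:, 0], pts[:, 1], s=10, alpha=0.6)
    for i, (lev, mean) in enumerate(aug.group_means.items()):
        color = f"C{i % 10}"
        cov = aug.group_covariances[lev][:2, :2]
        # group members are not stored; plot mean + ellipse only
        ax.scatter(*mean[:2], s=80, color=color, edgecolor="black", zorder=3, label=str(lev))
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
        width, height = 2 * n_sd * np.sqrt(evals[::-1])
        ax.add_patch(
            Ellipse(
                mean[:2], width, height, angle=angle,
                facecolor="none", edgecolor=color, lw=1.5,
            )
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    if aug.group_means:
        ax.legend(fontsize=8)
    return ax
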