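"""Optional SVG plots for the dating diagnostics."""

from __future__ import annotations

import numpy as np


def infinite_sites_plot(summaries, path, slope=None, intercept=None) -> None:
    """Scatter of 95% HPD width against posterior mean age, with the OLS fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(summaries, dict):
        summaries = list(summaries.values())
    means = np.array([s.mean for s in summaries])
    widths = np.array([s.hpd_width for s in summaries])
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.scatter(means, widths, s=18, color="#2c6fbb", zorder=3)
    if slope is not None:
        xx = np.linspace(0, means.max() * 1.05, 50)
        ax.plot(xx, intercept + slope * xx, color="#888888",
                label=f"slope = {slope:.3f}")
        ax.legend(frameon=False)
    ax.set_xlabel("posterior mean age (Ma)")
    ax.set_ylabel("95% HPD width (Ma)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def sweep_plot(result, path, labels=None) -> None:
    """Posterior mean age of each tracked clade against the root maximum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    for c, node in enumerate(result.clade_nodes):
        name = labels[node] if labels else f"node {node}"
        ax.plot(result.grid, result.mean_ages[:, c], marker="o", ms=3,
                label=f"{name} ({result.slopes[c]:.2f})")
    ax.set_xlabel("root maximum age (Ma)")
    ax.set_ylabel("posterior mean age (Ma)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
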