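"""Plotting hooks: Bland-Altman and scan-rescan scatter figures."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .reliability import BlandAltman, bland_altman


def plot_bland_altman(table: np.ndarray, title: str = "", out: str | Path | None = None):
    """Bland-Altman plot of a (subjects x 2 sessions) table.

    Marks the bias and the 95 % limits of agreement; differences are
    session1 - session2.  Returns the matplotlib figure; saves to ``out``
    (PNG/SVG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba: BlandAltman = bland_altman(np.asarray(table, dtype=float))
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(ba.means, ba.differences, s=25, color="tab:blue", zorder=3)
    ax.axhline(ba.bias, color="k", lw=1.2, label=f"bias = {ba.bias:.3g}")
    for y, ls in ((ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="tab:red", lw=1.0, linestyle=ls)
    ax.set_xlabel("mean of sessions")
    ax.set_ylabel("session 1 $-$ session 2")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def plot_scan_rescan(table: np.ndarray, title: str = "", out: str | Path | None = None):
    """Session-1 vs session-2 scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(table, dtype=float)
    fig, ax = plt.subplots(figsize=(4.0, 4.0))
    ax.scatter(t[:, 0], t[:, 1], s=25, color="tab:blue", zorder=3)
    lims = [t.min(), t.max()]
    ax.plot(lims, lims, "k--", lw=1.0)
    ax.set_xlabel("session 1")
    ax.set_ylabel("session 2")
    ax.set_title(title)
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
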