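"""State-probability (SP) and circadian-profile plots.

Both plots stack the smoothed state probabilities cumulatively per epoch
(they sum to one, so the bands fill the unit height), with the field's
colour convention: IA blue, MA light red, HA dark red.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .hmm import StateProbabilities  # noqa: E402
from .metrics import CircadianProfile, CircadianSummary  # noqa: E402

__all__ = ["sp_plot", "circadian_profile_plot", "STATE_COLORS"]

STATE_COLORS = ["#2c5f9e", "#f2a09a", "#a93226", "#6c3483", "#1e8449"]


def _stack(ax, x, probs, labels=None):
    m = probs.shape[1]
    colors = [STATE_COLORS[j % len(STATE_COLORS)] for j in range(m)]
    labels = labels or (
        ["IA", "MA", "HA"][:m] if m <= 3 else [f"state {j + 1}" for j in range(m)]
    )
    ax.stackplot(x, probs.T, colors=colors, labels=labels, step="post")
    ax.set_ylim(0, 1)
    ax.set_ylabel("state probability")
    return ax


def sp_plot(probs: StateProbabilities, decoded=None, path=None, ax=None):
    """Stacked cumulative plot of P(S_t = j | Y^(T)) over the recording."""
    p = probs.probs
    if ax is None:
        fig, ax = plt.subplots(figsize=(10, 2.8))
    else:
        fig = ax.figure
    if probs.time_grid is not None:
        x = probs.time_grid
    else:
        x = np.arange(p.shape[0])
    _stack(ax, x, p)
    if decoded is not None:
        ax.step(x, (np.asarray(decoded) + 0.5) / p.shape[1], where="post",
                color="gold", lw=0.8, label="decoded")
    ax.legend(loc="upper right", fontsize="x-small", ncol=p.shape[1] + 1)
    ax.set_title("state probability (SP) plot")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def circadian_profile_plot(
    profile: CircadianProfile,
    summary: CircadianSummary = None,
    path=None,
    ax=None,
):
    """24-h stacked periodic state-probability profile with the circadian
    parameters (a, c, RI) annotated in the title."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 3))
    else:
        fig = ax.figure
    _stack(ax, profile.grid_hours, profile.probs)
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 4))
    ax.set_xlabel("clock time (h)")
    if summary is not None:
        ri = summary.rhythm_index
        ri_txt = "n/a" if np.isnan(ri) else f"{ri:.2f}"
        c = summary.rest_centre
        c_txt = "n/a" if np.isnan(c) else f"{int(c):02d}:{int(round((c % 1) * 60)):02d}"
        ax.set_title(
            f"a = {summary.rest_amount_h:.1f} h, c = {c_txt}, RI = {ri_txt}"
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
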