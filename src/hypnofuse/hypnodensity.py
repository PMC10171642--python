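"""Hypnodensity graphs: stacked per-stage probability bands over the night.

A hypnodensity graph generalises the hypnogram: instead of one discrete
stage per 30-s epoch it shows the full probability distribution over the
five stages, either as predicted by a model or as the soft-consensus of a
group of scorers.  Stages stack bottom-to-top in the fixed order
W, N1, N2, N3, R.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .annotations import K, STAGES
from .errors import DimensionError

__all__ = ["HypnodensitySeries", "build_hypnodensity", "render"]

#: default band colours, W -> R
PALETTE = ("#c8c8c8", "#8dd3c7", "#80b1d3", "#4a6fa5", "#fb8072")

_SOURCES = ("model", "soft_consensus")


@dataclass(frozen=True)
class HypnodensitySeries:
    """Validated row-stochastic ``(T, K)`` series with provenance tag."""

    probabilities: np.ndarray
    source: str
    epoch_duration_s: float = 30.0

    @property
    def n_epochs(self) -> int:
        return self.probabilities.shape[0]


def build_hypnodensity(matrix: np.ndarray, source: str,
                       epoch_duration_s: float = 30.0) -> HypnodensitySeries:
    """Validate a probability matrix and wrap it as a plottable series.

    Rows off unit sum by more than 1e-6 are rejected (with the offending
    epoch index); rows off by at most 1e-6 are renormalised.  Rows already
    stochastic to within 1e-12 are passed through unaltered.
    """
    if source not in _SOURCES:
        raise ValueError(f"source must be one of {_SOURCES}, got {source!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != K:
        raise DimensionError(f"expected a (T, {K}) matrix, got {m.shape}")
    if (m < 0).any():
        raise ValueError("probabilities must be nonnegative")
    sums = m.sum(axis=1)
    off = np.abs(sums - 1.0)
    if (off > 1e-6).any():
        t = int(np.argmax(off))
        raise ValueError(
            f"row {t} sums to {sums[t]:.8f}, not 1 (tolerance 1e-6)"
        )
    if (off > 1e-12).any():
        m = m / sums[:, None]
    return HypnodensitySeries(probabilities=m, source=source,
                              epoch_duration_s=epoch_duration_s)


def _plot_hypnogram(ax, labels: np.ndarray, minutes: np.ndarray) -> None:
    # conventional display order: W on top, then R, N1, N2, N3 downwards
    display_y = {0: 4, 4: 3, 1: 2, 2: 1, 3: 0}
    y = np.array([display_y[int(v)] for v in labels])
    ax.step(minutes, y, where="post", color="black", linewidth=0.8)
    ax.set_yticks([4, 3, 2, 1, 0])
    ax.set_yticklabels(["W", "R", "N1", "N2", "N3"])
    ax.set_ylabel("stage")
    ax.set_xlim(minutes[0], minutes[-1])


def render(series: HypnodensitySeries, path, hypnogram: np.ndarray | None = None,
           acs_value: float | None = None, title: str | None = None,
           palette=PALETTE) -> None:
    """Render a hypnodensity graph (optionally with an aligned hypnogram).

    Stacked-area plot with x in minutes; band heights at every x sum to 1.
    If ``acs_value`` is given it is printed in the panel title, the usual
    way to annotate a model-vs-consensus comparison.
    """
    minutes = np.arange(series.n_epochs) * series.epoch_duration_s / 60.0
    nrows = 2 if hypnogram is not None else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(10, 2.2 * nrows), sharex=True,
        gridspec_kw={"height_ratios": [1, 2]} if nrows == 2 else None,
    )
    axes = np.atleast_1d(axes)
    if hypnogram is not None:
        _plot_hypnogram(axes[0], np.asarray(hypnogram), minutes)
    ax = axes[-1]
    ax.stackplot(minutes, series.probabilities.T, labels=STAGES,
                 colors=palette, linewidth=0)
    ax.set_ylim(0, 1)
    ax.set_xlim(minutes[0], minutes[-1] if series.n_epochs > 1 else 1.0)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("probability")
    ax.legend(loc="upper right", ncol=K, fontsize=7, frameon=False)
    head = title or f"hypnodensity ({series.source})"
    if acs_value is not None:
        head += f" — ACS = {acs_value:.3f}"
    axes[0].set_title(head, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_comparison(panels, path, hypnogram: np.ndarray | None = None) -> None:
    """Render several hypnodensity panels stacked vertically.

    ``panels`` is a list of ``(series, title, acs_value_or_None)`` tuples —
    the usual consensus-vs-models side-by-side figure.
    """
    n = len(panels) + (1 if hypnogram is not None else 0)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.9 * n), sharex=True)
    axes = np.atleast_1d(axes)
    row = 0
    if hypnogram is not None:
        minutes = np.arange(len(hypnogram)) * panels[0][0].epoch_duration_s / 60.0
        _plot_hypnogram(axes[0], np.asarray(hypnogram), minutes)
        row = 1
    for series, ptitle, acs_value in panels:
        ax = axes[row]
        minutes = np.arange(series.n_epochs) * series.epoch_duration_s / 60.0
        ax.stackplot(minutes, series.probabilities.T, labels=STAGES,
                     colors=PALETTE, linewidth=0)
        ax.set_ylim(0, 1)
        head = ptitle + (f" — ACS = {acs_value:.3f}" if acs_value is not None else "")
        ax.set_title(head, fontsize=9)
        row += 1
    axes[-1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
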