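"""Plotting helpers for the sliding-window tracks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sfs import WindowResult


def plot_sliding_window(
    windows: list[WindowResult],
    path: str | Path,
    percentile_line: float | None = None,
    title: str = "",
) -> None:
    """Window statistic vs position, with an optional 5th-percentile line."""
    xs = [(w.start + w.end) / 2 for w in windows]
    ys = [w.value for w in windows]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(xs, ys, lw=1.2, color="steelblue")
    flagged = [(x, y) for x, y, w in zip(xs, ys, windows) if w.below_5th]
    if flagged:
        ax.scatter(*zip(*flagged), color="crimson", s=12, zorder=3,
                   label="below 5th percentile")
        ax.legend(frameon=False)
    if percentile_line is not None:
        ax.axhline(percentile_line, ls="--", color="grey", lw=1)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(windows[0].stat if windows else "")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
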