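"""Final-sum histogram figures.

Plots are data-first: the plotted count table always exists as CSV next to
the image, so downstream checks read numbers, never pixels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .scheme import ScoringScheme
from .scoring import classify

CLASS_COLOURS = {
    "A": "#038141",   # dark green
    "B": "#85bb2f",
    "C": "#fecb02",
    "D": "#ee8100",
    "E": "#e63e11",   # dark orange
}


def plot_histograms(
    histograms: Mapping[int, pd.Series],
    group: str,
    category: str,
    scheme: ScoringScheme,
    out_path: str | Path,
    display_name: str | None = None,
) -> Path:
    """Side-by-side final-sum histograms for one food group.

    ``histograms`` maps year -> integer-binned counts.  Bars are coloured
    by the class letter of each final sum (waters, classified A outright,
    are not distinguishable in sum-space and take the sum's class colour).
    """
    if not histograms:
        raise ValueError(f"no histogram data for group {group!r}")
    years = sorted(histograms)
    fig, axes = plt.subplots(
        1, len(years), figsize=(6 * len(years), 4), sharey=True, squeeze=False
    )
    for ax, year in zip(axes[0], years):
        counts = histograms[year]
        colours = [
            CLASS_COLOURS[classify(int(s), category, scheme)] for s in counts.index
        ]
        ax.bar(counts.index, counts.values, color=colours, width=0.9)
        ax.set_title(f"{display_name or group} — {year} (n {int(counts.sum())})")
        ax.set_xlabel("final sum of points")
        ax.set_ylabel("number of products")
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in CLASS_COLOURS.values()]
    fig.legend(handles, CLASS_COLOURS.keys(), title="class", loc="upper right")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
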