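"""Boxplot export for distance-ratio summaries.

Because dyad vectors run to millions of values, plots are drawn from the
five-number summaries rather than the raw vectors; the underlying summary
table is always exported alongside, so the figure is never the only record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import DistanceSummary

__all__ = ["boxplot_summaries"]


def boxplot_summaries(
    summaries: Sequence[DistanceSummary],
    path: Union[str, Path],
    title: str = "Standardized distance ratios",
) -> Path:
    """Draw one box (median + IQR, whiskers at the quartiles) per group pair."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(1.4 * max(4, len(summaries)), 4))
    stats = [
        {
            "label": f"{s.group_pair[0]}\n({s.group_pair[1]})",
            "med": s.median,
            "q1": s.q1,
            "q3": s.q3,
            "whislo": s.q1,
            "whishi": s.q3,
            "fliers": [],
        }
        for s in summaries
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("standardized distance ratio")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
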