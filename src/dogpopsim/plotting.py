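"""Box plots of scenario outcome distributions, matching the field's usual
presentation: one box per scenario of final population size over replicates,
with a dashed reference line at community capacity."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import ReplicateSummary


def boxplot_final_sizes(
    summaries: Mapping[str, ReplicateSummary],
    capacity: int | None = None,
    title: str | None = None,
    path: str | Path | None = None,
):
    """One box per scenario; returns the matplotlib figure."""
    labels = list(summaries)
    data = [summaries[k].finals for k in labels]
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(labels), 4.5))
    ax.boxplot(data, tick_labels=labels)
    if capacity is not None:
        ax.axhline(capacity, linestyle="--", color="grey",
                   label=f"community capacity ({capacity})")
        ax.legend(frameon=False, fontsize=8)
    ax.set_ylabel("final population size (dogs)")
    ax.set_xlabel("scenario")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
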