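"""Optional diagnostic plot: measured vs predicted mixed-substrate rates."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import PredictionRecord


def plot_measured_vs_predicted(
    records: Sequence[PredictionRecord],
    lambda_c: float,
    path: str | Path,
) -> Path:
    """Scatter of measured vs predicted rates with the diagonal and speed limit.

    Group-A pairs (filled) should hug the diagonal; group-B pairs (open)
    scatter below it.  The dashed line marks ``lambda_c``, which no mixed
    rate can exceed under the model.
    """
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for group, filled in (("A", True), ("B", False)):
        xs = [r.predicted for r in records if r.group == group]
        ys = [r.measured for r in records if r.group == group]
        ax.scatter(
            xs, ys,
            facecolors="C0" if filled else "none",
            edgecolors="C0",
            label=f"group {group}",
        )
    lim = max([lambda_c] + [r.predicted for r in records] + [r.measured for r in records])
    lim *= 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.axhline(lambda_c, ls="--", color="C1", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("predicted growth rate (1/h)")
    ax.set_ylabel("measured growth rate (1/h)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
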