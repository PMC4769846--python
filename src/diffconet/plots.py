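"""Plotting helpers (matplotlib, Agg-safe)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .config import AnalysisConfig
from .diffnet import DiffNetResult


def diffnet_scatter(
    result: DiffNetResult, config: AnalysisConfig, path: str | Path
) -> None:
    """Differential expression vs differential connectivity scatter with
    the eight sector boundaries."""
    fig, ax = plt.subplots(figsize=(6, 5))
    table = result.table
    in_sector = table["sector"] != "NS"
    ax.scatter(
        table.loc[~in_sector, "t"], table.loc[~in_sector, "diff_k"],
        s=8, c="lightgrey", label="NS",
    )
    ax.scatter(
        table.loc[in_sector, "t"], table.loc[in_sector, "diff_k"],
        s=10, c="crimson", label="R1-R8",
    )
    for x in (-config.t_threshold, config.t_threshold):
        ax.axvline(x, color="k", lw=0.8, ls="--")
    for y in (-config.k_threshold, config.k_threshold):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("differential expression (t)")
    ax.set_ylabel("differential connectivity (diffK)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
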