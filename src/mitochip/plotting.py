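"""Simple linear strand-coverage plots (the circular-display analogue)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .coverage import StrandCoverage


def plot_strand_coverage(
    chip: StrandCoverage,
    input_cov: StrandCoverage | None,
    path: str | Path,
    bin_size: int = 50,
) -> None:
    """Binned +/- strand ChIP coverage (and optional input) over one contig."""
    import numpy as np

    def _binned(track):
        n = track.size // bin_size * bin_size
        return track[:n].reshape(-1, bin_size).sum(axis=1)

    x = (0.5 + np.arange(_binned(chip.plus).size)) * bin_size
    fig, axes = plt.subplots(
        2 if input_cov is not None else 1, 1, figsize=(10, 5), sharex=True,
        squeeze=False,
    )
    ax = axes[0][0]
    ax.plot(x, _binned(chip.plus), color="crimson", lw=0.8, label="+ strand")
    ax.plot(x, -_binned(chip.minus), color="royalblue", lw=0.8,
            label="- strand")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("ChIP 5' ends / bin")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(f"{chip.contig} strand-specific read density")
    if input_cov is not None:
        ax2 = axes[1][0]
        ax2.plot(x, _binned(input_cov.plus), color="crimson", lw=0.8)
        ax2.plot(x, -_binned(input_cov.minus), color="royalblue", lw=0.8)
        ax2.axhline(0, color="k", lw=0.5)
        ax2.set_ylabel("input 5' ends / bin")
        ax2.set_xlabel(f"position on {chip.contig} (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
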