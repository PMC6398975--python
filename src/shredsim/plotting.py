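"""Optional trajectory plots (matplotlib, Agg backend)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .engine import ReplicateSummary

__all__ = ["plot_summary"]


def plot_summary(summary: ReplicateSummary, path: str | Path) -> Path:
    """Two-panel plot: total N with allosome genotypes, and autosome genotypes."""
    cycles = range(summary.mean.shape[0])
    years = [c / summary.cycles_per_year for c in cycles]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for name, color in (("N", "k"), ("XX", "tab:red"), ("XY", "tab:blue"), ("XO", "tab:purple")):
        mean, lo, hi = summary.series(name)
        ax1.plot(years, mean, color=color, label=name)
        ax1.fill_between(years, lo, hi, color=color, alpha=0.15, linewidth=0)
    ax1.set_xlabel("years")
    ax1.set_ylabel("individuals")
    ax1.legend(frameon=False, fontsize=8)
    for name in ("WW", "WG", "GG", "WR", "GR", "RR"):
        mean, lo, hi = summary.series(name)
        ax2.plot(years, mean, label=name)
        ax2.fill_between(years, lo, hi, alpha=0.15, linewidth=0)
    ax2.set_xlabel("years")
    ax2.set_ylabel("individuals by autosome genotype")
    ax2.legend(frameon=False, fontsize=8, ncol=2)
    fig.suptitle(
        f"eradication probability {summary.eradication_probability:.2f} "
        f"({summary.n_replicates} replicates)"
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
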