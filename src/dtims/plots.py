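"""Optional SVG plots for campaign reports.

Cosmetic companions to the analytics reports: the CCS-m/z trend with the
filter band, replicate-spread box plots, and threshold pie charts.  These
are presentation helpers; nothing downstream depends on their output.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .curation import TrendlineFit
from .library_io import Library

__all__ = ["plot_ccs_mz_trend", "plot_replicate_spread", "plot_threshold_pie"]


def plot_ccs_mz_trend(
    library: Library,
    trend: TrendlineFit | None = None,
    band_pct: float = 15.0,
    path=None,
):
    """Scatter of library entries in (m/z, CCS) with the trend and filter band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    e = library.entries
    for ion, sub in e.groupby("ion_type"):
        ax.scatter(sub["mz_measured_mean"], sub["ccs_mean_A2"], s=8, label=ion)
    if trend is not None and len(e):
        mz = np.linspace(e["mz_measured_mean"].min(), e["mz_measured_mean"].max(), 200)
        mid = trend.predict(mz)
        ax.plot(mz, mid, "k-", lw=1)
        ax.fill_between(mz, mid * (1 - band_pct / 100), mid * (1 + band_pct / 100),
                        alpha=0.15, color="gray")
    ax.set_xlabel("m/z (Th)")
    ax.set_ylabel(r"CCS ($\AA^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_replicate_spread(library: Library, by: str = "mode", path=None):
    """Box plot of replicate percent differences grouped by mode or class."""
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [
        (label, sub["replicate_pct_diff"].dropna().to_numpy())
        for label, sub in library.entries.groupby(by)
    ]
    groups = [(l, v) for l, v in groups if len(v)]
    if groups:
        ax.boxplot([v for _, v in groups], tick_labels=[l for l, _ in groups])
    ax.axhline(1.0, color="r", ls="--", lw=0.8)
    ax.set_ylabel("replicate % difference")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_threshold_pie(fractions: dict[str, float], path=None):
    """Pie of threshold-bin fractions (e.g. <=2%, 2-5%, >5%)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    labels = [k for k, v in fractions.items() if v]
    values = [v for v in fractions.values() if v]
    if values:
        ax.pie(values, labels=labels, autopct="%.0f%%")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
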