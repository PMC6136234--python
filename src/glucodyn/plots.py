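"""Basic diagnostic plots: Poincare scattergram with fitting ellipse, and
the DFA log-log fluctuation curve with its two fitted slopes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from glucodyn.dfa import DFAResult
from glucodyn.poincare import lagged_pairs, poincare_descriptors
from glucodyn.series import GlucoseSeries


def poincare_plot(
    series: GlucoseSeries, path: str | Path, lag_min: float = 60.0
) -> None:
    """Scatter of (G(t), G(t+dt)) with the SD1/SD2 fitting ellipse."""
    x, y = lagged_pairs(series, lag_min)
    r = poincare_descriptors(series, lag_min)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(x, y, ".", ms=2, alpha=0.4, color="tab:blue")
    cx, cy = x.mean(), y.mean()
    theta = np.linspace(0, 2 * np.pi, 200)
    # ellipse axes along (SD2) and across (SD1) the identity line
    ex = r.sd2 * np.cos(theta) / np.sqrt(2) - r.sd1 * np.sin(theta) / np.sqrt(2)
    ey = r.sd2 * np.cos(theta) / np.sqrt(2) + r.sd1 * np.sin(theta) / np.sqrt(2)
    ax.plot(cx + ex, cy + ey, "-", color="tab:red", lw=1.5)
    lims = [min(x.min(), y.min()) - 0.5, max(x.max(), y.max()) + 0.5]
    ax.plot(lims, lims, "--", color="grey", lw=0.8)
    ax.set_xlabel("G(t) (mmol/l)")
    ax.set_ylabel(f"G(t + {lag_min:g} min) (mmol/l)")
    ax.set_title(
        f"{series.subject_id}: SD1={r.sd1:.2f}, SD2={r.sd2:.2f}, AFE={r.afe:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dfa_loglog_plot(result: DFAResult, path: str | Path) -> None:
    """log10 F(n) against log10 n with the short/long-range regression lines."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    sel = result.fluctuations > 0
    lx = np.log10(result.box_sizes[sel].astype(float))
    ly = np.log10(result.fluctuations[sel])
    ax.plot(lx, ly, "o", ms=4, color="tab:blue")
    for (lo, hi), alpha, color in (
        (result.fit_range_short, result.alpha1, "tab:red"),
        (result.fit_range_long, result.alpha2, "tab:green"),
    ):
        if not np.isfinite(alpha):
            continue
        m = (result.box_sizes[sel] >= lo) & (result.box_sizes[sel] <= hi)
        coef = np.polyfit(lx[m], ly[m], 1)
        ax.plot(lx[m], np.polyval(coef, lx[m]), "-", color=color,
                label=f"n {lo}-{hi}: alpha={alpha:.2f}")
    ax.set_xlabel("log10 n (box size, samples)")
    ax.set_ylabel("log10 F(n)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
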