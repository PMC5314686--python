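"""Publication-style diagnostic plots (log-log spectra, q^4-rescaled
fits, Kc convergence series). All functions return the matplotlib Figure
and never call ``show``; use a non-interactive backend in scripts.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .convergence import KcSeries
from .fitting import HeightFitResult, ThicknessFitResult
from .spectra import PowerSpectrum

__all__ = ["plot_height_spectrum", "plot_thickness_spectrum", "plot_kc_series"]


def plot_height_spectrum(spectrum: PowerSpectrum, fit: HeightFitResult | None = None):
    """Two panels: log-log spectrum and the q^4-rescaled constant fit."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    ax1.loglog(spectrum.q, spectrum.intensity, "s", ms=3, color="0.4")
    ax1.set_xlabel(r"$q$ (nm$^{-1}$)")
    ax1.set_ylabel(r"$\langle|h(q)|^2\rangle$ (nm$^4$)")
    if fit is not None:
        qq = np.geomspace(spectrum.q.min(), fit.q_max, 50)
        ax1.loglog(qq, 1.0 / (fit.Kc * qq**4), "r-", lw=1.5,
                   label=rf"$K_c$ = {fit.Kc:.1f} $k_BT$")
        ax1.legend(frameon=False)
    y = spectrum.q**4 * spectrum.intensity
    ax2.semilogx(spectrum.q, y, "o", ms=3, color="0.4")
    if fit is not None:
        sel = spectrum.q < fit.q_max
        ax2.semilogx(spectrum.q[sel], y[sel], "o", ms=3, color="tab:blue")
        ax2.axhline(fit.fitted_constant, color="r", lw=1.5)
        ax2.axvline(fit.q_max, color="0.7", ls="--")
    ax2.set_xlabel(r"$q$ (nm$^{-1}$)")
    ax2.set_ylabel(r"$q^4\langle|h(q)|^2\rangle$")
    fig.tight_layout()
    return fig


def plot_thickness_spectrum(spectrum: PowerSpectrum, fit: ThicknessFitResult | None = None):
    """Log-log thickness spectrum with the direct Helfrich fit."""
    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    ax.loglog(spectrum.q, spectrum.intensity, "s", ms=3, color="0.4")
    if fit is not None:
        qq = np.geomspace(spectrum.q.min(), spectrum.q.max(), 100)
        ax.loglog(qq, 1.0 / (fit.Kd * qq**4 + fit.Ke), "g-", lw=1.5,
                  label=rf"$K_d$={fit.Kd:.1f}, $K_e$={fit.Ke:.1f} $k_BT$")
        ax.legend(frameon=False)
    ax.set_xlabel(r"$q$ (nm$^{-1}$)")
    ax.set_ylabel(r"$\langle|t(q)|^2\rangle$ (nm$^4$)")
    fig.tight_layout()
    return fig


def plot_kc_series(series: KcSeries):
    """Per-bin Kc time series with failed bins marked."""
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    mid = 0.5 * (series.bin_start + series.bin_end)
    ax.plot(mid[series.ok], series.Kc[series.ok], ".-", ms=4)
    bad = ~series.ok
    if bad.any():
        ax.plot(mid[bad], np.full(bad.sum(), np.nanmean(series.Kc)), "rx", label="failed fit")
        ax.legend(frameon=False)
    ax.set_xlabel("bin")
    ax.set_ylabel(r"$K_c$ ($k_BT$)")
    fig.tight_layout()
    return fig
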