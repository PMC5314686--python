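"""Equilibration and sampling-quality diagnostics for Kc estimates.

Two instruments, mirroring standard MD practice:

* a binned Kc time series — the trajectory is cut into bins of equal
  width (conventionally 1000, or 100 for short runs), the spectrum is
  computed and fitted per bin, and the resulting series is inspected for
  drifts;
* the statistical inefficiency g of a scalar series, estimated as the
  plateau of the block-averaging variance ratio
  g(b) = b * var(block means of width b) / var(series). The effective
  number of independent samples is n/g. For an AR(1) series with lag-1
  correlation rho the closed form is g = (1+rho)/(1-rho).

"Reverse penetration" scans g over trailing fractions of the series:
an initial transient inflates g as soon as the window reaches back into
it, so the recommended equilibration cut is the shortest prefix whose
removal leaves the g-profile stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .errors import (
    FitError,
    ParameterError,
    SizeError,
    UndefinedInefficiencyError,
)
from .fitting import fit_bending_rigidity
from .spectra import Spectrum2D, average_over_frames

__all__ = [
    "KcSeries",
    "InefficiencyProfile",
    "kc_timeseries",
    "statistical_inefficiency",
    "inefficiency_profile",
]


@dataclass
class KcSeries:
    """Per-bin bending rigidities over a trajectory."""

    bin_start: np.ndarray      # ps
    bin_end: np.ndarray        # ps
    Kc: np.ndarray             # k_BT; NaN where the bin fit failed
    ok: np.ndarray             # bool per bin

    def __len__(self) -> int:
        return len(self.Kc)

    @property
    def valid(self) -> np.ndarray:
        return self.Kc[self.ok]


@dataclass
class InefficiencyProfile:
    """g over (reverse-penetration fraction, block width) plus the cut."""

    fractions: np.ndarray            # trailing fraction of the series used
    bin_widths: np.ndarray
    g: np.ndarray                    # shape (n_fractions, n_widths)
    g_plateau: np.ndarray            # plateau g per fraction
    recommended_cut: int             # samples to discard from the start
    meta: dict = dc_field(default_factory=dict)


def kc_timeseries(
    per_frame_spectra: Sequence[Spectrum2D],
    q_max: float,
    n_bins: int = 1000,
    shell_width: float | None = None,
) -> KcSeries:
    """Kc fitted on each of ``n_bins`` contiguous equal-width bins.

    Bins whose fit fails are flagged (``ok=False``, Kc=NaN) rather than
    imputed — silent interpolation would mask exactly the pathologies the
    diagnostic is looking for.
    """
    spectra = list(per_frame_spectra)
    n = len(spectra)
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    if n_bins > n:
        raise SizeError(f"n_bins={n_bins} exceeds the {n} available frames")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    kc = np.full(n_bins, np.nan)
    ok = np.zeros(n_bins, dtype=bool)
    t0 = np.empty(n_bins)
    t1 = np.empty(n_bins)
    for b in range(n_bins):
        t0[b] = edges[b]
        t1[b] = edges[b + 1]
        try:
            ps = average_over_frames(spectra[edges[b] : edges[b + 1]], shell_width)
            kc[b] = fit_bending_rigidity(ps, q_max).Kc
            ok[b] = True
        except Exception:
            pass
    if not ok.any():
        raise FitError("every per-bin fit failed")
    return KcSeries(bin_start=t0, bin_end=t1, Kc=kc, ok=ok)


def _block_g(series: np.ndarray, width: int) -> float:
    """g(b) = b * var(block means) / var(series) at one block width."""
    n = len(series)
    nb = n // width
    means = series[: nb * width].reshape(nb, width).mean(axis=1)
    v = series.var()
    return float(width * means.var(ddof=1) / v)


def _default_widths(n: int) -> np.ndarray:
    """Geometric block-width grid keeping >= ~100 blocks per estimate."""
    wmax = max(2, n // 100)
    grid = np.unique(np.geomspace(1, wmax, 24).astype(int))
    return grid[grid >= 1]


def statistical_inefficiency(
    series: np.ndarray, block_width: int | None = None
) -> float:
    """Statistical inefficiency g of a scalar series.

    With ``block_width`` given, the single-width block estimate
    g(b) = b var(block means)/var(series) — this is the value the
    block-averaging curve converges to from below as b grows past the
    correlation time. Without it, g is computed from the truncated
    autocorrelation sum

        g = 1 + 2 sum_k (1 - k/n) rho_k,

    summed up to the first non-positive autocorrelation; the two agree on
    the g(b) plateau but the sum has far smaller estimator variance than
    any single large-b block estimate. g >= 1 up to estimator noise; 1
    means uncorrelated samples.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if block_width is not None:
        if n < 4 * block_width:
            raise SizeError("series must be at least 4 block widths long")
        if np.ptp(series) == 0:
            raise UndefinedInefficiencyError("zero-variance series")
        return _block_g(series, block_width)
    if n < 8:
        raise SizeError("series too short")
    if np.ptp(series) == 0:
        raise UndefinedInefficiencyError("zero-variance series")
    centered = series - series.mean()
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(centered, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    positive = np.flatnonzero(rho[1:] <= 0)
    kmax = (positive[0] + 1) if positive.size else n
    k = np.arange(1, kmax)
    g = 1.0 + 2.0 * np.sum((1.0 - k / n) * rho[1:kmax])
    return float(max(g, 1.0))


def inefficiency_profile(
    series: np.ndarray,
    bin_widths: Sequence[int] | None = None,
    reverse_fractions: Sequence[float] | None = None,
) -> InefficiencyProfile:
    """Scan g over trailing fractions of the series and pick the cut.

    For each reverse-penetration fraction f the inefficiency is computed
    over the last f*n samples, across all block widths. The recommended
    equilibration cut is the smallest (1 - f)*n whose plateau-g lies
    within 20% of the deep-cut reference (the median over the most-
    truncated fractions) — i.e. the shortest prefix whose removal makes
    the diagnostic agree with the well-equilibrated tail.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if reverse_fractions is None:
        reverse_fractions = np.round(np.arange(1.0, 0.45, -0.05), 10)
    fractions = np.asarray(sorted(reverse_fractions, reverse=True), dtype=float)
    if np.any((fractions <= 0) | (fractions > 1)):
        raise ParameterError("reverse fractions must lie in (0, 1]")
    if bin_widths is None:
        bin_widths = _default_widths(int(fractions.min() * n))
    widths = np.asarray(bin_widths, dtype=int)
    if np.any(widths < 1) or int(fractions.min() * n) < 4 * widths.max():
        raise SizeError("each truncated series must cover 4x the largest width")

    g = np.empty((len(fractions), len(widths)))
    g_plateau = np.empty(len(fractions))
    for i, f in enumerate(fractions):
        tail = series[n - int(round(f * n)) :]
        if np.ptp(tail) == 0:
            raise UndefinedInefficiencyError("zero-variance trailing series")
        g[i] = [_block_g(tail, int(w)) for w in widths]
        g_plateau[i] = statistical_inefficiency(tail)

    # reference g from the deepest cuts (assumed past any transient);
    # the cut is the smallest prefix removal whose g (and all deeper
    # ones) sits within 20% of that reference
    ref = float(np.median(g_plateau[-min(5, len(g_plateau)) :]))
    within = np.abs(g_plateau / max(ref, 1e-300) - 1.0) <= 0.2
    cut_idx = int(np.argmax(within)) if within.any() else len(fractions) - 1
    recommended = int(round((1.0 - fractions[cut_idx]) * n))
    return InefficiencyProfile(
        fractions=fractions,
        bin_widths=widths,
        g=g,
        g_plateau=g_plateau,
        recommended_cut=recommended,
        meta={"n": n},
    )
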