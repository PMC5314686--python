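"""Helfrich-Canham elastic fits of radially averaged fluctuation spectra.

Height (undulatory) spectrum, moduli in k_BT so temperature never enters:

    S_h(q) = 1 / (Kc q^4)          =>   q^4 S_h(q) = 1/Kc  (a constant)

A direct least-squares fit of S_h is dominated by the few lowest-q points
(their intensities are orders of magnitude larger), so the constant is
instead fitted on the q^4-rescaled spectrum, where every shell carries
equal weight: c = mean(q_k^4 I_k), Kc = 1/c.

Thickness (peristaltic) spectrum:

    S_t(q) = 1 / (Kd q^4 + Ke)

fitted directly (nonlinear least squares) on the un-rescaled intensities;
at low q it approaches the constant asymptote 1/Ke.

The low-q fit window for the height fit follows the patch-size rule used
throughout this kind of analysis: q_max = 0.6, 0.4, 0.2 nm^-1 for small
(< 30 nm), medium (30-80 nm) and large (>= 80 nm) patches. The class
boundaries are this package's (configurable) choice; the windows are the
standard ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, ParameterError, SizeError
from .spectra import PowerSpectrum, Spectrum2D, average_over_frames

__all__ = [
    "HeightFitResult",
    "ThicknessFitResult",
    "default_fit_window",
    "fit_bending_rigidity",
    "fit_thickness_moduli",
    "block_error",
]

#: patch-size class boundaries (nm) -> fit window (nm^-1)
SMALL_MEDIUM_BOUNDARY = 30.0
MEDIUM_LARGE_BOUNDARY = 80.0
FIT_WINDOWS = {"small": 0.6, "medium": 0.4, "large": 0.2}


@dataclass
class HeightFitResult:
    """Bending rigidity from the q^4-rescaled height spectrum."""

    Kc: float                      # k_BT
    Kc_se: float                   # k_BT, propagated from shell scatter
    q_max: float                   # nm^-1
    n_shells_used: int
    fitted_constant: float         # 1/Kc
    residuals: np.ndarray = dc_field(default_factory=lambda: np.empty(0))

    def kc_joules(self, temperature: float) -> float:
        """Kc in joules at the given temperature (K). Display-time only."""
        return self.Kc * 1.380649e-23 * temperature


@dataclass
class ThicknessFitResult:
    """Peristaltic moduli from the direct thickness-spectrum fit."""

    Kd: float                      # k_BT
    Ke: float                      # k_BT nm^-4 (reported on the k_BT scale)
    Kd_se: float
    Ke_se: float
    q_max: float
    n_shells_used: int
    low_q_anomaly: bool = False    # lowest shell rises above the asymptote


def default_fit_window(box_lengths: Sequence[float]) -> float:
    """Low-q fit window q_max (nm^-1) from the patch size.

    0.6 for max(L) < 30 nm, 0.4 for 30-80 nm, 0.2 for >= 80 nm.
    """
    lmax = max(box_lengths)
    if lmax <= 0:
        raise ParameterError("box lengths must be positive")
    if lmax < SMALL_MEDIUM_BOUNDARY:
        return FIT_WINDOWS["small"]
    if lmax < MEDIUM_LARGE_BOUNDARY:
        return FIT_WINDOWS["medium"]
    return FIT_WINDOWS["large"]


def fit_bending_rigidity(spectrum: PowerSpectrum, q_max: float) -> HeightFitResult:
    """Fit Kc as the inverse of the mean q^4-rescaled shell intensity.

    Uses shells with 0 < q < q_max; each shell contributes equally. The
    standard error comes from the scatter of the rescaled shell values.
    """
    if spectrum.kind != "height":
        raise ParameterError(f"expected a height spectrum, got kind={spectrum.kind!r}")
    if q_max <= 0:
        raise ParameterError("q_max must be positive")
    sel = (spectrum.q > 0) & (spectrum.q < q_max)
    k = int(sel.sum())
    if k < 3:
        raise InsufficientDataError(
            f"only {k} shells below q_max={q_max} nm^-1; need >= 3"
        )
    y = spectrum.q[sel] ** 4 * spectrum.intensity[sel]
    c = float(y.mean())
    if c <= 0:
        raise FitError("non-positive rescaled intensity: cannot invert for Kc")
    se_c = float(y.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    kc = 1.0 / c
    return HeightFitResult(
        Kc=kc,
        Kc_se=se_c / c**2,  # delta method on Kc = 1/c
        q_max=float(q_max),
        n_shells_used=k,
        fitted_constant=c,
        residuals=y - c,
    )


def fit_thickness_moduli(
    spectrum: PowerSpectrum, q_max: float | None = None
) -> ThicknessFitResult:
    """Fit S_t(q) = 1/(Kd q^4 + Ke) directly to the thickness spectrum.

    ``q_max=None`` uses every shell (the peristaltic form is fitted over
    the full spectrum; the q^4 term only becomes identifiable well above
    the height-fit windows). Initialised at Ke = 1/I(lowest shell),
    Kd = 0, with a few bounded restarts on non-convergence. Sets
    ``low_q_anomaly`` when the lowest shell exceeds the fitted asymptote
    by more than 3 of its standard errors (spectra rising again at low q
    fall outside the Helfrich-Canham thickness form).
    """
    if spectrum.kind != "thickness":
        raise ParameterError(f"expected a thickness spectrum, got kind={spectrum.kind!r}")
    sel = spectrum.q > 0 if q_max is None else (spectrum.q > 0) & (spectrum.q < q_max)
    k = int(sel.sum())
    if k < 5:
        raise InsufficientDataError(f"only {k} shells in the fit window; need >= 5")
    q = spectrum.q[sel]
    y = spectrum.intensity[sel]
    counts = spectrum.counts[sel]

    def model(qv, kd, ke):
        return 1.0 / (kd * qv**4 + ke)

    ke0 = 1.0 / max(y[0], 1e-300)
    last_err: Exception | None = None
    for kd0 in (0.0, 1.0, 10.0):
        try:
            popt, pcov = curve_fit(
                model,
                q,
                y,
                p0=(kd0, ke0),
                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
            break
        except RuntimeError as err:  # pragma: no cover - depends on data
            last_err = err
    else:
        raise FitError(f"thickness fit did not converge after restarts: {last_err}")

    kd, ke = float(popt[0]), float(popt[1])
    kd_se, ke_se = (float(np.sqrt(pcov[i, i])) for i in range(2))

    # per-mode intensities are ~exponential => SE of a shell mean is
    # intensity/sqrt(count); flag non-HC low-q behaviour at 3 sigma
    se0 = y[0] / np.sqrt(counts[0])
    anomaly = bool(y[0] > 1.0 / ke + 3.0 * se0)
    return ThicknessFitResult(
        Kd=kd,
        Ke=ke,
        Kd_se=kd_se,
        Ke_se=ke_se,
        q_max=float(q_max) if q_max is not None else float(q[-1]),
        n_shells_used=k,
        low_q_anomaly=anomaly,
    )


def block_error(
    per_frame_spectra: Sequence[Spectrum2D],
    q_max: float,
    n_blocks: int = 5,
    shell_width: float | None = None,
) -> Tuple[float, np.ndarray]:
    """Block-resampled standard error of Kc.

    Splits the trajectory into ``n_blocks`` contiguous blocks, fits Kc on
    each block's spectrum, and returns (SE = stdev/sqrt(n_blocks),
    per-block Kc values). A failing block fit propagates with its index.
    """
    if n_blocks < 5:
        raise ParameterError("need n_blocks >= 5")
    spectra = list(per_frame_spectra)
    n = len(spectra)
    if n < n_blocks:
        raise SizeError(f"{n} frames cannot fill {n_blocks} blocks")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    kcs = np.empty(n_blocks)
    for b in range(n_blocks):
        block = spectra[edges[b] : edges[b + 1]]
        try:
            ps = average_over_frames(block, shell_width)
            kcs[b] = fit_bending_rigidity(ps, q_max).Kc
        except Exception as err:
            raise FitError(f"fit failed in block {b}: {err}") from err
    se = float(kcs.std(ddof=1) / np.sqrt(n_blocks))
    return se, kcs
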