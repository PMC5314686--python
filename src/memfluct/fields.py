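"""Core containers for gridded membrane surfaces and marker coordinates.

Conventions (used consistently across the package):

* lengths in nm, times in ps, moduli in units of k_BT;
* grid node (i, j) sits at position (i*dx, j*dy), 0-based, on the
  half-open cell [0, Lx) x [0, Ly) with periodic wrap (index Nx == 0);
* discrete Fourier coefficients follow h_hat(q) = (1/N) sum_r h(r) e^{-iq.r}
  with wavevectors q = 2*pi*(nx/Lx, ny/Ly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

from .errors import ParameterError, SizeError

FieldKind = Literal["height", "thickness"]


@dataclass
class GridField:
    """A periodic 2D scalar field (height or thickness) on a regular grid.

    Parameters
    ----------
    values
        Nx x Ny real array, nm. ``values[i, j]`` lives at
        ``(i * Lx / Nx, j * Ly / Ny)``.
    box_lengths
        (Lx, Ly) in nm.
    kind
        ``"height"`` (bilayer midplane) or ``"thickness"`` (leaflet
        separation).
    time
        Frame time in ps (0 for synthetic/static fields).
    mean_value
        Spatial mean stripped from (thickness) fields before spectral
        analysis; kept as metadata.
    """

    values: np.ndarray
    box_lengths: Tuple[float, float]
    kind: FieldKind = "height"
    time: float = 0.0
    mean_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SizeError("GridField.values must be a 2D array")
        if min(self.values.shape) < 4:
            raise SizeError(
                f"grid {self.values.shape} too small; need at least 4x4"
            )
        lx, ly = self.box_lengths
        if not (np.isfinite(lx) and np.isfinite(ly) and lx > 0 and ly > 0):
            raise ParameterError(f"box lengths must be positive, got {self.box_lengths}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("GridField values must all be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def spacing(self) -> Tuple[float, float]:
        """(dx, dy) grid spacing in nm."""
        return (self.box_lengths[0] / self.shape[0], self.box_lengths[1] / self.shape[1])

    @property
    def area(self) -> float:
        """Projected box area Lx*Ly in nm^2."""
        return float(self.box_lengths[0] * self.box_lengths[1])

    def wavevectors(self) -> Tuple[np.ndarray, np.ndarray]:
        """1D wavevector axes (qx, qy) in nm^-1 in FFT layout."""
        nx, ny = self.shape
        lx, ly = self.box_lengths
        qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
        qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
        return qx, qy

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the field at arbitrary (x, y) points.

        Uses the trigonometric (Fourier-series) interpolant of the grid, the
        unique smooth periodic surface with the grid's spectral content;
        exact at grid nodes and for any band-limited surface.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        qx, qy = self.wavevectors()
        n = self.values.size
        hq = np.fft.fft2(self.values) / n
        ex = np.exp(1j * np.outer(xy[:, 0], qx))
        ey = np.exp(1j * np.outer(xy[:, 1], qy))
        return np.einsum("pi,ij,pj->p", ex, hq, ey).real


@dataclass
class MarkerFrame:
    """Headgroup-marker coordinates of one trajectory frame.

    ``positions`` is an (N, 3) array in nm, wrapped into the primary box
    ``[0, Lx) x [0, Ly) x [0, Lz)``.
    """

    positions: np.ndarray
    box_lengths: Tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise SizeError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 16:
            raise SizeError(
                f"need at least 16 marker particles, got {self.positions.shape[0]}"
            )
        if any(l <= 0 for l in self.box_lengths):
            raise ParameterError(f"box lengths must be positive, got {self.box_lengths}")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("marker positions must be finite")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeafletPair:
    """Marker positions split into upper and lower leaflets (nm)."""

    upper: np.ndarray
    lower: np.ndarray
    box_lengths: Tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))
    time: float = 0.0

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        for name, pts in (("upper", self.upper), ("lower", self.lower)):
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise SizeError(f"{name} leaflet must be an (N, 3) array")
            if pts.shape[0] < 8:
                raise SizeError(f"{name} leaflet has {pts.shape[0]} markers; need >= 8")
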