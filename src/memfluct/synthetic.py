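"""Synthetic Helfrich membrane ensembles.

Generates periodic Monge-gauge height fields h(x, y) and thickness fields
t(x, y) whose Fourier modes are independent zero-mean Gaussians with the
variances predicted by Helfrich-Canham continuum elasticity (all moduli in
k_BT units):

* height (undulatory) modes:    A <|h_hat(q)|^2> = 1 / (Kc q^4)
* thickness (peristaltic) modes: A <|t_hat(q)|^2> = 1 / (Kd q^4 + Ke)

with A = Lx*Ly the projected box area and the package's spectral
convention h_hat(q) = (1/N) sum_r h(r) e^{-iq.r}. The q = 0 mode is always
zero: the theory describes fluctuations about the mean plane, and fields
are mean-free by construction.

Each frame is an independent draw — the generator reproduces the *equal-
time* statistics of an equilibrated membrane, not its dynamics. A separate
AR(1) series generator provides time-correlated scalar observables for
exercising the convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

import numpy as np

from .errors import ParameterError, SizeError
from .fields import GridField, MarkerFrame

__all__ = [
    "SyntheticSpec",
    "RandomStream",
    "sample_height_field",
    "sample_height_ensemble",
    "sample_thickness_field",
    "sample_thickness_ensemble",
    "sample_correlated_series",
    "beads_from_surfaces",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic Helfrich membrane ensemble.

    Attributes
    ----------
    Kc
        Bending rigidity, k_BT. Sets the amplitude of height undulations.
    Kd
        Peristaltic elastic rigidity, k_BT (coefficient of q^4 in the
        thickness spectrum).
    Ke
        Harmonic leaflet-separation force constant, k_BT nm^-4; the
        low-q thickness spectrum asymptotes to 1/Ke.
    box_lengths
        (Lx, Ly), nm.
    grid_spacing
        Target grid spacing, nm (default 0.5, the standard surface grid).
        Actual spacing is Lx/Nx with Nx = round(Lx/spacing).
    n_frames
        Number of independent frames in the ensemble.
    mean_thickness
        Mean bilayer thickness, nm (MARTINI-like bilayers sit near 4 nm).
    seed
        RNG seed used when no explicit RandomStream is supplied.
    """

    Kc: float = 25.0
    Kd: float = 2.4
    Ke: float = 26.7
    box_lengths: Tuple[float, float] = (50.0, 50.0)
    grid_spacing: float = 0.5
    n_frames: int = 1
    mean_thickness: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lx, ly = self.box_lengths
        if not (lx > 0 and ly > 0):
            raise ParameterError(f"box lengths must be positive, got {self.box_lengths}")
        if not (self.grid_spacing > 0):
            raise ParameterError("grid_spacing must be positive")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        nx, ny = self.grid_shape
        if nx < 4 or ny < 4:
            raise SizeError(f"grid {nx}x{ny} too small; need at least 4x4")

    @property
    def grid_shape(self) -> Tuple[int, int]:
        lx, ly = self.box_lengths
        return (int(round(lx / self.grid_spacing)), int(round(ly / self.grid_spacing)))

    @property
    def area(self) -> float:
        return float(self.box_lengths[0] * self.box_lengths[1])


@dataclass
class RandomStream:
    """Seeded random source; identical seed => bit-identical draws."""

    seed: int = 0
    algorithm: str = "PCG64"
    _gen: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.algorithm != "PCG64":
            raise ParameterError(f"unsupported RNG algorithm {self.algorithm!r}")
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    @property
    def generator(self) -> np.random.Generator:
        return self._gen

    def spawn(self, key: int) -> "RandomStream":
        """Independent child stream, deterministic in (seed, key)."""
        child = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        rs = RandomStream.__new__(RandomStream)
        rs.seed = self.seed
        rs.algorithm = self.algorithm
        rs._gen = np.random.Generator(np.random.PCG64(child))
        return rs


def _mode_sigma(spec: SyntheticSpec, kind: str) -> np.ndarray:
    """Per-mode standard-deviation filter sqrt(N * Var|h_hat(q)|^2)...

    Returns the array s(q) such that filtering FFT'd unit white noise by
    s(q) yields fields with exactly the target per-mode variances.
    """
    nx, ny = spec.grid_shape
    lx, ly = spec.box_lengths
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
    q2 = qx[:, None] ** 2 + qy[None, :] ** 2
    n = nx * ny
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "height":
            var = 1.0 / (spec.area * spec.Kc * q2**2)
        else:
            denom = spec.area * (spec.Kd * q2**2 + spec.Ke)
            var = np.where(np.isinf(denom), 0.0, 1.0 / denom)
    var[0, 0] = 0.0  # q = 0: fields fluctuate about a zero mean plane
    return np.sqrt(n * var)


def _sample_fields(spec: SyntheticSpec, rng: RandomStream, kind: str, n_frames: int) -> np.ndarray:
    """Draw (n_frames, Nx, Ny) mean-free Gaussian fields with Helfrich spectra.

    White Gaussian noise is shaped in Fourier space; because the filter is
    real and inversion-symmetric the result is exactly real and Hermitian
    symmetry holds by construction.
    """
    nx, ny = spec.grid_shape
    sigma = _mode_sigma(spec, kind)
    w = rng.generator.standard_normal((n_frames, nx, ny))
    hq = np.fft.fft2(w, axes=(-2, -1)) * sigma
    return np.fft.ifft2(hq, axes=(-2, -1)).real


def _validate_height_spec(spec: SyntheticSpec) -> None:
    if not np.isfinite(spec.Kc) or spec.Kc <= 0:
        raise ParameterError(f"Kc must be finite and positive, got {spec.Kc}")


def _validate_thickness_spec(spec: SyntheticSpec) -> None:
    if spec.Kd < 0 or spec.Ke < 0:
        raise ParameterError("Kd and Ke must be non-negative")
    if spec.Kd == 0 and spec.Ke == 0:
        raise ParameterError("Kd and Ke cannot both be zero")


def sample_height_field(spec: SyntheticSpec, rng: RandomStream | None = None) -> GridField:
    """One periodic height field with exact Helfrich mode variances.

    Fourier coefficients are independent complex Gaussians with
    A <|h_hat(q)|^2> = 1/(Kc q^4) for q != 0 and h_hat(0) = 0.
    """
    _validate_height_spec(spec)
    rng = rng if rng is not None else RandomStream(spec.seed)
    values = _sample_fields(spec, rng, "height", 1)[0]
    return GridField(values, spec.box_lengths, kind="height")


def sample_height_ensemble(
    spec: SyntheticSpec, rng: RandomStream | None = None, n_frames: int | None = None
) -> Iterator[GridField]:
    """Stream of independent height-field frames (chunked internally)."""
    _validate_height_spec(spec)
    rng = rng if rng is not None else RandomStream(spec.seed)
    total = spec.n_frames if n_frames is None else int(n_frames)
    chunk = max(1, min(total, int(4e6 / max(1, spec.grid_shape[0] * spec.grid_shape[1]))))
    done = 0
    while done < total:
        k = min(chunk, total - done)
        block = _sample_fields(spec, rng, "height", k)
        for i in range(k):
            yield GridField(block[i], spec.box_lengths, kind="height", time=float(done + i))
        done += k


def sample_thickness_field(spec: SyntheticSpec, rng: RandomStream | None = None) -> GridField:
    """One periodic thickness field t = mean_thickness + dt.

    Fluctuation modes obey A <|dt_hat(q)|^2> = 1/(Kd q^4 + Ke), q != 0.
    """
    _validate_thickness_spec(spec)
    rng = rng if rng is not None else RandomStream(spec.seed)
    values = spec.mean_thickness + _sample_fields(spec, rng, "thickness", 1)[0]
    return GridField(
        values, spec.box_lengths, kind="thickness", mean_value=spec.mean_thickness
    )


def sample_thickness_ensemble(
    spec: SyntheticSpec, rng: RandomStream | None = None, n_frames: int | None = None
) -> Iterator[GridField]:
    """Stream of independent thickness-field frames."""
    _validate_thickness_spec(spec)
    rng = rng if rng is not None else RandomStream(spec.seed)
    total = spec.n_frames if n_frames is None else int(n_frames)
    chunk = max(1, min(total, int(4e6 / max(1, spec.grid_shape[0] * spec.grid_shape[1]))))
    done = 0
    while done < total:
        k = min(chunk, total - done)
        block = _sample_fields(spec, rng, "thickness", k)
        for i in range(k):
            yield GridField(
                spec.mean_thickness + block[i],
                spec.box_lengths,
                kind="thickness",
                time=float(done + i),
                mean_value=spec.mean_thickness,
            )
        done += k


def sample_correlated_series(
    n: int, rho: float, sigma: float, rng: RandomStream | None = None
) -> np.ndarray:
    """Stationary AR(1) series: mean 0, marginal variance sigma^2.

    x_0 ~ N(0, sigma^2); x_t = rho x_{t-1} + sigma sqrt(1-rho^2) eps_t.
    Statistical inefficiency of the series is (1+rho)/(1-rho) in closed
    form, which makes it the reference fixture for the convergence module.
    """
    if not abs(rho) < 1:
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    if n < 2:
        raise SizeError("need n >= 2")
    rng = rng if rng is not None else RandomStream(0)
    if sigma == 0:
        return np.zeros(n)
    eps = rng.generator.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * eps[0]
    c = sigma * np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + c * eps[t]
    return x


def beads_from_surfaces(
    height: GridField,
    thickness: GridField,
    beads_per_leaflet: int,
    jitter: float = 0.0,
    rng: RandomStream | None = None,
) -> MarkerFrame:
    """Sample a headgroup-marker point cloud on a pair of leaflet surfaces.

    (x, y) positions are uniform in the box; upper-leaflet markers sit at
    z = h + t/2 (+ Gaussian noise of sd ``jitter``), lower at z = h - t/2.
    The bilayer is centred at Lz/2 so wrapped coordinates stay contiguous.
    The first ``beads_per_leaflet`` rows of the returned frame are the
    upper leaflet, the rest the lower (ground-truth labels for tests).
    """
    if height.shape != thickness.shape or height.box_lengths != thickness.box_lengths:
        raise SizeError("height and thickness grids must match")
    if beads_per_leaflet < 16:
        raise SizeError("need at least 16 beads per leaflet")
    if jitter < 0:
        raise ParameterError("jitter must be >= 0")
    rng = rng if rng is not None else RandomStream(0)
    gen = rng.generator
    lx, ly = height.box_lengths

    pts = []
    for sign in (+1.0, -1.0):
        xy = gen.uniform((0.0, 0.0), (lx, ly), size=(beads_per_leaflet, 2))
        z = height.evaluate(xy) + 0.5 * sign * thickness.evaluate(xy)
        if jitter > 0:
            z = z + jitter * gen.standard_normal(beads_per_leaflet)
        pts.append(np.column_stack([xy, z]))
    xyz = np.vstack(pts)

    span = float(np.max(np.abs(xyz[:, 2]))) if xyz.size else 1.0
    lz = max(2.0 * span + 4.0, 10.0)
    xyz[:, 2] += 0.5 * lz
    xyz[:, 0] %= lx
    xyz[:, 1] %= ly
    xyz[:, 2] %= lz
    return MarkerFrame(xyz, (lx, ly, lz), time=height.time)
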