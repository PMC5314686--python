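"""Protein lateral organisation: 2D RDFs, area density, rigidity trends.

Protein positions are represented by their xy centroids (rotation-robust).
The radial distribution function g(r) uses minimum-image in-plane pair
distances, normalised per frame by the ideal-gas expectation at that
frame's density, so clustering shows up as g > 1 peaks and g -> 1 at
large r for an unstructured system.

Protein area fraction is inferred from the simulation box area and the
lipid count: the lipids of one leaflet cover (n_lipids/2) * APL where APL
is the area per lipid of a matched protein-free control; whatever box
area is left is attributed to protein. The box area is averaged over a
trailing window (default the last 20% of the run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence, Tuple

import numpy as np

from .errors import ParameterError, SizeError

__all__ = [
    "RadialDistribution",
    "AreaDensityEstimate",
    "radial_distribution_2d",
    "protein_area_density",
    "rigidity_density_trend",
]


@dataclass
class RadialDistribution:
    """2D radial distribution function averaged over frames."""

    r: np.ndarray              # bin centers, nm
    g: np.ndarray
    pair_counts: np.ndarray    # raw pair counts per bin (all frames)
    n_particles: int
    n_frames: int
    mean_area: float           # nm^2


@dataclass
class AreaDensityEstimate:
    """Protein area fraction inferred from box area and lipid count."""

    fraction: float
    mean_box_area: float       # nm^2, over the trailing window
    area_per_lipid: float      # nm^2, per-leaflet reference
    n_lipids: int              # both leaflets
    meta: dict = dc_field(default_factory=dict)


def _min_image_distances(xy: np.ndarray, box: Tuple[float, float]) -> np.ndarray:
    """Unordered minimum-image pair distances in the xy plane."""
    d = xy[:, None, :] - xy[None, :, :]
    for k in (0, 1):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    dist = np.sqrt((d**2).sum(axis=-1))
    iu = np.triu_indices(len(xy), k=1)
    return dist[iu]


def radial_distribution_2d(
    frames: Sequence[np.ndarray],
    boxes: Sequence[Tuple[float, float]],
    bin_width: float,
    r_max: float | None = None,
) -> RadialDistribution:
    """g(r) of 2D point sets over frames with periodic minimum image.

    ``frames[i]`` is an (N_i, 2) array of positions (nm) in box
    ``boxes[i]``. Bins extend to half the smallest box edge (distances
    beyond it are ambiguous under minimum image); a larger requested
    ``r_max`` is truncated with a warning.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if len(frames) == 0 or len(frames) != len(boxes):
        raise SizeError("need matching, non-empty frames and boxes")
    half_min = min(min(b) for b in boxes) / 2.0
    if r_max is None:
        r_max = half_min
    elif r_max > half_min:
        warnings.warn(
            f"r_max={r_max} nm exceeds half the smallest box edge; truncated to {half_min} nm",
            stacklevel=2,
        )
        r_max = half_min
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if len(edges) < 2:
        raise ParameterError("bin_width too large for the box")
    nbins = len(edges) - 1

    counts = np.zeros(nbins)
    ideal = np.zeros(nbins)
    n_particles = 0
    areas = []
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    for xy, box in zip(frames, boxes):
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 2:
            raise SizeError("each frame needs an (N>=2, 2) position array")
        area = float(box[0] * box[1])
        areas.append(area)
        n = len(xy)
        n_particles = max(n_particles, n)
        dist = _min_image_distances(xy, box)
        counts += np.histogram(dist, bins=edges)[0]
        # ideal-gas expectation at this frame's density
        ideal += (n * (n - 1) / 2.0) * annulus / area
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialDistribution(
        r=centers,
        g=g,
        pair_counts=counts,
        n_particles=n_particles,
        n_frames=len(frames),
        mean_area=float(np.mean(areas)),
    )


def protein_area_density(
    box_areas: Sequence[float],
    n_lipids: int,
    area_per_lipid_ref: float,
    window: float = 0.2,
) -> AreaDensityEstimate:
    """Protein area fraction from the trailing-window mean box area.

    fraction = 1 - (n_lipids/2 * APL_ref) / <A>_window. ``n_lipids``
    counts both leaflets; ``area_per_lipid_ref`` is the per-leaflet area
    per lipid of a matched protein-free control (nm^2). Negative values
    (control covers more than the box) clamp to 0 with a warning.
    """
    areas = np.asarray(box_areas, dtype=float)
    if area_per_lipid_ref <= 0:
        raise ParameterError("area_per_lipid_ref must be positive")
    if not (0 < window <= 1):
        raise ParameterError("window must lie in (0, 1]")
    if n_lipids < 2:
        raise ParameterError("need at least 2 lipids (one per leaflet)")
    if len(areas) == 0:
        raise SizeError("trailing window contains no frames")
    k = max(1, int(round(window * len(areas))))
    tail = areas[len(areas) - k :]
    mean_area = float(tail.mean())
    lipid_area = (n_lipids / 2.0) * area_per_lipid_ref
    fraction = 1.0 - lipid_area / mean_area
    if fraction < 0:
        warnings.warn(
            f"inferred lipid area exceeds the box area (fraction {fraction:.3f}); clamping to 0",
            stacklevel=2,
        )
        fraction = 0.0
    return AreaDensityEstimate(
        fraction=float(fraction),
        mean_box_area=mean_area,
        area_per_lipid=float(area_per_lipid_ref),
        n_lipids=int(n_lipids),
        meta={
            "window": window,
            "n_frames_window": k,
            "convention": "n_lipids counts both leaflets; APL is per-leaflet",
        },
    )


def rigidity_density_trend(
    points: Sequence[Tuple[float, float, float]],
) -> Tuple[float, float, float]:
    """Inverse-variance-weighted line of Kc vs protein area fraction.

    ``points`` is a list of (area_fraction, Kc, Kc_se). Returns
    (slope, intercept, slope_se). Zero/invalid SEs fall back to an
    unweighted fit with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise SizeError("need at least 3 (fraction, Kc, Kc_se) points")
    x, y, se = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.any(se <= 0):
        warnings.warn("non-positive Kc uncertainties: falling back to an unweighted fit",
                      stacklevel=2)
        w = np.ones_like(se)
    else:
        w = 1.0 / se**2
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ParameterError("all area fractions identical: slope undefined")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    slope_se = float(np.sqrt(1.0 / sxx))
    return float(slope), float(intercept), slope_se
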