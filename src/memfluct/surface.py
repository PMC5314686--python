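"""Monge-gauge surface extraction from headgroup-marker point clouds.

Per frame: split the markers into upper/lower leaflets by their z
coordinate, interpolate each leaflet's scattered z-values onto a regular
periodic grid (cubic, 0.5 nm default spacing — the standard choice for
bilayer surface analysis), and combine the two leaflet grids into a
height field h = (upper + lower)/2 and a thickness field t = upper - lower.

Scattered cubic interpolants are not natively periodic; periodicity is
enforced by tiling the input points over the 8 neighbouring images before
interpolating and cropping to the primary cell.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import cKDTree

from .errors import (
    AmbiguousLeafletError,
    InvertedLeafletError,
    ParameterError,
    SizeError,
)
from .fields import GridField, LeafletPair, MarkerFrame

__all__ = [
    "assign_leaflets",
    "grid_interpolate",
    "fields_from_leaflets",
    "frame_to_fields",
    "SparseCoverageWarning",
]


class SparseCoverageWarning(UserWarning):
    """Some grid nodes are far from every input point."""


def assign_leaflets(frame: MarkerFrame) -> LeafletPair:
    """Split markers into leaflets by sign of z - median(z).

    The frame's z coordinates are first re-centred on their circular mean
    (so a bilayer wrapped across the periodic z boundary stays contiguous)
    and then split at the median. Geometries whose two z-populations
    overlap by more than half of the thinner population's range are
    rejected: that regime (strong curvature, non-Monge) cannot be split by
    a plane and silent mis-assignment would corrupt every later stage.
    """
    lz = frame.box_lengths[2]
    z = frame.positions[:, 2]
    # circular re-centring: place the population's mean angle at Lz/2
    ang = 2.0 * np.pi * z / lz
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    shift = lz / 2.0 - mean_ang * lz / (2.0 * np.pi)
    zc = (z + shift) % lz

    med = np.median(zc)
    upper_idx = zc > med
    lower_idx = ~upper_idx
    if upper_idx.sum() < 8 or lower_idx.sum() < 8:
        raise AmbiguousLeafletError(
            f"leaflet split gives {upper_idx.sum()}/{lower_idx.sum()} markers; need >= 8 each"
        )

    zu, zl = zc[upper_idx], zc[lower_idx]
    overlap = min(zu.max(), zl.max()) - max(zu.min(), zl.min())
    smaller = max(min(np.ptp(zu), np.ptp(zl)), 1e-12)
    if overlap > 0.5 * smaller:
        raise AmbiguousLeafletError(
            "upper/lower z-ranges overlap by more than 50%: geometry is not "
            "separable into two planar leaflets (extreme curvature?)"
        )

    pos = frame.positions.copy()
    pos[:, 2] = (zc - shift) % lz  # undo the shift; keep original frame z
    return LeafletPair(
        upper=pos[upper_idx],
        lower=pos[lower_idx],
        box_lengths=frame.box_lengths,
        time=frame.time,
    )


def _unwrap_z(points: np.ndarray, lz: float) -> np.ndarray:
    """Unwrap one leaflet's z across the periodic boundary (if split)."""
    z = points[:, 2]
    if np.ptp(z) <= 0.5 * lz:
        return points
    out = points.copy()
    ang = 2.0 * np.pi * z / lz
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    center = mean_ang * lz / (2.0 * np.pi)
    out[:, 2] = z - lz * np.round((z - center) / lz)
    return out


def grid_interpolate(
    points: np.ndarray,
    box_lengths: Tuple[float, float],
    spacing: float = 0.5,
) -> GridField:
    """Interpolate scattered (x, y, z) points onto a regular periodic grid.

    Piecewise-cubic (Clough-Tocher) interpolation over the points tiled
    into the 8 neighbouring periodic images; every grid node receives a
    finite value, so regions without markers (e.g. under an embedded
    protein) are bridged smoothly by the interpolant. Nodes farther than
    max(5*spacing, 3x the typical nearest-neighbour distance) from every
    input point trigger a ``SparseCoverageWarning``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise SizeError("points must be an (N, 3) array")
    if points.shape[0] < 8:
        raise SizeError(f"need at least 8 points, got {points.shape[0]}")
    if not np.all(np.isfinite(points)):
        raise ParameterError("points contain non-finite values")
    lx, ly = float(box_lengths[0]), float(box_lengths[1])
    if not (spacing > 0 and spacing < min(lx, ly) / 4):
        raise ParameterError(
            f"spacing {spacing} must be positive and < min(Lx, Ly)/4"
        )

    xy = points[:, :2] % (lx, ly)
    z = points[:, 2]

    nx, ny = int(round(lx / spacing)), int(round(ly / spacing))
    gx = np.arange(nx) * (lx / nx)
    gy = np.arange(ny) * (ly / ny)

    tiles = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            tiles.append(xy + np.array([sx * lx, sy * ly]))
    xy_tiled = np.vstack(tiles)
    z_tiled = np.tile(z, 9)

    interp = CloughTocher2DInterpolator(xy_tiled, z_tiled)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    nodes = np.column_stack([gxx.ravel(), gyy.ravel()])
    values = interp(nodes).reshape(nx, ny)
    if np.any(~np.isfinite(values)):  # nodes outside the tiled hull (rare)
        from scipy.interpolate import NearestNDInterpolator

        bad = ~np.isfinite(values)
        values[bad] = NearestNDInterpolator(xy_tiled, z_tiled)(nodes[bad.ravel()])

    tree = cKDTree(xy_tiled)
    dist, _ = tree.query(nodes, k=1)
    nn_tree = cKDTree(xy)
    typical = float(np.median(nn_tree.query(xy, k=2)[0][:, 1])) if len(xy) > 1 else spacing
    threshold = max(5.0 * spacing, 3.0 * typical)
    if np.any(dist > threshold):
        warnings.warn(
            f"{int(np.sum(dist > threshold))} grid nodes farther than "
            f"{threshold:.2f} nm from every marker: surface is extrapolated there",
            SparseCoverageWarning,
            stacklevel=2,
        )

    return GridField(values, (lx, ly))


def fields_from_leaflets(
    upper_grid: GridField, lower_grid: GridField
) -> Tuple[GridField, GridField]:
    """Combine leaflet grids into (height, thickness) fields.

    height = (upper + lower)/2, spatial mean subtracted; thickness =
    upper - lower, spatial mean subtracted from the field but retained in
    ``mean_value`` metadata. Any non-positive thickness value means the
    leaflets crossed and is a hard error.
    """
    if upper_grid.shape != lower_grid.shape or upper_grid.box_lengths != lower_grid.box_lengths:
        raise SizeError("upper and lower grids must have identical shape and box")
    up, lo = upper_grid.values, lower_grid.values
    t_raw = up - lo
    if np.any(t_raw <= 0):
        raise InvertedLeafletError(
            "thickness <= 0 at some grid nodes: leaflets inverted or mis-assigned"
        )
    h_raw = 0.5 * (up + lo)
    t_mean = float(t_raw.mean())
    height = GridField(
        h_raw - h_raw.mean(),
        upper_grid.box_lengths,
        kind="height",
        time=upper_grid.time,
    )
    thickness = GridField(
        t_raw - t_mean,
        upper_grid.box_lengths,
        kind="thickness",
        time=upper_grid.time,
        mean_value=t_mean,
    )
    return height, thickness


def _recenter_bilayer(pair: LeafletPair, lz: float) -> Tuple[np.ndarray, np.ndarray]:
    """Shift both leaflets by one joint circular offset so z is contiguous.

    Only relative heights matter downstream (the height field is
    mean-subtracted, thickness is a difference), so a rigid z-shift of the
    whole bilayer is free.
    """
    z = np.concatenate([pair.upper[:, 2], pair.lower[:, 2]])
    ang = 2.0 * np.pi * z / lz
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    shift = lz / 2.0 - mean_ang * lz / (2.0 * np.pi)
    up, lo = pair.upper.copy(), pair.lower.copy()
    up[:, 2] = (up[:, 2] + shift) % lz
    lo[:, 2] = (lo[:, 2] + shift) % lz
    return up, lo


def frame_to_fields(
    frame: MarkerFrame, spacing: float = 0.5
) -> Tuple[GridField, GridField]:
    """One-call extraction: markers -> leaflets -> grids -> (h, t) fields."""
    pair = assign_leaflets(frame)
    lz = frame.box_lengths[2]
    up_pts, lo_pts = _recenter_bilayer(pair, lz)
    upper = grid_interpolate(_unwrap_z(up_pts, lz), frame.box_lengths[:2], spacing)
    lower = grid_interpolate(_unwrap_z(lo_pts, lz), frame.box_lengths[:2], spacing)
    upper.time = lower.time = frame.time
    height, thickness = fields_from_leaflets(upper, lower)
    return height, thickness
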