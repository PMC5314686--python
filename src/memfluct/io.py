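"""File formats and trajectory plumbing.

* Gridded fields: a plain-text format, one file per frame, with a header
  carrying Nx, Ny, Lx, Ly, kind, time and mean value; full float
  precision so write -> read round-trips numerically bit-exactly.
* Power spectra / Kc series: TSV with a provenance header (config hash,
  code version) that likewise round-trips exactly.
* Marker coordinates: GRO/PDB topology plus XTC/TRR/DCD trajectories via
  MDAnalysis; package units are nm (MDAnalysis speaks angstrom
  internally, converted at this boundary).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import __version__
from .errors import ParameterError, SizeError, ValidationError
from .fields import GridField, MarkerFrame
from .spectra import PowerSpectrum
from .synthetic import SyntheticSpec

__all__ = [
    "TrajectorySource",
    "write_grid",
    "read_grid",
    "write_spec_sidecar",
    "read_spec_sidecar",
    "write_markers_gro",
    "load_marker_trajectory",
    "write_spectrum_table",
    "read_spectrum_table",
    "config_hash",
]

GRID_MAGIC = "# memfluct-grid 1"


@dataclass
class TrajectorySource:
    """Where and how to read marker coordinates.

    ``selection`` is an MDAnalysis particle-name pattern; "PO4" matches
    the coarse-grained phosphate bead, "P" the atomistic phosphorus.
    """

    topology: str
    trajectories: Sequence[str] = ()
    selection: str = "PO4"
    stride: int = 1
    first: int = 0
    last: int | None = None

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if not Path(self.topology).exists():
            raise ValidationError(f"topology file not found: {self.topology}")
        for t in self.trajectories:
            if not Path(t).exists():
                raise ValidationError(f"trajectory file not found: {t}")


# ---------------------------------------------------------------- grids


def write_grid(field: GridField, path: str | Path) -> None:
    """Write one GridField in the package's text grid format."""
    path = Path(path)
    nx, ny = field.shape
    lx, ly = field.box_lengths
    with path.open("w") as fh:
        fh.write(GRID_MAGIC + "\n")
        fh.write(f"# kind: {field.kind}\n")
        fh.write(f"# Nx Ny: {nx} {ny}\n")
        fh.write(f"# Lx Ly: {float(lx)!r} {float(ly)!r}\n")
        fh.write(f"# time_ps: {float(field.time)!r}\n")
        fh.write(f"# mean_nm: {float(field.mean_value)!r}\n")
        np.savetxt(fh, field.values, fmt="%.17e")


def read_grid(path: str | Path) -> GridField:
    """Read a GridField written by :func:`write_grid`."""
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != GRID_MAGIC:
            raise ValidationError(f"{path} is not a memfluct grid file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        values = np.loadtxt(fh)
    nx, ny = (int(v) for v in header["Nx Ny"].split())
    lx, ly = (float(v) for v in header["Lx Ly"].split())
    values = values.reshape(nx, ny)
    return GridField(
        values,
        (lx, ly),
        kind=header.get("kind", "height"),  # type: ignore[arg-type]
        time=float(header.get("time_ps", 0.0)),
        mean_value=float(header.get("mean_nm", 0.0)),
    )


def write_spec_sidecar(spec: SyntheticSpec, path: str | Path) -> None:
    """JSON sidecar describing a synthetic ensemble."""
    payload = asdict(spec)
    payload["box_lengths"] = list(spec.box_lengths)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_spec_sidecar(path: str | Path) -> SyntheticSpec:
    payload = json.loads(Path(path).read_text())
    payload["box_lengths"] = tuple(payload["box_lengths"])
    return SyntheticSpec(**payload)


# ----------------------------------------------------------- coordinates


def write_markers_gro(frame: MarkerFrame, path: str | Path, name: str = "PO4") -> None:
    """Write a MarkerFrame as a GRO coordinate file (positions in nm).

    Each marker becomes one bead of residue MEM named ``name``; GRO
    stores fixed-point nm with 3 decimals, so positions round-trip to
    1e-3 nm.
    """
    import MDAnalysis as mda

    n = frame.n_markers
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [name] * n)
    u.add_TopologyAttr("resnames", ["MEM"])
    u.add_TopologyAttr("resids", [1])
    u.atoms.positions = frame.positions * 10.0  # nm -> angstrom
    lx, ly, lz = frame.box_lengths
    u.dimensions = [lx * 10, ly * 10, lz * 10, 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def load_marker_trajectory(source: TrajectorySource) -> Iterator[MarkerFrame]:
    """Stream MarkerFrames from a topology (+ optional trajectories).

    Selected marker positions are wrapped into the primary box. Marker
    beads are single particles, so wrapping alone keeps them whole; the
    caller is expected to have removed broken-molecule artefacts from the
    raw trajectory beforehand.
    """
    import MDAnalysis as mda

    try:
        if source.trajectories:
            u = mda.Universe(source.topology, *source.trajectories)
        else:
            u = mda.Universe(source.topology)
    except Exception as err:
        raise ValidationError(f"could not read input files: {err}") from err

    sel = u.select_atoms(f"name {source.selection}")
    if sel.n_atoms == 0:
        raise ValidationError(
            f"selection 'name {source.selection}' matches no particles"
        )
    if sel.n_atoms < 16:
        raise SizeError(
            f"selection matches only {sel.n_atoms} particles; need >= 16"
        )

    stop = source.last
    for ts in u.trajectory[source.first : stop : source.stride]:
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValidationError("frame has no periodic box")
        box = ts.dimensions[:3].astype(float) / 10.0  # angstrom -> nm
        pos = sel.positions.astype(float) / 10.0
        pos %= box
        yield MarkerFrame(pos, tuple(float(b) for b in box), time=float(ts.time))


# ---------------------------------------------------------------- tables


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_spectrum_table(
    spectrum: PowerSpectrum, path: str | Path, config: dict | None = None
) -> None:
    """Serialize a PowerSpectrum as TSV with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# memfluct-spectrum 1\n")
        fh.write(f"# code_version: {__version__}\n")
        fh.write(f"# config_hash: {config_hash(config or {})}\n")
        fh.write(f"# kind: {spectrum.kind}\n")
        fh.write(f"# n_frames: {spectrum.n_frames}\n")
        fh.write(f"# shell_width: {float(spectrum.shell_width)!r}\n")
        fh.write("q_nm^-1\tintensity_nm^4\tcounts\n")
        for q, i, c in zip(spectrum.q, spectrum.intensity, spectrum.counts):
            fh.write(f"{float(q)!r}\t{float(i)!r}\t{int(c)}\n")


def read_spectrum_table(path: str | Path) -> PowerSpectrum:
    """Read back a spectrum table written by :func:`write_spectrum_table`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != "# memfluct-spectrum 1":
            raise ValidationError(f"{path} is not a memfluct spectrum table")
        for line in fh:
            if line.startswith("# "):
                key, _, val = line[2:].partition(":")
                header[key.strip()] = val.strip()
            elif line.startswith("q_"):
                continue
            elif line.strip():
                rows.append(line.split())
    arr = np.array(rows, dtype=float)
    return PowerSpectrum(
        q=arr[:, 0],
        intensity=arr[:, 1],
        counts=arr[:, 2].astype(int),
        n_frames=int(header.get("n_frames", 1)),
        kind=header.get("kind", "height"),  # type: ignore[arg-type]
        shell_width=float(header.get("shell_width", 0.0)),
    )
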