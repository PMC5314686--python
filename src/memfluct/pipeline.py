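"""End-to-end analysis pipeline: surfaces -> spectra -> fits -> diagnostics.

``run_pipeline`` drives the whole chain for either a trajectory source or
a synthetic ensemble specification, writing a deterministic result bundle
(JSON summary, TSV spectra and Kc series, resolved configuration) to an
output directory. Given the same seed and inputs the bundle is
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List

import numpy as np

from . import __version__
from .errors import ConfigurationError, MemfluctError
from .fields import GridField
from .fitting import (
    block_error,
    default_fit_window,
    fit_bending_rigidity,
    fit_thickness_moduli,
)
from .convergence import kc_timeseries
from .io import TrajectorySource, config_hash, load_marker_trajectory, write_spectrum_table
from .spectra import Spectrum2D, average_over_frames, power_spectrum_2d
from .surface import frame_to_fields
from .synthetic import (
    RandomStream,
    SyntheticSpec,
    sample_height_ensemble,
    sample_thickness_ensemble,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Temperature (K) is used only to convert fitted moduli from k_BT to
    joules in the report; every fit happens in k_BT units. 323 K is the
    usual coarse-grained membrane simulation temperature (313 K for
    PE/PG bilayers).
    """

    grid_spacing: float = 0.5       # nm
    shell_width: float | None = None  # nm^-1; None = auto per box
    q_max: float | None = None        # nm^-1; None = patch-size rule
    n_bins: int = 100
    n_blocks: int = 5
    seed: int = 0
    temperature: float = 323.0      # K
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if self.shell_width is not None and self.shell_width <= 0:
            raise ConfigurationError("shell_width must be positive")
        if self.q_max is not None:
            if self.q_max <= 0:
                raise ConfigurationError("q_max must be positive")
            nyquist = np.pi / self.grid_spacing
            if self.q_max > nyquist:
                raise ConfigurationError(
                    f"q_max={self.q_max} nm^-1 beyond the grid Nyquist {nyquist:.3f} nm^-1"
                )
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.n_bins < 1 or self.n_blocks < 5:
            raise ConfigurationError("need n_bins >= 1 and n_blocks >= 5")


@dataclass
class PipelineResult:
    """In-memory result bundle of one pipeline run."""

    summary: dict
    height_spectrum: object
    thickness_spectrum: object | None
    kc_series: object | None
    config: RunConfig
    output_dir: Path | None = None
    _extras: dict = field(default_factory=dict)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(
    config: RunConfig,
    source: TrajectorySource | SyntheticSpec,
) -> PipelineResult:
    """Run extraction, spectra, elastic fits and convergence diagnostics.

    For a :class:`SyntheticSpec` the height and thickness ensembles are
    generated (seeded from ``config.seed``); for a
    :class:`TrajectorySource` marker frames are read and turned into
    surfaces. Raises stage-tagged :class:`MemfluctError` subclasses on
    hard failures.
    """
    height_specs: List[Spectrum2D] = []
    thickness_specs: List[Spectrum2D] = []
    box = None

    if isinstance(source, SyntheticSpec):
        rng = RandomStream(config.seed)
        for f in sample_height_ensemble(source, rng.spawn(0)):
            height_specs.append(power_spectrum_2d(f))
        for f in sample_thickness_ensemble(source, rng.spawn(1)):
            f2 = GridField(
                f.values - f.values.mean(),
                f.box_lengths,
                kind="thickness",
                time=f.time,
                mean_value=f.mean_value,
            )
            thickness_specs.append(power_spectrum_2d(f2))
        box = source.box_lengths
        n_frames = source.n_frames
    else:
        for frame in load_marker_trajectory(source):
            h, t = frame_to_fields(frame, spacing=config.grid_spacing)
            height_specs.append(power_spectrum_2d(h))
            thickness_specs.append(power_spectrum_2d(t))
            box = h.box_lengths
        if not height_specs:
            raise MemfluctError("trajectory produced no frames")
        n_frames = len(height_specs)

    q_max = config.q_max if config.q_max is not None else default_fit_window(box)

    h_spec = average_over_frames(height_specs, config.shell_width)
    h_fit = fit_bending_rigidity(h_spec, q_max)
    block_se = None
    if n_frames >= config.n_blocks:
        block_se, _ = block_error(
            height_specs, q_max, n_blocks=config.n_blocks, shell_width=config.shell_width
        )

    t_spec = t_fit = None
    if thickness_specs:
        t_spec = average_over_frames(thickness_specs, config.shell_width)
        try:
            t_fit = fit_thickness_moduli(t_spec)
        except MemfluctError:
            t_fit = None

    series = None
    n_bins = min(config.n_bins, n_frames)
    if n_bins >= 2:
        series = kc_timeseries(height_specs, q_max, n_bins=n_bins,
                               shell_width=config.shell_width)

    kbt_j = BOLTZMANN_J_PER_K * config.temperature
    summary = {
        "code_version": __version__,
        "n_frames": n_frames,
        "box_lengths_nm": list(box),
        "q_max_nm^-1": q_max,
        "Kc_kBT": h_fit.Kc,
        "Kc_se_kBT": h_fit.Kc_se,
        "Kc_block_se_kBT": block_se,
        "Kc_J": h_fit.Kc * kbt_j,
        "n_shells": h_fit.n_shells_used,
        "Kd_kBT": t_fit.Kd if t_fit else None,
        "Ke_kBT": t_fit.Ke if t_fit else None,
        "thickness_low_q_anomaly": t_fit.low_q_anomaly if t_fit else None,
        "temperature_K": config.temperature,
    }

    outdir = None
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        resolved = asdict(config)
        # the hash identifies the analysis, not where it was written
        hashed = {k: v for k, v in resolved.items() if k != "output_dir"}
        resolved["config_hash"] = config_hash(hashed)
        (outdir / "config.json").write_text(
            json.dumps(resolved, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        write_spectrum_table(h_spec, outdir / "height_spectrum.tsv", hashed)
        if t_spec is not None:
            write_spectrum_table(t_spec, outdir / "thickness_spectrum.tsv", hashed)
        if series is not None:
            with (outdir / "kc_series.tsv").open("w") as fh:
                fh.write("bin_start\tbin_end\tKc_kBT\tok\n")
                for a, b, kc, ok in zip(series.bin_start, series.bin_end, series.Kc, series.ok):
                    fh.write(f"{a:.0f}\t{b:.0f}\t{float(kc)!r}\t{int(ok)}\n")

    return PipelineResult(
        summary=summary,
        height_spectrum=h_spec,
        thickness_spectrum=t_spec,
        kc_series=series,
        config=config,
        output_dir=outdir,
        _extras={"height_fit": h_fit, "thickness_fit": t_fit},
    )
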