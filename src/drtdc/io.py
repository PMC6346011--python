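"""Frame reading, result writing, and run configuration.

The canonical frame inputs are multi-page TIFF stacks or directories of
numbered PNG frames; both come back as a :class:`~drtdc.imaging.FrameStream`
with fps and pixel size attached (reading fails loudly when those are
missing).  Results are written as a tidy CSV plus an HDF5 container holding
the per-frame traces, together with a JSON manifest carrying the
configuration hash and software version so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .imaging import FrameStream
from .rheology import (BufferViscosityModel, ChannelConfig, BUFFER_MC_06,
                       BUFFER_MC_10, ViscoelasticResult,
                       load_calibration_table)
from .shape_modes import DeformationTrace

__all__ = ["RunConfig", "read_frames", "write_results", "load_config",
           "FormatError"]


class FormatError(ValueError):
    """Unreadable or inconsistent input data; message names the file."""


@dataclass
class RunConfig:
    """Everything needed to re-run an analysis."""

    pixel_size_um: float = 0.34
    fps: float = 4000.0
    inlet_x_px: float = 150.0
    outlet_x_px: float | None = None
    cross_section_um: float = 30.0
    channel_length_um: float = 300.0
    flow_rate_nl_s: float = 8.0
    buffer_model: str = "1.0mc"          # "0.6mc" or "1.0mc" methylcellulose
    mean_surface_stress_pa: float = 142.0
    mean_shear_rate_s: float = 5100.0
    r2_cutoff: float = 0.6
    calibration_table_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "fps", "cross_section_um",
                     "channel_length_um", "flow_rate_nl_s",
                     "mean_surface_stress_pa", "mean_shear_rate_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.buffer_model not in ("0.6mc", "1.0mc"):
            raise ValueError("buffer_model must be '0.6mc' or '1.0mc'")

    @property
    def buffer(self) -> BufferViscosityModel:
        return BUFFER_MC_06 if self.buffer_model == "0.6mc" else BUFFER_MC_10

    def channel_config(self) -> ChannelConfig:
        table = None
        if self.calibration_table_path:
            p = Path(self.calibration_table_path)
            if not p.exists():
                raise FormatError(f"calibration table not found: {p}")
            table = load_calibration_table(p)
        return ChannelConfig(
            cross_section_um=self.cross_section_um,
            channel_length_um=self.channel_length_um,
            flow_rate_nl_s=self.flow_rate_nl_s,
            mean_surface_stress_pa=self.mean_surface_stress_pa,
            mean_shear_rate_s=self.mean_shear_rate_s,
            buffer=self.buffer, r2_cutoff=self.r2_cutoff,
            calibration_table=table)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"config {path} is not a mapping")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# frame input
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def read_frames(path: str | Path, fps: float | None = None,
                pixel_size_um: float | None = None) -> FrameStream:
    """Load a TIFF stack or a directory of numbered PNG frames.

    fps and pixel size must come either from a JSON metadata sidecar
    (``<stem>.json`` or ``metadata.json`` with keys ``fps`` /
    ``pixel_size_um``) or from the arguments; missing values are an error.
    A gap in PNG numbering is reported with the missing index.  The optional
    TDMS instrument format needs the npTDMS package and raises an actionable
    error when it is absent.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such input: {p}")
    meta: dict = {}
    for cand in ([p.with_suffix(".json")] if p.is_file()
                 else [p / "metadata.json"]):
        if cand.exists():
            try:
                meta = json.loads(cand.read_text())
            except json.JSONDecodeError as exc:
                raise FormatError(f"malformed metadata sidecar {cand}: {exc}")
    fps = fps if fps is not None else meta.get("fps")
    pixel_size_um = (pixel_size_um if pixel_size_um is not None
                     else meta.get("pixel_size_um"))
    if fps is None or pixel_size_um is None:
        raise FormatError(
            f"{p}: fps and pixel_size_um required (argument or JSON sidecar)")

    if p.is_file() and p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        try:
            frames = tifffile.imread(p)
        except Exception as exc:
            raise FormatError(f"cannot read TIFF {p}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
    elif p.is_file() and p.suffix.lower() == ".tdms":
        try:
            import nptdms  # noqa: F401
        except ImportError:
            raise FormatError(
                f"{p}: reading TDMS requires the optional npTDMS package "
                "(pip install npTDMS), or convert the recording to TIFF")
        raise FormatError(f"{p}: TDMS layout not supported by this build")
    elif p.is_dir():
        import imageio.v3 as iio
        pngs = sorted(p.glob("*.png"))
        if not pngs:
            raise FormatError(f"{p}: no .png frames found")
        indices = []
        for f in pngs:
            m = _NUM_RE.search(f.stem)
            if not m:
                raise FormatError(f"{p}: frame {f.name} has no numeric index")
            indices.append(int(m.group(1)))
        order = np.argsort(indices)
        indices = [indices[i] for i in order]
        pngs = [pngs[i] for i in order]
        expected = range(indices[0], indices[0] + len(indices))
        for want, got in zip(expected, indices):
            if want != got:
                raise FormatError(f"{p}: missing frame index {want}")
        frames = np.stack([iio.imread(f) for f in pngs])
        if frames.ndim == 4:          # drop a trivial channel axis
            frames = frames[..., 0]
    else:
        raise FormatError(f"{p}: unsupported input (use TIFF stack or PNG dir)")
    return FrameStream(frames=frames, fps=float(fps),
                       pixel_size_um=float(pixel_size_um))


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["cell_id", "A_um2", "a0_um", "d_hat_inlet", "d_hat_channel",
                  "tau_inlet_ms", "tau_channel_ms", "r2_inlet", "r2_channel",
                  "E_pa", "eta_pas", "flags"]


def results_frame(results: Sequence[ViscoelasticResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "cell_id": r.cell_id, "A_um2": r.A_um2, "a0_um": r.a0_um,
            "d_hat_inlet": r.d_hat_inlet, "d_hat_channel": r.d_hat_channel,
            "tau_inlet_ms": (r.tau_inlet * 1e3 if r.tau_inlet else np.nan),
            "tau_channel_ms": r.tau_channel * 1e3,
            "r2_inlet": (r.r2_inlet if r.r2_inlet is not None else np.nan),
            "r2_channel": r.r2_channel,
            "E_pa": r.E, "eta_pas": r.eta, "flags": ";".join(r.flags)})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[ViscoelasticResult],
                  traces: Sequence[DeformationTrace],
                  out_dir: str | Path,
                  config: RunConfig | None = None) -> Path:
    """Write results CSV, per-frame trace container (HDF5) and manifest.

    Output is byte-stable for identical inputs: floats are serialized with
    repr-precision and the manifest holds the config digest and package
    version.  Returns the manifest path.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = results_frame(results)
    csv_path = out / "results.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")

    h5_path = out / "traces.h5"
    import h5py
    with h5py.File(h5_path, "w") as h5:
        h5.attrs["n_cells"] = len(traces)
        for tr in traces:
            g = h5.create_group(f"cell_{tr.cell_id}")
            for name in ("times", "z", "d_raw", "d_even", "d_odd", "a0"):
                g.create_dataset(name, data=getattr(tr, name))
            if tr.spectra:
                g.create_dataset(
                    "a", data=np.stack([s.a for s in tr.spectra]))
                g.create_dataset(
                    "b", data=np.stack([s.b for s in tr.spectra]))

    manifest = {
        "software": "drtdc",
        "version": __version__,
        "n_cells": len(df),
        "results_csv": csv_path.name,
        "traces_h5": h5_path.name,
        "config": (asdict(config) if config else None),
        "config_digest": (config.digest() if config else None),
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return man_path
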