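"""End-to-end glue: frames or contours -> deformation traces -> rheology.

Per cell: track -> convex-hull contours -> shape-mode decomposition ->
parity traces -> creep fits -> (E, eta).  Every rejection (short track,
collision, failed reconstruction, r^2 gate, calibration range) is counted
with its reason so dropped cells are accounted for in the run summary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import imaging, rheology, shape_modes as sm

__all__ = ["RunSummary", "analyze_trace", "analyze_contour_sequence",
           "analyze_stream"]


@dataclass
class RunSummary:
    n_tracks: int = 0
    n_accepted: int = 0
    rejections: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejections[reason.split(":")[0]] += 1


def analyze_trace(trace: sm.DeformationTrace,
                  cfg: rheology.ChannelConfig,
                  inlet_z: float = 0.0) -> rheology.ViscoelasticResult:
    """Fit one deformation trace and convert to material parameters."""
    outlet_z = inlet_z + cfg.channel_length_um
    d_hat_inlet, d_hat_channel, ch_fit, in_fit = rheology.extract_peaks(
        trace, inlet_z, outlet_z, cfg)
    flags = []
    if ch_fit.no_plateau:
        flags.append("no-plateau")
    if ch_fit.tau_at_bound:
        flags.append("tau-at-bound")
    a0 = float(np.median(trace.a0))
    E = rheology.young_modulus(d_hat_channel, a0, cfg)
    eta = rheology.apparent_viscosity(ch_fit.tau, E)
    area = np.pi * (a0 / 2.0) ** 2
    return rheology.ViscoelasticResult(
        cell_id=trace.cell_id, E=E, eta=eta,
        tau_inlet=(in_fit.tau if in_fit else None),
        tau_channel=ch_fit.tau,
        d_hat_inlet=d_hat_inlet, d_hat_channel=d_hat_channel,
        A_um2=area, a0_um=a0,
        r2_inlet=(in_fit.r2 if in_fit else None),
        r2_channel=ch_fit.r2, flags=flags)


def analyze_contour_sequence(contours: Sequence[np.ndarray],
                             times: Sequence[float], z: Sequence[float],
                             cfg: rheology.ChannelConfig,
                             cell_id: int | str = 0
                             ) -> rheology.ViscoelasticResult:
    """Analyze pre-extracted contours (micrometre coordinates, z at COM)."""
    trace = sm.decompose_trace(contours, times, z, cell_id=cell_id)
    return analyze_trace(trace, cfg)


def analyze_stream(stream: imaging.FrameStream,
                   cfg: rheology.ChannelConfig,
                   inlet_x_px: float,
                   summary: RunSummary | None = None,
                   **track_kwargs
                   ) -> tuple[list[rheology.ViscoelasticResult],
                              list[sm.DeformationTrace], RunSummary]:
    """Full pipeline on an image sequence.

    Returns per-cell results, the underlying deformation traces, and a
    summary with rejection counts.
    """
    summary = summary or RunSummary()
    clean, rejected = imaging.track_cells_full(stream, **track_kwargs)
    summary.n_tracks += len(clean) + len(rejected)
    for cell in rejected:
        summary.reject(cell.flag_reason or "tracking")
    results, traces = [], []
    s = stream.pixel_size_um
    for cell in clean:
        times = np.array([c.timestamp for c in cell.contours])
        z = cell.z_um(s, inlet_x_px)
        conts = []
        for c in cell.contours:
            v = c.vertices * s
            _, _, com = sm.polygon_geometry(v)
            conts.append(v - np.asarray(com))
        try:
            trace = sm.decompose_trace(conts, times, z, cell_id=cell.cell_id)
        except sm.ShapeError as exc:
            summary.reject(f"decomposition: {exc}")
            continue
        try:
            res = analyze_trace(trace, cfg)
        except rheology.FitRejection as exc:
            summary.reject(f"fit: {exc}")
            continue
        except rheology.CalibrationRangeError as exc:
            summary.reject(f"calibration: {exc}")
            continue
        results.append(res)
        traces.append(trace)
        summary.n_accepted += 1
    return results, traces, summary
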