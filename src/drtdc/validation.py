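"""Ground-truth recovery experiments on the synthetic world.

These are the package's own end-to-end checks: simulate cells with known
(E, eta), run the full chain (rendered frames -> tracking -> shape modes ->
creep fits -> look-up table), and compare the recovered parameters with the
ground truth.  Used by the validation tests and the acceptance script.

The (E, eta) design spans E in [0.1, 2] kPa and eta in [0.5, 10] Pa s with
pairings that keep tau = eta / E inside the creep-time window a 300 um
channel at these flow conditions can resolve (roughly 5-22 ms: a relaxation
much shorter than a few frame intervals or much longer than the transit
time is not identifiable from a single trace; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import imaging, pipeline, rheology as rh, shape_modes as sm
from . import synthetic as syn

__all__ = ["RECOVERY_COMBOS", "RecoveryResult", "recover_combo",
           "recovery_grid", "noisy_tau_recovery", "default_channel_config"]

#: (E_true [Pa], eta_true [Pa s]) pairs spanning both parameter ranges
#: inside the resolvable creep-time window.
RECOVERY_COMBOS = (
    (100.0, 0.5), (100.0, 2.24), (160.0, 1.06),
    (250.0, 2.24), (450.0, 2.24), (450.0, 10.0),
    (900.0, 4.7), (1400.0, 10.0), (2000.0, 10.0),
)


def default_channel_config() -> rh.ChannelConfig:
    """Channel constants plus the calibration table of the synthetic world."""
    return rh.ChannelConfig(
        calibration_table=rh.linear_elastic_table(142.0,
                                                  gain=syn.STRAIN_GAIN))


@dataclass
class RecoveryResult:
    E_true: float
    eta_true: float
    tau_true: float
    E_rel_err: float
    eta_rel_err: float
    tau_rel_err: float
    n_cells: int


def recover_combo(E_true: float, eta_true: float, n_replicates: int = 5,
                  seed: int = 7, noise_sd: float = 0.0,
                  cfg: rh.ChannelConfig | None = None) -> RecoveryResult:
    """Median recovery over replicate cells rendered to frames.

    Replicates share the material parameters; radius (2% jitter) and
    sub-pixel entry phase vary so the medians average over rasterization
    phase.
    """
    cfg = cfg or default_channel_config()
    rng = np.random.default_rng(seed)
    taus, Es, etas = [], [], []
    for _ in range(n_replicates):
        spec = syn.SyntheticCellSpec(
            E_true=E_true, eta_true=eta_true, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            radius_um=7.5 * (1 + 0.02 * (rng.uniform() - 0.5)),
            z_start_um=-40.0 - 0.34 * rng.uniform())
        gt, contours = syn.simulate_trace(spec)
        stack, _ = syn.cell_stream_frames(spec, gt, contours)
        stream = imaging.FrameStream(frames=stack, fps=spec.fps,
                                     pixel_size_um=syn.DEFAULT_PIXEL_SIZE_UM)
        results, _, _ = pipeline.analyze_stream(
            stream, cfg, inlet_x_px=syn.DEFAULT_INLET_X_PX)
        if results:
            taus.append(results[0].tau_channel)
            Es.append(results[0].E)
            etas.append(results[0].eta)
    if not taus:
        raise RuntimeError(
            f"no cell recovered for E={E_true}, eta={eta_true}")
    tau_true = eta_true / E_true
    return RecoveryResult(
        E_true=E_true, eta_true=eta_true, tau_true=tau_true,
        E_rel_err=abs(float(np.median(Es)) - E_true) / E_true,
        eta_rel_err=abs(float(np.median(etas)) - eta_true) / eta_true,
        tau_rel_err=abs(float(np.median(taus)) - tau_true) / tau_true,
        n_cells=len(taus))


def recovery_grid(n_replicates: int = 5, seed: int = 7
                  ) -> list[RecoveryResult]:
    """Noiseless frame-level recovery over the full (E, eta) design."""
    return [recover_combo(E, eta, n_replicates=n_replicates, seed=seed)
            for E, eta in RECOVERY_COMBOS]


def noisy_tau_recovery(n_cells: int = 100, seed: int = 7,
                       noise_fraction: float = 0.02,
                       cfg: rh.ChannelConfig | None = None
                       ) -> tuple[float, int]:
    """Median tau recovery with radial contour noise (contour-level chain).

    Noise is ``noise_fraction`` of the cell radius per vertex.  Returns the
    relative error of the median recovered tau and the number of cells that
    survived the quality gates.
    """
    cfg = cfg or default_channel_config()
    base = syn.SyntheticCellSpec(
        noise_sd=noise_fraction * 7.5, seed=seed)
    cells = syn.simulate_population(n_cells, base, radius_cv=0.0, seed=seed)
    taus = []
    for spec, gt, contours in cells:
        try:
            tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
            _, _, ch_fit, _ = rh.extract_peaks(tr, cfg=cfg)
        except (sm.ShapeError, rh.FitRejection):
            continue
        taus.append(ch_fit.tau)
    tau_true = base.tau_true
    med = float(np.median(taus))
    return abs(med - tau_true) / tau_true, len(taus)
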