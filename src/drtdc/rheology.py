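"""Creep fitting and viscoelastic parameter extraction.

The parity-separated deformation traces are fitted with the exponential creep
law

    d(t) = d0 + d_hat * exp(-t / tau),

with the sign convention d_hat_inlet = +d_hat (relaxation from a peak) and
d_hat_channel = -d_hat (saturation towards a plateau).  Fit quality is gated
by the coefficient of correlation r^2 = 1 - SS_res / SS_tot with a default
cutoff of 0.6; rejected segments carry a reason.

Interpreting the channel trace as a creep-compliance experiment under the
constant stress sigma_channel, a Kelvin-Voigt solid gives tau_channel =
eta / E: the apparent Young's modulus E comes from the steady-state channel
deformation through a calibration look-up table (deformation x cell size ->
E, computed externally from a hydrodynamic stress model), and the apparent
viscosity follows as eta = E * tau_channel.

A power-law creep compliance J(t) = (1/E) * (t/t0)^beta (t0 = 1 s) is
available for model comparison, and the shear-thinning carrier buffers are
modelled as eta(gdot) = K * (gdot/gdot0)^(n-1).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import curve_fit

__all__ = [
    "CreepFit", "ViscoelasticResult", "PowerLawResult",
    "BufferViscosityModel", "ChannelConfig", "PopulationStats",
    "FitRejection", "fit_exponential", "extract_peaks", "young_modulus",
    "apparent_viscosity", "buffer_viscosity", "powerlaw_fit",
    "population_fit", "linear_elastic_table", "load_calibration_table",
    "BUFFER_MC_06", "BUFFER_MC_10",
]

R2_CUTOFF = 0.6


class FitRejection(RuntimeError):
    """A trace segment failed a quality gate; the message carries the reason."""


class ParameterError(ValueError):
    pass


class CalibrationRangeError(ValueError):
    """Query outside the calibration table hull; message lists the hull."""


@dataclass
class CreepFit:
    """Exponential creep fit of one trace segment."""

    d0: float
    d_hat: float              # signed: + for inlet relaxation, - for channel
    tau: float                # s
    r2: float
    segment: Literal["inlet", "channel"]
    t0: float = 0.0           # segment start time, s
    n_points: int = 0
    tau_at_bound: bool = False
    no_plateau: bool = False

    @property
    def amplitude(self) -> float:
        """Unsigned deformation amplitude."""
        return abs(self.d_hat)

    def model(self, t: np.ndarray) -> np.ndarray:
        return self.d0 + self.d_hat * np.exp(-(np.asarray(t) - self.t0) / self.tau)


@dataclass
class ViscoelasticResult:
    """Apparent material parameters of one cell."""

    cell_id: int | str
    E: float                  # Pa
    eta: float                # Pa s
    tau_inlet: float | None   # s
    tau_channel: float        # s
    d_hat_inlet: float
    d_hat_channel: float
    A_um2: float
    a0_um: float
    r2_inlet: float | None = None
    r2_channel: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PowerLawResult:
    E_pl: float               # Pa
    beta: float               # fluidity
    t0: float                 # reference time, s
    rmse: float               # residual on the compliance scale
    rmse_exponential: float | None = None
    sigma_channel: float | None = None


@dataclass
class BufferViscosityModel:
    """Power-law (Ostwald-de Waele) shear-thinning viscosity model."""

    K: float                  # consistency coefficient, Pa s
    n: float                  # flow behaviour index
    gamma_dot_0: float = 1.0  # reference shear rate, 1/s

    def __post_init__(self) -> None:
        if self.K <= 0 or not (0 < self.n <= 1) or self.gamma_dot_0 <= 0:
            raise ParameterError("need K > 0, 0 < n <= 1, gamma_dot_0 > 0")


#: PBS with 0.6% (w/v) methylcellulose
BUFFER_MC_06 = BufferViscosityModel(K=0.16, n=0.74)
#: PBS with 1% (w/v) methylcellulose
BUFFER_MC_10 = BufferViscosityModel(K=0.60, n=0.64)


@dataclass
class ChannelConfig:
    """Measurement-condition constants for one channel/flow-rate/buffer set.

    The mean surface stress and shear rate come from hydrodynamic (FEM)
    simulations of the full microfluidic geometry and enter as constants:
    142 Pa / 5100 1/s (30 um channel, 8 nl/s), 216 Pa / 9700 1/s (20 um,
    4 nl/s, leukocytes) and 128 Pa / 8600 1/s (20 um, 4 nl/s, erythrocytes).
    """

    cross_section_um: float = 30.0
    channel_length_um: float = 300.0
    flow_rate_nl_s: float = 8.0
    mean_surface_stress_pa: float = 142.0
    mean_shear_rate_s: float = 5100.0
    buffer: BufferViscosityModel = field(default_factory=lambda: BUFFER_MC_10)
    r2_cutoff: float = R2_CUTOFF
    inlet_fit_fraction: float = 0.4   # inlet fit ends at inlet + 40% of length
    calibration_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("cross_section_um", "channel_length_um", "flow_rate_nl_s",
                     "mean_surface_stress_pa", "mean_shear_rate_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class PopulationStats:
    log_mu: float
    log_sigma: float
    n_total: int
    n_outliers: int
    ci_sigma: float = 3.0


# ---------------------------------------------------------------------------
# exponential creep fit
# ---------------------------------------------------------------------------

def _r_squared(y: np.ndarray, f: np.ndarray) -> float:
    ss_res = float(((y - f) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_exponential(t: Sequence[float], d: Sequence[float],
                    segment: Literal["inlet", "channel"],
                    r2_cutoff: float = R2_CUTOFF) -> CreepFit:
    """Bounded least-squares fit of d(t) = d0 + d_hat exp(-(t-t0)/tau).

    ``t0`` is the first sample time of the segment, so tau and d0 are
    invariant to where the segment is cut.  The inlet segment should start at
    the local maximum of the even trace; the channel segment at the first
    in-channel frame of the odd trace.  Raises :class:`FitRejection` when the
    optimizer fails or r^2 falls below ``r2_cutoff``; a tau at its bounds is
    flagged, not rejected.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(d, dtype=float)
    if t.size != y.size or t.size < 5:
        raise FitRejection(f"segment has {t.size} points; need >= 5")
    if segment not in ("inlet", "channel"):
        raise ParameterError(f"unknown segment {segment!r}")
    t0 = float(t[0])
    tt = t - t0
    span = float(tt[-1])
    if span <= 0:
        raise FitRejection("segment has zero time span")
    dt = float(np.min(np.diff(t)))
    tau_lo, tau_hi = dt / 10.0, 100.0 * span
    sign = 1.0 if segment == "inlet" else -1.0

    def model(x, d0, amp, tau):
        return d0 + sign * amp * np.exp(-x / tau)

    d0_guess = float(y[-1])
    amp_guess = max(abs(float(y[0] - y[-1])), 1e-6)
    p0 = [d0_guess, amp_guess, span / 3.0]
    try:
        popt, _ = curve_fit(
            model, tt, y, p0=p0,
            bounds=([-1.0, 0.0, tau_lo], [1.0, 1.0, tau_hi]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitRejection(f"{segment} fit did not converge: {exc}") from exc
    d0, amp, tau = (float(p) for p in popt)
    r2 = _r_squared(y, model(tt, *popt))
    if r2 < r2_cutoff:
        raise FitRejection(
            f"{segment} fit rejected: r^2 = {r2:.3f} < cutoff {r2_cutoff}")
    at_bound = bool(np.isclose(tau, tau_lo, rtol=1e-3)
                    or np.isclose(tau, tau_hi, rtol=1e-3))
    return CreepFit(d0=d0, d_hat=sign * amp, tau=tau, r2=r2, segment=segment,
                    t0=t0, n_points=int(t.size), tau_at_bound=at_bound,
                    no_plateau=bool(span < 2.0 * tau))


# ---------------------------------------------------------------------------
# peak / plateau extraction
# ---------------------------------------------------------------------------

def extract_peaks(trace, inlet_z: float = 0.0,
                  outlet_z: float | None = None,
                  cfg: ChannelConfig | None = None,
                  r2_cutoff: float | None = None
                  ) -> tuple[float, float, CreepFit, CreepFit | None]:
    """Peak / plateau deformations and creep fits of one trace.

    Returns ``(d_hat_inlet, d_hat_channel, channel_fit, inlet_fit)``:

    * ``d_hat_inlet`` — the local maximum of the even trace near the inlet;
    * ``d_hat_channel`` — the steady-state plateau of the odd trace (fit
      parameter d0 of the channel fit) minus the odd deformation at the
      inlet (pre-inlet baseline); when no pre-inlet frames exist the fit
      amplitude is used and the fit is flagged ``no_plateau``-style.

    The inlet fit runs from the even-trace maximum to ``inlet_z`` plus
    ``cfg.inlet_fit_fraction`` of the channel length; the channel fit from
    the first in-channel frame to the outlet.  The inlet fit may fail
    (returned as None) without rejecting the cell; a failed channel fit
    raises :class:`FitRejection`.
    """
    cfg = cfg or ChannelConfig()
    cutoff = cfg.r2_cutoff if r2_cutoff is None else r2_cutoff
    if outlet_z is None:
        outlet_z = inlet_z + cfg.channel_length_um
    t, z = trace.times, trace.z
    if z.min() > inlet_z or z.max() < outlet_z:
        raise FitRejection("trace does not span inlet to outlet")

    in_channel = (z >= inlet_z) & (z <= outlet_z)
    if not np.any(in_channel):
        raise FitRejection("no in-channel frames")
    ch_fit = fit_exponential(t[in_channel], trace.d_odd[in_channel],
                             "channel", cutoff)
    pre = z < inlet_z
    if np.any(pre):
        baseline = float(np.median(trace.d_odd[pre]))
        d_hat_channel = ch_fit.d0 - baseline
    else:
        d_hat_channel = ch_fit.amplitude
        ch_fit.no_plateau = True

    # inlet: local maximum of d_even in the neighbourhood of the inlet
    near = z <= inlet_z + cfg.inlet_fit_fraction * cfg.channel_length_um
    if not np.any(near):
        raise FitRejection("no frames near the inlet")
    seg_end = int(np.flatnonzero(near)[-1]) + 1
    i_max = int(np.argmax(trace.d_even[:seg_end]))
    d_hat_inlet = float(trace.d_even[i_max])
    if d_hat_inlet <= 0 and d_hat_channel <= 0:
        # constant-shape track: both responses are flat
        return 0.0, max(d_hat_channel, 0.0), ch_fit, None
    inlet_fit: CreepFit | None = None
    if seg_end - i_max >= 5:
        try:
            inlet_fit = fit_exponential(t[i_max:seg_end],
                                        trace.d_even[i_max:seg_end],
                                        "inlet", cutoff)
        except FitRejection:
            inlet_fit = None
    return d_hat_inlet, d_hat_channel, ch_fit, inlet_fit


# ---------------------------------------------------------------------------
# calibration look-up table -> Young's modulus
# ---------------------------------------------------------------------------

def linear_elastic_table(sigma_pa: float, gain: float = 0.1,
                         diameters_um: Sequence[float] = (5.0, 10.0, 15.0,
                                                          20.0, 25.0),
                         d_min: float = 1e-3, d_max: float = 0.6,
                         n_d: int = 120) -> pd.DataFrame:
    """Synthetic linear-elastic calibration table E = sigma * gain / d.

    Stand-in for a calibration table computed from a hydrodynamic
    stress model; matches the simulator's strain-to-deformation gain so
    synthetic worlds are self-consistent.  Deformation grid is geometric so
    bilinear interpolation of the convex 1/d relation stays accurate.
    """
    defs = np.geomspace(d_min, d_max, n_d)
    rows = [(dia, dd, sigma_pa * gain / dd)
            for dia in diameters_um for dd in defs]
    return pd.DataFrame(rows, columns=["cell_diameter_um", "deformation", "E_pa"])


def load_calibration_table(path: str | Path | _io.IOBase) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"cell_diameter_um", "deformation", "E_pa"}
    if not need.issubset(df.columns):
        raise ParameterError(f"calibration table must have columns {sorted(need)}")
    return df


def young_modulus(d_hat_channel: float, a0_um: float,
                  cfg: ChannelConfig) -> float:
    """Apparent Young's modulus from the calibration look-up table.

    Bilinear interpolation in (cell diameter, steady-state channel
    deformation); the table must be monotone decreasing in deformation at
    fixed size.  Queries outside the table hull raise
    :class:`CalibrationRangeError` listing the hull.
    """
    if cfg.calibration_table is None:
        raise ParameterError("ChannelConfig.calibration_table is not set")
    if d_hat_channel <= 0:
        raise ParameterError("d_hat_channel must be positive")
    df = cfg.calibration_table
    dias = np.sort(df["cell_diameter_um"].unique())
    defs = np.sort(df["deformation"].unique())
    grid = (df.pivot_table(index="cell_diameter_um", columns="deformation",
                           values="E_pa").loc[dias, defs].to_numpy())
    diameter = a0_um  # a0 = 2 * mean radius = effective diameter
    lo = (dias[0], defs[0])
    hi = (dias[-1], defs[-1])
    if not (lo[0] <= diameter <= hi[0]) or not (lo[1] <= d_hat_channel <= hi[1]):
        raise CalibrationRangeError(
            f"query (diameter={diameter:.3g} um, d={d_hat_channel:.3g}) outside "
            f"table hull: diameter in [{lo[0]:g}, {hi[0]:g}] um, "
            f"deformation in [{lo[1]:g}, {hi[1]:g}]")
    interp = RegularGridInterpolator((dias, defs), grid, method="linear")
    return float(interp([[diameter, d_hat_channel]])[0])


def apparent_viscosity(tau_channel: float, E: float) -> float:
    """Kelvin-Voigt identity eta = E * tau_channel."""
    if tau_channel <= 0 or E <= 0:
        raise ParameterError("tau_channel and E must be positive")
    return E * tau_channel


def buffer_viscosity(gamma_dot, model: BufferViscosityModel) -> float | np.ndarray:
    """Shear-thinning carrier viscosity eta = K * (gdot/gdot0)^(n-1)."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g <= 0):
        raise ParameterError("shear rate must be positive")
    out = model.K * (g / model.gamma_dot_0) ** (model.n - 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# power-law rheology
# ---------------------------------------------------------------------------

def powerlaw_fit(t: Sequence[float], d_channel: Sequence[float],
                 cfg: ChannelConfig, strain_scale: float = 1.0,
                 peak_strain: float = 0.1, t0: float = 1.0,
                 compare_exponential: bool = True) -> PowerLawResult:
    """Fit the power-law creep compliance J(t) = (1/E) (t/t0)^beta.

    The channel deformation trace is mapped to strain as
    ``eps(t) = strain_scale * d(t) / max(d) * peak_strain`` (the 10% default
    reflects the estimated ratio of maximal cell surface displacement to
    radius), then to compliance ``J = eps / sigma_channel``.  Time is
    measured from the segment start.  The RMSE of the exponential
    (Kelvin-Voigt) fit on the same compliance series is reported alongside
    for model comparison.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d_channel, dtype=float)
    if t.size != d.size or t.size < 5:
        raise ParameterError("need >= 5 samples")
    dmax = d.max()
    if dmax <= 0:
        raise ParameterError("all-zero channel trace")
    eps = strain_scale * d / dmax * peak_strain
    J = eps / cfg.mean_surface_stress_pa
    tt = t - t[0]

    def model(x, E, beta):
        return (1.0 / E) * (np.maximum(x, 0.0) / t0) ** beta

    J_pos = J[J > 0]
    E0 = 1.0 / np.median(J_pos) if J_pos.size else 1e3
    popt, _ = curve_fit(model, tt, J, p0=[E0, 0.3],
                        bounds=([1e-3, 0.0], [1e9, 1.0]), maxfev=20000)
    E_pl, beta = (float(p) for p in popt)
    rmse_pl = float(np.sqrt(np.mean((J - model(tt, *popt)) ** 2)))

    rmse_exp = None
    if compare_exponential:
        try:
            f = fit_exponential(t, d, "channel", r2_cutoff=-np.inf)
            d_model = f.model(t)
            J_model = strain_scale * d_model / dmax * peak_strain \
                / cfg.mean_surface_stress_pa
            rmse_exp = float(np.sqrt(np.mean((J - J_model) ** 2)))
        except FitRejection:
            rmse_exp = None
    return PowerLawResult(E_pl=E_pl, beta=beta, t0=t0, rmse=rmse_pl,
                          rmse_exponential=rmse_exp,
                          sigma_channel=cfg.mean_surface_stress_pa)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def population_fit(values: Sequence[float], ci_sigma: float = 3.0
                   ) -> PopulationStats:
    """Log-normal population fit with one round of 3-sigma outlier exclusion.

    Log-transform, estimate (mu, sigma), drop points outside mu +/- ci_sigma
    * sigma in log space, refit once.  All values must be positive and
    non-degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ParameterError(f"need >= 20 values, got {x.size}")
    if np.any(x <= 0):
        raise ParameterError("all values must be positive for a log-normal fit")
    lx = np.log(x)
    mu, sigma = float(lx.mean()), float(lx.std(ddof=1))
    tiny = 1e-12 * max(abs(mu), 1.0)
    if sigma <= tiny:
        raise ParameterError("degenerate sample: all values identical")
    keep = np.abs(lx - mu) <= ci_sigma * sigma
    n_out = int((~keep).sum())
    lk = lx[keep]
    if lk.size < 2 or lk.std(ddof=1) <= tiny:
        raise ParameterError("degenerate sample after outlier exclusion")
    return PopulationStats(log_mu=float(lk.mean()),
                           log_sigma=float(lk.std(ddof=1)),
                           n_total=int(x.size), n_outliers=n_out,
                           ci_sigma=ci_sigma)
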