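"""Creep fitting, quality gates, material parameters, population stats."""

import numpy as np
import pytest

from drtdc import rheology as rh
from drtdc import shape_modes as sm
from drtdc import synthetic as syn


# ---------------------------------------------------------------------------
# exponential creep fit
# ---------------------------------------------------------------------------

def test_exponential_fit_exact_on_model_data():
    """d(t) = 0.02 + 0.05 exp(-t/2ms) is recovered exactly (model in class)."""
    t = np.linspace(0, 10e-3, 50)
    d = 0.02 + 0.05 * np.exp(-t / 2e-3)
    fit = rh.fit_exponential(t, d, "inlet")
    assert fit.d0 == pytest.approx(0.02, abs=1e-9)
    assert fit.d_hat == pytest.approx(0.05, abs=1e-9)
    assert fit.tau == pytest.approx(2e-3, rel=1e-8)
    assert fit.r2 == pytest.approx(1.0)


def test_exponential_fit_channel_sign_convention():
    """Channel saturation carries d_hat_channel = -d_hat."""
    t = np.linspace(0, 30e-3, 60)
    d = 0.04 * (1 - np.exp(-t / 8e-3))
    fit = rh.fit_exponential(t, d, "channel")
    assert fit.d_hat == pytest.approx(-0.04, abs=1e-9)
    assert fit.amplitude == pytest.approx(0.04, abs=1e-9)
    assert fit.d0 == pytest.approx(0.04, abs=1e-9)
    assert fit.tau == pytest.approx(8e-3, rel=1e-8)


def test_exponential_fit_noisy_median_tau():
    """Median tau over 200 noisy replicates stays within 5% of truth."""
    rng = np.random.default_rng(99)
    t = np.linspace(0, 10e-3, 50)
    taus = []
    for _ in range(200):
        d = 0.02 + 0.05 * np.exp(-t / 2e-3) + rng.normal(0, 0.002, t.size)
        try:
            taus.append(rh.fit_exponential(t, d, "inlet").tau)
        except rh.FitRejection:
            pass
    assert len(taus) > 150
    assert np.median(taus) == pytest.approx(2e-3, rel=0.05)


def test_white_noise_segment_rejected_by_r2_gate():
    rng = np.random.default_rng(3)
    t = np.linspace(0, 10e-3, 50)
    with pytest.raises(rh.FitRejection, match="r\\^2"):
        rh.fit_exponential(t, rng.normal(0, 0.01, t.size), "inlet")


def test_fit_noiseless_unbiased_across_tau_range():
    """Noiseless recovery error < 0.1% for tau from 0.1 ms to 50 ms when
    sampled at >= 14 points spanning >= 3 tau."""
    for tau in (1e-4, 1e-3, 8.6e-3, 5e-2):
        t = np.linspace(0, 3.5 * tau, 20)
        d = 0.03 * (1 - np.exp(-t / tau))
        fit = rh.fit_exponential(t, d, "channel")
        assert fit.tau == pytest.approx(tau, rel=1e-3)


def test_fit_too_few_points_rejected():
    with pytest.raises(rh.FitRejection):
        rh.fit_exponential([0, 1e-3, 2e-3], [0.1, 0.2, 0.3], "channel")


def test_time_origin_invariance():
    """Shifting the segment start leaves tau and d0 unchanged."""
    t = np.linspace(0, 20e-3, 40)
    d = 0.05 * (1 - np.exp(-t / 5e-3))
    f1 = rh.fit_exponential(t, d, "channel")
    f2 = rh.fit_exponential(t + 0.125, d, "channel")
    assert f2.tau == pytest.approx(f1.tau, rel=1e-6)
    assert f2.d0 == pytest.approx(f1.d0, abs=1e-9)


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def test_extract_peaks_on_simulated_trace(default_sim, default_cfg):
    """Both peak measures match the simulator ground truth within 2%."""
    spec, gt, contours = default_sim
    tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
    d_hat_inlet, d_hat_channel, ch_fit, in_fit = rh.extract_peaks(
        tr, cfg=default_cfg)
    assert d_hat_inlet == pytest.approx(gt.d_hat_inlet_true, rel=0.02)
    assert d_hat_channel == pytest.approx(gt.d_hat_channel_true, rel=0.02)
    assert ch_fit.r2 > 0.99


def test_extract_peaks_constant_track(default_cfg):
    """A constant circular track has zero peaks (flat fit is accepted as
    zero-amplitude, not an error)."""
    n = 30
    phi = np.linspace(-np.pi, np.pi, 240, endpoint=False)
    circ = np.column_stack([8 * np.cos(phi), 8 * np.sin(phi)])
    tr = sm.decompose_trace([circ] * n, np.arange(n) / 4000.0,
                            np.linspace(-20, 320, n))
    try:
        dhi, dhc, ch_fit, _ = rh.extract_peaks(tr, cfg=default_cfg)
        assert dhi < 1e-3 and abs(dhc) < 1e-3
    except rh.FitRejection:
        pass                                      # flat trace may fail r^2


def test_extract_peaks_no_plateau_flag(default_cfg):
    """A trace cut before saturation still yields d_hat from the fit, with
    the no-plateau flag raised."""
    spec = syn.SyntheticCellSpec(E_true=100.0, eta_true=10.0)  # tau = 100 ms
    gt, contours = syn.simulate_trace(spec)
    tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
    _, d_hat_channel, ch_fit, _ = rh.extract_peaks(tr, cfg=default_cfg)
    assert ch_fit.no_plateau
    assert d_hat_channel > 0


# ---------------------------------------------------------------------------
# calibration table -> E, viscosity
# ---------------------------------------------------------------------------

def toy_table():
    return rh.linear_elastic_table(142.0, gain=0.1)


def test_young_modulus_closed_form_toy_table():
    """E = sigma * g / d_hat with g = 0.1: d = 0.05, sigma = 142 -> 284 Pa."""
    cfg = rh.ChannelConfig(calibration_table=toy_table())
    E = rh.young_modulus(0.05, 15.0, cfg)
    assert E == pytest.approx(284.0, rel=5e-3)


def test_young_modulus_exact_at_grid_node():
    cfg = rh.ChannelConfig(calibration_table=toy_table())
    node_d = float(cfg.calibration_table["deformation"].unique()[40])
    E = rh.young_modulus(node_d, 15.0, cfg)
    assert E == pytest.approx(142.0 * 0.1 / node_d, rel=1e-12)


def test_young_modulus_monotone_in_deformation():
    cfg = rh.ChannelConfig(calibration_table=toy_table())
    ds = np.linspace(0.01, 0.4, 50)
    Es = [rh.young_modulus(d, 15.0, cfg) for d in ds]
    assert np.all(np.diff(Es) < 0)


def test_young_modulus_out_of_range_lists_hull():
    cfg = rh.ChannelConfig(calibration_table=toy_table())
    with pytest.raises(rh.CalibrationRangeError, match="hull"):
        rh.young_modulus(0.9, 15.0, cfg)
    with pytest.raises(rh.CalibrationRangeError):
        rh.young_modulus(0.05, 80.0, cfg)


def test_apparent_viscosity_identity_and_linearity():
    assert rh.apparent_viscosity(1.0, 1.0) == 1.0
    assert rh.apparent_viscosity(8.575e-3, 400.0) == pytest.approx(3.43)
    assert rh.apparent_viscosity(5e-3, 800.0) \
        == pytest.approx(2 * rh.apparent_viscosity(5e-3, 400.0))
    with pytest.raises(rh.ParameterError):
        rh.apparent_viscosity(-1.0, 400.0)


# ---------------------------------------------------------------------------
# buffer viscosity
# ---------------------------------------------------------------------------

def test_buffer_viscosity_reference_values():
    """At the reference shear rate the viscosity equals the consistency
    coefficient: 0.16 Pa s (0.6% MC) and 0.60 Pa s (1% MC)."""
    assert rh.buffer_viscosity(1.0, rh.BUFFER_MC_06) == pytest.approx(0.16)
    assert rh.buffer_viscosity(1.0, rh.BUFFER_MC_10) == pytest.approx(0.60)


def test_buffer_viscosity_channel_shear_rates_are_tens_of_mPas():
    """At channel shear rates the carrier thins to the 10 mPa s scale."""
    for gdot, model in [(5100.0, rh.BUFFER_MC_10), (9700.0, rh.BUFFER_MC_10),
                        (8600.0, rh.BUFFER_MC_06)]:
        eta = rh.buffer_viscosity(gdot, model)
        assert 0.005 < eta < 0.06
    assert rh.buffer_viscosity(5100.0, rh.BUFFER_MC_10) \
        == pytest.approx(0.60 * 5100.0 ** (0.64 - 1.0), rel=1e-12)


def test_buffer_viscosity_loglog_slope_is_n_minus_1():
    g = np.geomspace(1, 1e4, 30)
    eta = rh.buffer_viscosity(g, rh.BUFFER_MC_10)
    slopes = np.diff(np.log(eta)) / np.diff(np.log(g))
    assert np.allclose(slopes, rh.BUFFER_MC_10.n - 1.0, atol=1e-9)


def test_buffer_viscosity_invalid_inputs():
    with pytest.raises(rh.ParameterError):
        rh.buffer_viscosity(-5.0, rh.BUFFER_MC_10)
    with pytest.raises(rh.ParameterError):
        rh.BufferViscosityModel(K=0.1, n=1.5)


# ---------------------------------------------------------------------------
# power-law rheology
# ---------------------------------------------------------------------------

def test_powerlaw_fit_recovers_exact_model():
    """J(t) = (1/500)(t/1s)^0.3 over two decades -> E = 500, beta = 0.3."""
    cfg = rh.ChannelConfig()
    t = np.geomspace(1e-3, 1e-1, 60)
    t = np.concatenate([[0.0], t])
    J = (1.0 / 500.0) * (t / 1.0) ** 0.3
    # invert the strain mapping so the fit sees exactly J
    d = J * cfg.mean_surface_stress_pa
    res = rh.powerlaw_fit(t, d, cfg, strain_scale=d.max() / 0.1,
                          compare_exponential=False)
    assert res.E_pl == pytest.approx(500.0, rel=1e-6)
    assert res.beta == pytest.approx(0.3, abs=1e-6)


def test_powerlaw_elastic_limit_beta_zero():
    cfg = rh.ChannelConfig()
    t = np.linspace(0, 30e-3, 40)
    d = np.full_like(t, 0.05)
    res = rh.powerlaw_fit(t, d, cfg, strain_scale=0.05 * cfg.
                          mean_surface_stress_pa / 0.1 / 0.05,
                          compare_exponential=False)
    assert res.beta == pytest.approx(0.0, abs=1e-6)


def test_exponential_beats_powerlaw_on_kelvin_voigt_trace(default_sim,
                                                          default_cfg):
    """On Kelvin-Voigt creep the exponential model has the smaller RMSE."""
    spec, gt, contours = default_sim
    tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
    sel = (tr.z >= 0) & (tr.z <= 300.0)
    res = rh.powerlaw_fit(tr.times[sel], tr.d_odd[sel], default_cfg)
    assert res.rmse_exponential is not None
    assert res.rmse_exponential < res.rmse


def test_powerlaw_all_zero_trace_rejected():
    with pytest.raises(rh.ParameterError):
        rh.powerlaw_fit(np.linspace(0, 1, 10), np.zeros(10),
                        rh.ChannelConfig())


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def test_population_fit_monte_carlo():
    rng = np.random.default_rng(11)
    x = rng.lognormal(mean=0.0, sigma=0.5, size=1000)
    stats = rh.population_fit(x)
    assert stats.log_mu == pytest.approx(0.0, abs=0.05)
    assert stats.log_sigma == pytest.approx(0.5, abs=0.05)
    assert stats.n_total == 1000


def test_population_fit_excludes_injected_outliers():
    rng = np.random.default_rng(12)
    x = rng.lognormal(0.0, 0.3, 500)
    spiked = np.concatenate([x, x[:5] * 100.0])
    stats = rh.population_fit(spiked)
    assert stats.n_outliers == 5


def test_population_fit_degenerate_and_invalid():
    with pytest.raises(rh.ParameterError):
        rh.population_fit(np.full(50, 3.3))
    with pytest.raises(rh.ParameterError):
        rh.population_fit(np.linspace(-1, 1, 50))
    with pytest.raises(rh.ParameterError):
        rh.population_fit([1.0] * 10)              # too few


# ---------------------------------------------------------------------------
# Kelvin-Voigt closure
# ---------------------------------------------------------------------------

def test_eta_over_E_equals_tau_closure(default_sim, default_cfg):
    """For every accepted cell eta / E == tau_channel to machine accuracy."""
    from drtdc import pipeline
    spec, gt, contours = default_sim
    tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
    res = pipeline.analyze_trace(tr, default_cfg)
    assert res.eta / res.E == pytest.approx(res.tau_channel, rel=1e-12)
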