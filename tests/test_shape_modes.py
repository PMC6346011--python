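"""Shape-mode math: polar transform, radial DFT, parity reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drtdc import shape_modes as sm
from .conftest import random_convex_polygon


def naive_radial_dft(r, phi, dphi, k_max=9):
    """Independent brute-force evaluation of the weighted radial DFT."""
    a = np.zeros(k_max + 1)
    b = np.zeros(k_max + 1)
    n = len(r)
    for k in range(k_max + 1):
        sa = sb = 0.0
        for i in range(n):
            sa += r[i] * np.cos(k * phi[i]) * dphi[i]
            sb += r[i] * np.sin(k * phi[i]) * dphi[i]
        a[k] = sa / np.pi
        b[k] = sb / np.pi
    b[0] = 0.0
    return a, b


def circle(n=360, R=10.0, center=(0.0, 0.0)):
    phi = np.linspace(-np.pi, np.pi, n, endpoint=False)
    return np.column_stack([center[0] + R * np.cos(phi),
                            center[1] + R * np.sin(phi)])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("verts,area,perim,com", [
    ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0, 4.0, (0.5, 0.5)),
    ([(0, 0), (2, 0), (0, 2)], 2.0, 4 + 2 * np.sqrt(2), (2 / 3, 2 / 3)),
])
def test_polygon_geometry_closed_forms(verts, area, perim, com):
    A, P, c = sm.polygon_geometry(np.array(verts, dtype=float))
    assert A == pytest.approx(area)
    assert P == pytest.approx(perim)
    assert c == pytest.approx(com)


def test_polygon_geometry_polygon_limit():
    """A regular 360-gon of radius 10 has almost exactly the disk area."""
    A, P, _ = sm.polygon_geometry(circle(360, 10.0))
    assert A == pytest.approx(np.pi * 100, rel=1e-3)


def test_degenerate_polygon_rejected():
    with pytest.raises(sm.ShapeError):
        sm.polygon_geometry(np.array([[0., 0.], [1., 1.], [2., 2.]]))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def test_interpolation_counts_and_identity():
    square = np.array([(0., 0.), (1., 0.), (1., 1.), (0., 1.)])
    dense = sm.interpolate_contour(square, 49)
    assert dense.shape == (200, 2)            # 4 * (49 + 1)
    # original vertices preserved
    for v in square:
        assert np.any(np.all(np.isclose(dense, v), axis=1))
    assert np.allclose(sm.interpolate_contour(square, 0), square)


def test_interpolation_preserves_perimeter(rng):
    poly = random_convex_polygon(rng)
    _, p0, _ = sm.polygon_geometry(poly)
    _, p1, _ = sm.polygon_geometry(sm.interpolate_contour(poly, 49))
    assert p1 == pytest.approx(p0, rel=1e-12)


# ---------------------------------------------------------------------------
# polar transform
# ---------------------------------------------------------------------------

def test_polar_transform_circle_any_center():
    pc = sm.polar_transform(circle(500, 7.0, center=(123.4, -56.7)))
    assert np.allclose(pc.r, 7.0, atol=1e-9)
    assert pc.dphi.sum() == pytest.approx(2 * np.pi, abs=1e-6)


def test_polar_transform_unit_square():
    square = np.array([(0., 0.), (1., 0.), (1., 1.), (0., 1.)])
    pc = sm.polar_transform(sm.interpolate_contour(square, 1))
    # corners at sqrt(2)/2 from the centre, edge midpoints at 1/2
    assert np.max(pc.r) == pytest.approx(np.sqrt(2) / 2)
    assert np.min(pc.r) == pytest.approx(0.5)


def test_polar_transform_rejects_non_star_shaped():
    # a thin crescent is not star-shaped about its centroid
    phi = np.linspace(-0.9 * np.pi, 0.9 * np.pi, 200)
    outer = np.column_stack([10 * np.cos(phi), 10 * np.sin(phi)])
    inner = np.column_stack([9.0 * np.cos(phi[::-1]), 9.0 * np.sin(phi[::-1])])
    crescent = np.vstack([outer, inner])
    with pytest.raises(sm.ShapeError):
        sm.polar_transform(crescent)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_angular_weights_telescope(seed):
    """Sum of angular weights is 2*pi for any valid convex contour."""
    poly = random_convex_polygon(np.random.default_rng(seed))
    pc = sm.polar_transform(poly)
    assert pc.dphi.sum() == pytest.approx(2 * np.pi, abs=1e-6)
    assert np.all(pc.r > 0)


# ---------------------------------------------------------------------------
# Fourier coefficients
# ---------------------------------------------------------------------------

def test_dft_matches_naive_oracle(rng):
    """Vectorized coefficients equal a brute-force double loop to 1e-9."""
    for _ in range(100):
        poly = random_convex_polygon(rng, n=30)
        pc = sm.polar_transform(poly)
        spec = sm.fourier_coefficients(pc)
        a, b = naive_radial_dft(pc.r, pc.phi, pc.dphi)
        scale = np.abs(a[0])
        assert np.allclose(spec.a, a, atol=1e-9 * scale)
        assert np.allclose(spec.b, b, atol=1e-9 * scale)


def test_constant_radius_spectrum():
    """r = R gives a0 = 2R and negligible higher coefficients."""
    R = 5.0
    spec = sm.fourier_coefficients(sm.polar_transform(circle(1500, R)))
    assert spec.a[0] == pytest.approx(2 * R, rel=1e-9)
    assert np.all(np.abs(spec.a[1:]) < 1e-6 * R)
    assert np.all(np.abs(spec.b) < 1e-6 * R)


def test_cos2_mode_amplitude_quadrature():
    """r(phi) = 1 + 0.1 cos(2 phi) has a0 ~ 2, a2 ~ 0.1, rest ~ 0."""
    phi = np.linspace(-np.pi, np.pi, 4000, endpoint=False)
    r = 1.0 + 0.1 * np.cos(2 * phi)
    verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    spec = sm.fourier_coefficients(sm.polar_transform(verts))
    assert spec.a[0] == pytest.approx(2.0, abs=2e-3)
    assert spec.a[2] == pytest.approx(0.1, abs=2e-3)
    others = np.delete(spec.a, [0, 2])
    assert np.all(np.abs(others) < 2e-3)


def test_fore_aft_symmetry_kills_odd_cosines():
    """r(phi) = r(pi - phi) implies vanishing odd-order cosine terms."""
    phi = np.linspace(-np.pi, np.pi, 3000, endpoint=False)
    r = 1.0 + 0.08 * np.cos(2 * phi) + 0.03 * np.cos(4 * phi)
    verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    spec = sm.fourier_coefficients(sm.polar_transform(verts))
    assert np.all(np.abs(spec.a[1::2]) < 1e-4)


def test_coefficient_convergence_rate():
    """Quadrature error decays as the sampling density doubles.

    The reference is the densely converged coefficient of the same shape
    (the centroid-frame value, which differs at second order from the
    construction coefficient when several modes mix).
    """
    def a3(n):
        phi = np.linspace(-np.pi, np.pi, n, endpoint=False)
        r = 1.0 + 0.07 * np.cos(3 * phi) + 0.05 * np.cos(2 * phi)
        verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        return sm.fourier_coefficients(sm.polar_transform(verts)).a[3]

    ref = a3(25600)
    errs = np.array([abs(a3(n) - ref) for n in (100, 200, 400, 800)])
    ratios = errs[:-1] / errs[1:]
    assert np.all(ratios > 1.8)          # ~halves (or better) per doubling


def test_normalization_by_a0():
    spec = sm.fourier_coefficients(sm.polar_transform(circle(800, 4.0)),
                                   normalized=True)
    assert spec.normalized
    assert spec.a[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# deformation and reconstruction
# ---------------------------------------------------------------------------

def test_deformation_circle_square_ellipse():
    assert sm.deformation(circle(360)) < 1e-3
    square = np.array([(0., 0.), (1., 0.), (1., 1.), (0., 1.)])
    assert sm.deformation(square) == pytest.approx(1 - np.sqrt(np.pi) / 2,
                                                   rel=1e-12)
    # 2:1 ellipse against an independent perimeter oracle
    from scipy.special import ellipe
    a_ax, b_ax = 2.0, 1.0
    ecc2 = 1 - (b_ax / a_ax) ** 2
    P = 4 * a_ax * ellipe(ecc2)
    d_oracle = 1 - 2 * np.sqrt(np.pi * np.pi * a_ax * b_ax) / P
    t = np.linspace(-np.pi, np.pi, 20000, endpoint=False)
    ellipse = np.column_stack([a_ax * np.cos(t), b_ax * np.sin(t)])
    assert sm.deformation(ellipse) == pytest.approx(d_oracle, abs=1e-4)
    assert d_oracle == pytest.approx(0.083, abs=2e-3)


def test_reconstruction_of_circle_is_circle():
    spec = sm.fourier_coefficients(sm.polar_transform(circle(720, 6.0)))
    for parity in ("even", "odd", "full"):
        rec = sm.reconstruct_contour(spec, parity)
        assert np.allclose(rec.r, 6.0, atol=1e-5)
        # residual d is the regular-1000-gon discretization gap (~pi^2/6n^2)
        assert rec.d < 5e-6


def test_reconstruction_parity_subsets():
    """Even keeps orders 2,4,6,8; odd keeps 1,3,5,7,9; both carry a0."""
    a = np.zeros(10)
    a[0], a[2], a[3] = 10.0, 0.4, 0.3
    spec = sm.ShapeSpectrum(a=a, b=np.zeros(10))
    even = sm.reconstruct_contour(spec, "even")
    odd = sm.reconstruct_contour(spec, "odd")
    phi = even.phi
    assert np.allclose(even.r, 5.0 + 0.4 * np.cos(2 * phi), atol=1e-12)
    assert np.allclose(odd.r, 5.0 + 0.3 * np.cos(3 * phi), atol=1e-12)


def test_reconstruction_needs_length_units():
    spec = sm.fourier_coefficients(sm.polar_transform(circle(360, 3.0)),
                                   normalized=True)
    with pytest.raises(sm.ShapeError):
        sm.reconstruct_contour(spec)


def test_negative_radius_reconstruction_rejected():
    a = np.zeros(10)
    a[0], a[2] = 2.0, 1.5                 # a0/2 = 1 < a2
    spec = sm.ShapeSpectrum(a=a, b=np.zeros(10))
    with pytest.raises(sm.ShapeError):
        sm.reconstruct_contour(spec, "even")


def test_full_reconstruction_matches_raw_deformation(default_sim):
    """10-coefficient reconstruction reproduces d within ~1% relative."""
    _, gt, contours = default_sim
    rel = []
    for c in contours[::12]:
        spec, d_raw, _, _ = sm.analyze_contour(c)
        rec = sm.reconstruct_contour(spec, "full")
        if d_raw > 5e-3:
            rel.append(abs(rec.d - d_raw) / d_raw)
    assert rel and np.median(rel) < 0.015


def test_initially_noncircular_cell_has_zero_odd_deformation():
    """A resting ellipse (fore-aft symmetric) shows d_odd < 0.01."""
    phi = np.linspace(-np.pi, np.pi, 360, endpoint=False)
    r = 4.0 * (1 + 0.15 * np.cos(2 * phi))       # erythrocyte-like at rest
    verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    _, _, d_even, d_odd = sm.analyze_contour(verts)
    assert d_odd < 0.01
    assert d_even > 0.01


# ---------------------------------------------------------------------------
# trace decomposition
# ---------------------------------------------------------------------------

def test_decompose_trace_static_circle():
    contours = [circle(240, 8.0)] * 20
    tr = sm.decompose_trace(contours, np.arange(20) * 1e-3,
                            np.arange(20) * 5.0)
    assert np.all(tr.d_raw < 1e-3)
    assert np.all(tr.d_even < 1e-3)
    assert np.all(tr.d_odd < 1e-3)


def test_decompose_trace_needs_14_points():
    contours = [circle(240, 8.0)] * 13
    with pytest.raises(sm.ShapeError):
        sm.decompose_trace(contours, np.arange(13) * 1e-3, np.arange(13.))


def test_decompose_trace_shapes(default_sim):
    """Simulator trace: d_even peaks near the inlet, d_odd grows to the
    outlet and starts at ~0."""
    _, gt, contours = default_sim
    tr = sm.decompose_trace(contours, gt.times, gt.z_positions)
    i_peak = np.argmax(tr.d_even)
    assert abs(gt.z_positions[i_peak]) < 40.0          # peak near inlet
    pre = gt.z_positions < 0
    ch = (gt.z_positions > 0) & (gt.z_positions < 300)
    assert np.median(tr.d_odd[pre]) < 1e-3             # zero at inlet
    assert tr.d_odd[ch].max() == pytest.approx(tr.d_odd.max(), rel=0.05)
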