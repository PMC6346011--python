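"""Radial Fourier shape-mode analysis of cell contours.

A convex cell contour is interpreted as an angle-dependent radius function
``r(phi)`` about its area centroid and expanded into a small set of Fourier
coefficients ``a_0..a_9``, ``b_1..b_9``.  Even cosine modes (a2, a4, ...)
capture fore-aft symmetric elongation; odd modes (a1, a3, ...) capture the
bullet-like fore-aft asymmetry a cell acquires under the constant stress
inside a microfluidic constriction.  Reconstructing the contour from one
parity class at a time yields two deformation traces, ``d_even`` (inlet
response) and ``d_odd`` (channel response), that can be fitted independently.

Deformation is defined from circularity,

    d = 1 - c = 1 - 2 * sqrt(pi * A) / P,

zero for a circle and positive for any other simple closed shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PolarContour",
    "ShapeSpectrum",
    "ReconstructedContour",
    "DeformationTrace",
    "polygon_geometry",
    "interpolate_contour",
    "polar_transform",
    "fourier_coefficients",
    "reconstruct_contour",
    "deformation",
    "decompose_trace",
]

K_MAX_DEFAULT = 9
#: even reconstruction uses a0 plus cosine/sine orders 2,4,6,8
EVEN_ORDERS = (2, 4, 6, 8)
#: odd reconstruction uses a0 plus cosine/sine orders 1,3,5,7,9
ODD_ORDERS = (1, 3, 5, 7, 9)


class ShapeError(ValueError):
    """Raised for geometrically invalid contours (non star-shaped, degenerate)."""


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def polygon_geometry(vertices: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Shoelace area, perimeter and area centroid of a closed polygon.

    Parameters
    ----------
    vertices : (N, 2) array
        Polygon vertices (x, y), closing edge implied.  Orientation may be
        either; the absolute area is returned.

    Returns
    -------
    area, perimeter, (x_com, y_com)
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ShapeError("polygon needs at least 3 (x, y) vertices")
    # drop an explicit closing vertex
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = cross.sum()
    if area2 == 0.0:
        raise ShapeError("degenerate polygon: zero area")
    xcom = ((x + xn) * cross).sum() / (3.0 * area2)
    ycom = ((y + yn) * cross).sum() / (3.0 * area2)
    perim = np.hypot(xn - x, yn - y).sum()
    return abs(area2) / 2.0, float(perim), (float(xcom), float(ycom))


def deformation(arg) -> float:
    """Deformation d = 1 - 2*sqrt(pi*A)/P of a polygon or reconstruction.

    Accepts an (N, 2) vertex array, a ``ReconstructedContour`` or an
    ``(A, P)`` pair.  Clipped at 0: discretization of a near-circle can push
    circularity marginally above 1.
    """
    if isinstance(arg, ReconstructedContour):
        area, perim = arg.area, arg.perimeter
    elif isinstance(arg, tuple) and len(arg) == 2 and np.isscalar(arg[0]):
        area, perim = arg
    else:
        area, perim, _ = polygon_geometry(np.asarray(arg, dtype=float))
    if area <= 0 or perim <= 0:
        raise ShapeError("deformation needs positive area and perimeter")
    return max(0.0, 1.0 - 2.0 * np.sqrt(np.pi * area) / perim)


def convex_hull_polygon(vertices: np.ndarray) -> np.ndarray:
    """Convex hull of a polygon, counterclockwise.

    The hull is the first step of the analysis chain: it guarantees a
    star-shaped contour and suppresses inward segmentation jitter.
    """
    from scipy.spatial import ConvexHull

    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    hull = ConvexHull(v)
    out = v[hull.vertices]
    x, y = out[:, 0], out[:, 1]
    if (x * np.roll(y, -1) - np.roll(x, -1) * y).sum() < 0:
        out = out[::-1]
    return out


def interpolate_contour(vertices: np.ndarray, k_interp: int = 49) -> np.ndarray:
    """Piecewise-linearly insert ``k_interp`` points between neighbours.

    An N-vertex closed polygon becomes N*(k_interp+1) vertices; the original
    vertices are preserved and the polygon (hence its perimeter) is unchanged.
    """
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    if k_interp < 0:
        raise ValueError("k_interp must be >= 0")
    if k_interp == 0:
        return v.copy()
    nxt = np.roll(v, -1, axis=0)
    # fractions 0, 1/(k+1), ..., k/(k+1) along each edge
    f = (np.arange(k_interp + 1) / (k_interp + 1))[None, :, None]
    dense = v[:, None, :] * (1.0 - f) + nxt[:, None, :] * f
    return dense.reshape(-1, 2)


# ---------------------------------------------------------------------------
# polar representation
# ---------------------------------------------------------------------------

@dataclass
class PolarContour:
    """Contour as an angle-dependent radius function about its centroid.

    ``phi`` is measured from the flow axis by the two-argument arctangent and
    is strictly increasing, starting at the vertex nearest -pi.  ``dphi`` are
    the trapezoid-style angular weights used by the discrete transform; they
    telescope to 2*pi.
    """

    r: np.ndarray
    phi: np.ndarray
    dphi: np.ndarray
    com: tuple[float, float]
    area: float
    perimeter: float

    @property
    def n_points(self) -> int:
        return self.r.size


def polar_transform(vertices: np.ndarray) -> PolarContour:
    """Transform a (dense) closed polygon to polar form about its centroid.

    The contour must be star-shaped about the centroid (guaranteed for convex
    polygons): after unwrapping, the vertex angles must sweep 2*pi
    monotonically, otherwise a :class:`ShapeError` is raised.
    """
    v = np.asarray(vertices, dtype=float)
    area, perim, (xc, yc) = polygon_geometry(v)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    dx, dy = v[:, 0] - xc, v[:, 1] - yc
    r = np.hypot(dx, dy)
    if np.any(r <= 0):
        raise ShapeError("vertex coincides with centroid")
    phi = np.arctan2(dy, dx)

    # enforce a counterclockwise sweep, then rotate to start nearest -pi
    x, y = v[:, 0], v[:, 1]
    if (x * np.roll(y, -1) - np.roll(x, -1) * y).sum() < 0:
        r, phi = r[::-1], phi[::-1]
    start = int(np.argmin(phi))
    r = np.roll(r, -start)
    phi = np.roll(phi, -start)
    # unwrap: phi must now be non-decreasing over one revolution
    corr = np.cumsum(np.diff(phi) < -np.pi)  # jumps across the +pi/-pi cut
    phi = phi.copy()
    phi[1:] += 2.0 * np.pi * corr
    if np.any(np.diff(phi) < 0) or phi[-1] - phi[0] >= 2.0 * np.pi:
        raise ShapeError("contour is not star-shaped about its centroid")

    nxt = np.roll(phi, -1).copy()
    prv = np.roll(phi, 1).copy()
    nxt[-1] += 2.0 * np.pi
    prv[0] -= 2.0 * np.pi
    dphi = 0.5 * (phi - prv) + 0.5 * (nxt - phi)
    return PolarContour(r=r, phi=phi, dphi=dphi, com=(xc, yc),
                        area=area, perimeter=perim)


# ---------------------------------------------------------------------------
# Fourier coefficients
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpectrum:
    """Radial Fourier coefficients of one contour.

    ``a[k]`` and ``b[k]`` (b[0] is fixed at 0) carry units of length unless
    ``normalized`` is set, in which case all coefficients were divided by a0
    (size-invariant representation; a0 entry becomes 1).  a0 equals twice the
    mean radius, so a0/2 is the effective cell radius.
    """

    a: np.ndarray
    b: np.ndarray
    normalized: bool = False

    @property
    def k_max(self) -> int:
        return self.a.size - 1

    @property
    def radius(self) -> float:
        if self.normalized:
            raise ValueError("radius undefined for a normalized spectrum")
        return float(self.a[0]) / 2.0

    def normalize(self) -> "ShapeSpectrum":
        if self.normalized:
            return self
        a0 = self.a[0]
        if a0 <= 0:
            raise ShapeError("a0 must be positive to normalize")
        return ShapeSpectrum(a=self.a / a0, b=self.b / a0, normalized=True)


def fourier_coefficients(pc: PolarContour, k_max: int = K_MAX_DEFAULT,
                         normalized: bool = False) -> ShapeSpectrum:
    """Discrete radial Fourier transform with trapezoid angular weights.

    a_k = (1/pi) * sum_n r_n cos(k phi_n) dphi_n   (k >= 0)
    b_k = (1/pi) * sum_n r_n sin(k phi_n) dphi_n   (k >= 1)
    """
    k = np.arange(k_max + 1)[:, None]
    w = pc.r * pc.dphi / np.pi
    a = (np.cos(k * pc.phi[None, :]) * w[None, :]).sum(axis=1)
    b = (np.sin(k * pc.phi[None, :]) * w[None, :]).sum(axis=1)
    b[0] = 0.0
    spec = ShapeSpectrum(a=a, b=b, normalized=False)
    return spec.normalize() if normalized else spec


# ---------------------------------------------------------------------------
# parity reconstruction
# ---------------------------------------------------------------------------

Parity = Literal["even", "odd", "full"]


@dataclass
class ReconstructedContour:
    """Contour resampled from a parity subset of the spectrum.

    r_rec(phi) = a0/2 + sum_{k in orders} [a_k cos(k phi) + b_k sin(k phi)]
    evaluated on ``n_angles`` uniform angles; area, perimeter and deformation
    are those of the sampled polygon.
    """

    parity: Parity
    phi: np.ndarray
    r: np.ndarray
    area: float
    perimeter: float
    d: float

    @property
    def vertices(self) -> np.ndarray:
        return np.column_stack([self.r * np.cos(self.phi),
                                self.r * np.sin(self.phi)])


def _parity_orders(parity: Parity, k_max: int) -> Sequence[int]:
    if parity == "even":
        return [k for k in EVEN_ORDERS if k <= k_max]
    if parity == "odd":
        return [k for k in ODD_ORDERS if k <= k_max]
    if parity == "full":
        return list(range(1, k_max + 1))
    raise ValueError(f"unknown parity {parity!r}")


def reconstruct_contour(spec: ShapeSpectrum, parity: Parity = "full",
                        n_angles: int = 1000,
                        include_b: bool = True) -> ReconstructedContour:
    """Evaluate the parity-restricted radius function and its deformation.

    The even variant keeps a0 and orders 2,4,6,8; the odd variant a0 and
    1,3,5,7,9; ``full`` keeps all ten cosine orders.  Sine coefficients are
    carried along by default — they matter for cells displaced from the
    channel centreline — but can be dropped with ``include_b=False``.
    A negative reconstructed radius anywhere is a :class:`ShapeError`.
    """
    if spec.normalized:
        raise ShapeError("reconstruction needs unnormalized (length-unit) coefficients")
    if n_angles < 64:
        raise ValueError("n_angles must be >= 64")
    phi = np.linspace(-np.pi, np.pi, n_angles, endpoint=False)
    r = np.full(n_angles, spec.a[0] / 2.0)
    for k in _parity_orders(parity, spec.k_max):
        r += spec.a[k] * np.cos(k * phi)
        if include_b:
            r += spec.b[k] * np.sin(k * phi)
    if np.any(r <= 0):
        raise ShapeError(f"{parity} reconstruction produced non-positive radius")
    verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    area, perim, _ = polygon_geometry(verts)
    d = max(0.0, 1.0 - 2.0 * np.sqrt(np.pi * area) / perim)
    return ReconstructedContour(parity=parity, phi=phi, r=r,
                                area=area, perimeter=perim, d=d)


# ---------------------------------------------------------------------------
# per-track decomposition
# ---------------------------------------------------------------------------

@dataclass
class DeformationTrace:
    """Per-cell time series of raw and parity-reconstructed deformation.

    ``d_even`` is the inlet-response trace (alias ``d_inlet``), ``d_odd`` the
    channel-response trace (alias ``d_channel``); ``a0`` tracks cell size.
    ``z`` is the centre-of-mass position along the flow axis in micrometres,
    zero at the channel inlet.
    """

    cell_id: int | str
    times: np.ndarray
    z: np.ndarray
    d_raw: np.ndarray
    d_even: np.ndarray
    d_odd: np.ndarray
    a0: np.ndarray
    spectra: list[ShapeSpectrum] = field(default_factory=list, repr=False)
    n_failed: int = 0

    @property
    def d_inlet(self) -> np.ndarray:
        return self.d_even

    @property
    def d_channel(self) -> np.ndarray:
        return self.d_odd

    def __len__(self) -> int:
        return self.times.size


def analyze_contour(vertices: np.ndarray, k_interp: int = 49,
                    k_max: int = K_MAX_DEFAULT, n_angles: int = 1000,
                    include_b: bool = True, hull: bool = True):
    """Full single-contour chain: hull -> interpolate -> polar -> spectrum
    -> parity reconstructions.

    Returns ``(spectrum, d_raw, d_even, d_odd)``.
    """
    if hull:
        vertices = convex_hull_polygon(vertices)
    dense = interpolate_contour(vertices, k_interp)
    pc = polar_transform(dense)
    spec = fourier_coefficients(pc, k_max=k_max)
    d_raw = max(0.0, 1.0 - 2.0 * np.sqrt(np.pi * pc.area) / pc.perimeter)
    rec_e = reconstruct_contour(spec, "even", n_angles, include_b)
    rec_o = reconstruct_contour(spec, "odd", n_angles, include_b)
    return spec, d_raw, rec_e.d, rec_o.d


def decompose_trace(contours: Sequence[np.ndarray], times: Sequence[float],
                    z: Sequence[float], cell_id: int | str = 0,
                    min_points: int = 14, max_fail_frac: float = 0.2,
                    k_interp: int = 49, n_angles: int = 1000,
                    include_b: bool = True) -> DeformationTrace:
    """Decompose a tracked contour sequence into deformation traces.

    Each frame runs the full chain; frames whose reconstruction fails (e.g.
    negative radius) are dropped.  The trace is rejected (``ShapeError``)
    when fewer than ``min_points`` frames survive or more than
    ``max_fail_frac`` of the frames fail.
    """
    if len(contours) < min_points:
        raise ShapeError(
            f"track has {len(contours)} contours; need >= {min_points}")
    rows, failed = [], 0
    for cont, t, zi in zip(contours, times, z):
        try:
            spec, d_raw, d_e, d_o = analyze_contour(
                cont, k_interp=k_interp, n_angles=n_angles, include_b=include_b)
        except ShapeError:
            failed += 1
            continue
        rows.append((t, zi, d_raw, d_e, d_o, spec))
    if failed > max_fail_frac * len(contours) or len(rows) < min_points:
        raise ShapeError(
            f"trace rejected: {failed}/{len(contours)} frames failed analysis")
    t, zz, dr, de, do, specs = zip(*rows)
    return DeformationTrace(
        cell_id=cell_id, times=np.asarray(t), z=np.asarray(zz),
        d_raw=np.asarray(dr), d_even=np.asarray(de), d_odd=np.asarray(do),
        a0=np.asarray([s.a[0] for s in specs]), spectra=list(specs),
        n_failed=failed)
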