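# Methods

`drtdc` implements dynamic single-cell mechanophenotyping in a microfluidic
constriction: cells flowing through a narrow channel are imaged at
kilohertz frame rates, their contours are decomposed into radial Fourier
shape modes, and the time course of the mode content is fitted with a
linear viscoelastic (Kelvin–Voigt) creep model to give an apparent Young's
modulus *E* and apparent viscosity *η* per cell.

## Measurement model

**Deformation.** For a closed contour with projected area *A* and perimeter
*P*, deformation is one minus circularity,

    d = 1 − c = 1 − 2√(πA) / P,

zero for a circle and positive otherwise.  Area, perimeter and centroid are
computed with the shoelace sums on the polygon.

**Shape modes.** The convex hull of the contour is interpolated with 49
points per edge, transformed to polar coordinates (r_n, φ_n) about its area
centroid, and expanded as

    a_k = (1/π) Σ_n r_n cos(k φ_n) Δφ_n     (k = 0…9)
    b_k = (1/π) Σ_n r_n sin(k φ_n) Δφ_n     (k = 1…9)

with trapezoid-style angular weights Δφ_n = ½(φ_{n+1} − φ_{n−1}) (cyclic).
a₀ is twice the mean radius (cell size), a₁ eccentricity, a₂ ellipticity;
b_k encode angular orientation and centre on zero for cells on the channel
axis.  The edge interpolation is not cosmetic: hull chords subtend large
angular gaps, and the radius along a straight chord is not linear in φ, so
the quadrature needs the dense sampling to be stable.

**Parity separation.** Two truncated resyntheses at 1000 uniform angles,

    r_even(φ) = a₀/2 + Σ_{k=2,4,6,8} [a_k cos kφ + b_k sin kφ]
    r_odd (φ) = a₀/2 + Σ_{k=1,3,5,7,9} [a_k cos kφ + b_k sin kφ],

yield two deformation traces per cell.  Even (fore–aft symmetric) modes
respond to the stress peak at the channel inlet: `d_even` (= `d_inlet`)
peaks at the inlet and relaxes.  Odd (fore–aft antisymmetric) modes respond
to the constant stress inside the channel: `d_odd` (= `d_channel`) starts at
zero — for *any* initial cell shape, which is what makes the method
shape-independent — and saturates towards the outlet as the cell develops
its bullet profile.  Sine terms are carried through reconstruction by
default; they matter for cells displaced from the channel centreline.

**Creep fits.** Each trace segment is fitted with

    d(t) = d₀ + d̂ exp(−t/τ),

by bounded nonlinear least squares (trust-region; initial guesses d₀ = last
value, d̂ = first − last, τ = ⅓ span; bounds τ ∈ [dt/10, 100·span]); the
sign convention is d̂_inlet = +d̂ (relaxation) and d̂_channel = −d̂
(saturation).  Time is referenced to the segment start, which makes τ and
d₀ invariant to where the segment is cut.  Fits with a coefficient of
correlation r² = 1 − SS_res/SS_tot below 0.6 are rejected with a reason.
The inlet segment runs from the maximum of `d_even` to 40% of the channel
length; the channel segment from the first in-channel frame to the outlet.

**Material parameters.** The steady-state channel deformation relative to
the pre-inlet baseline, d̂_channel, is converted to an apparent Young's
modulus through a calibration look-up table (cell diameter × deformation →
E, bilinear interpolation); tables derived from hydrodynamic stress models
are read from CSV.  The bundled `linear_elastic_table` is a synthetic
stand-in, E = σ_channel·g/d̂, matched to the simulator's strain gain so the
synthetic world is self-consistent.  With the Kelvin–Voigt identity
τ_channel = η/E the apparent viscosity follows as η = E·τ_channel.  A
power-law creep compliance J(t) = (1/E)(t/t₀)^β (t₀ = 1 s; strain scale set
by the ~10% peak surface-displacement estimate) is available for model
comparison; on Kelvin–Voigt data the exponential fit has the smaller RMSE.

**Channel constants.** Mean surface stresses and shear rates from
hydrodynamic simulations enter as configuration constants per measurement
condition: 142 Pa / 5100 s⁻¹ (30 µm channel, 8 nl s⁻¹), 216 Pa / 9700 s⁻¹
and 128 Pa / 8600 s⁻¹ (20 µm channel, 4 nl s⁻¹).  The shear-thinning
methylcellulose carriers are modelled as η(γ̇) = K(γ̇/γ̇₀)^(n−1) with
K = 0.16 Pa s, n = 0.74 (0.6% MC) and K = 0.60 Pa s, n = 0.64 (1% MC),
γ̇₀ = 1 s⁻¹.

## Imaging

Frames are thresholded (Otsu by default, fixed threshold available), and
each connected component above 50 px² is outlined by marching squares on
the intensity image.  The border is then refined along local normals by
re-interpolating the threshold crossing of the intensity ramp — marching
squares alone has a structured sub-pixel bias of up to ~0.2 px that
systematically attenuates fine shape features — followed by periodic
Savitzky–Golay smoothing (window 9, order 2) of the polyline before the
convex hull; without the smoothing, the hull bridges over localization
noise peaks and biases the bullet asymmetry inward.  The border level is
the half-max between the background and interior plateaus of the component,
which on a ramp edge is the mid-coverage surface regardless of where the
global threshold fell.

Tracking uses a moving 250 × 80 px sub-region: a track opens when a
component appears in the inlet region; when the cell's centre of mass
exceeds (strictly) 70% of the ROI length the ROI advances by 48% of its
length, so slow and fast cells alike stay in their own ROI.  Tracks are
excluded, with counted reasons, on collision (two components in one ROI),
fewer than 14 observations, or no net displacement (debris).

## Synthetic data generator

The generator emulates one cell translating at constant speed (default
8.9 mm s⁻¹, the mean flow speed at 8 nl s⁻¹ in a 30 µm channel) through a
300 µm channel imaged at 0.34 µm/px and 4000 fps, giving ~135 in-channel
samples per trace.  Two shape drivers act on a circle of radius 7.5 µm:

* an elliptical elongation along the flow axis (cosine order 2), driven by
  the Kelvin–Voigt response to a half-Gaussian stress pulse (width 15 µm)
  peaking at the inlet, scaled so the even-trace peak equals
  `inlet_peak_amp` (default 0.03);
* a bullet template (odd cosine orders 1–9; the odd-harmonic content of a
  rear-flattened circle, Lanczos-tapered to remove the chord kink, with the
  order-1 coefficient adjusted to keep the centroid fixed), driven by the
  Kelvin–Voigt creep under the in-channel step stress σ_channel (142 Pa).

Because deformation is quadratic in mode amplitude near a circle, the
generator specifies the ground truth on the *deformation* traces (where the
exponential creep law lives) and inverts the measurement functional
numerically per frame — a log–log secant iteration on the monotone
amplitude→deformation map, warm-started frame to frame — so the measured
`d_odd` of the noiseless contours follows the Kelvin–Voigt creep to better
than 0.1%.  Strain maps to deformation with a fixed gain of 0.05, chosen
once so that over E ∈ [0.1, 2] kPa at 142 Pa the steady bullet deformation
(0.004–0.07) stays inside what convex-hull contours can represent: because
the hull of any contour is convex, a strong fore–aft asymmetry necessarily
carries some even Fourier content (clean odd-parity deformation saturates
near ~0.1), so the realized even trace relaxes into a small bullet-set
steady state rather than to zero — as the even modes of real cells do.
`d_even_true` therefore records the realized (measured-on-noiseless-
contours) even trace, while `d_odd_true` is the exact Kelvin–Voigt target.

Contour noise is i.i.d. Gaussian, radial, per vertex, applied before the
downstream hull.  Frames are rendered by supersampled rasterization (4×4
subpixels, box-averaged), giving soft one-pixel edge ramps like the finite
optical blur of a bright-field camera; `supersample=1` gives hard binary
pixels.  All randomness flows from a single seed; identical seeds give
identical outputs.

### What the generator does not emulate

Optical artefacts (diffraction rings, defocus, illumination gradients),
cell rotation and off-axis migration, velocity changes along the channel,
non-convex or textured cells, and cell-to-cell variation of the stress
field.  Passing the recovery tests therefore shows that the analysis chain
is correct and unbiased under the stated imaging model, not that the
instrument-specific segmentation of real video is solved.

## Validated operating window

End-to-end recovery (frames → tracking → modes → fits → LUT) is validated
on nine (E, η) pairs spanning E ∈ [0.1, 2] kPa and η ∈ [0.5, 10] Pa s with
τ = η/E kept in 5–22 ms; medians over replicate cells recover E, η and τ
within 5% (noiseless) and the median τ over 100 cells with 2%-of-radius
contour noise within 10%.  The τ window is a property of the experiment,
not of the code: a relaxation much faster than a few frame intervals
(τ ≲ 1 ms at 4 kHz) leaves too few samples on the rising flank of a
~0.004–0.07 deformation signal, and a relaxation much slower than the
~34 ms transit never approaches its plateau, making τ and d̂ jointly
ill-conditioned.  Outside this window single-trace estimates degrade
gracefully (they remain unbiased in the noiseless contour-level chain,
where the full grid recovers to <0.2%) but ensemble averaging would be
required in practice.

## Numerical choices and degenerate inputs

* Deformation is clipped at 0 when discretization pushes circularity
  marginally above 1.
* Non-star-shaped contours (angles not monotone about the centroid) raise a
  shape error; the hull step makes this unreachable for real components.
* Reconstructions with non-positive radius anywhere are errors; affected
  frames are dropped, and a trace is rejected when more than 20% of its
  frames fail or fewer than 14 survive.
* The τ lower bound dt/10 and upper bound 100·span keep the optimizer away
  from digitization artefacts; a τ at its bound is flagged, not silently
  accepted, as is a channel fit without a reached plateau.
* Calibration look-up queries outside the table hull raise a range error
  listing the hull rather than extrapolating.
* The log-normal population fit excludes points outside ±3σ in log space
  and refits once; degenerate (constant) samples are errors.

## Known limitations

* The inlet stress transient is not parameterized by the underlying
  physics; the half-Gaussian pulse is a documented stand-in, so τ_inlet
  recovery is qualitative (the trace peaks and relaxes) rather than exact.
* The analytical stress→modulus model behind real calibration tables is out
  of scope; only the table interface and a synthetic linear-elastic table
  ship with the package.
* One cell per ROI: colliding cells are excluded, not disentangled.
* Population statistics beyond the log-normal fit (mixed models,
  classification) are intentionally left to external statistical software;
  the per-cell CSV is the hand-off point.
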