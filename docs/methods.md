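# Methods

`saxsdic` implements a scanning small-angle X-ray scattering (SAXS)
nanomechanical-imaging pipeline for fibrous connective tissue: reduction of
2-D detector frames to 1-D profiles, per-point peak fitting of the collagen
and interfibrillar scattering, assembly of nanoscale parameter maps over the
scan grid, and diffraction-contrast digital image correlation (DIC) between
load states to measure spatially resolved fibril strain and reorientation.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data generator does and does not
emulate.

## Geometry and reduction

A flat photon-counting detector (Pilatus-2M class: 1475 × 1679 px, 172 μm
pitch) sits a distance L behind the sample; the reference configuration is
L = 5.5 m at 14 keV (λ = 1.23984/E nm·keV = 0.08856 nm). A pixel at radius
r from the beam center scatters at 2θ = atan(r/L) and probes
q = (4π/λ)·sin θ. The full trigonometric mapping is used — the small-angle
approximation is avoided because it costs nothing and removes a modelling
decision. The azimuth χ is counterclockwise from the detector +x (column)
axis in degrees on [0, 360), so a pixel displaced along +y (increasing row)
has χ = 90°; this convention is `atan2`-native and is stated here because
different beamline tools disagree on the χ origin.

Radial I(q) and azimuthal I(χ) profiles are the *mean* unmasked pixel count
per bin (not the sum), so intensities are comparable between bins with
different pixel populations; the pixel count per bin is kept alongside.
Empty bins are flagged (NaN, zero population), never interpolated, and
masked pixels (beamstop, gaps) are excluded, never imputed. The azimuthal
band for I(χ) of the 5th collagen order defaults to the radial fit window
0.40–0.52 nm⁻¹, and is configurable since the exact inner/outer rings used
in practice vary.

The sample–detector distance can be refined from calibrant rings (e.g.
silver behenate): the predicted ring radius is linear in L, so the
least-squares distance is closed-form; inconsistent rings (rms residual
above 0.5 px by default) flag the result rather than failing.

## Peak models

**Collagen (meridional).** Collagen fibrils have an axial stagger period
D ≈ 65–67 nm giving meridional orders at qₙ = n·2π/D. The 5th order
(window 0.40–0.52 nm⁻¹) is fitted because the diffuse background is gentle
there, with

    I(q) = A·exp(−(q − q₀₅)²/(2σ²)) + B·exp(−q·τ)

The D-period is D = 10π/q₀₅, the axial width w_q = σ, and the
background-corrected collagen peak intensity I_c = A·σ·√(2π). An
exponential diffuse background is the default; a linear sloping background
is available as a config switch (both appear in practice, and the choice is
recorded on the result object). Widths are reported as Gaussian sigma with
FWHM available as an accessor, since quoted peak widths in the field rarely
state which convention they use.

Initialization is deterministic: background from the window endpoints, the
center from the argmax of the detrended window, sigma from one twelfth of
the window width. Non-convergence, degenerate (constant) windows, and
centers pinned to a window edge return flagged results — never exceptions —
so batch fitting of thousands of scan points survives bad points. Fitted
D outside 60–72 nm (or D_IFC outside 50–200 nm) is flagged implausible but
not rejected.

**Interfibrillar component (IFC, equatorial).** A broad equatorial peak
with fundamental spacing ~88–100 nm is fitted with the same model family at
its 2nd order (D_IFC = 4π/q₂; default window 0.115–0.15 nm⁻¹, matching
D_IFC ∈ 88–100 nm). The 1st order sits partly behind the beamstop and is
not used.

**Azimuthal orientation.** I(χ) carries two 180°-separated lobes from the
in-plane fibril orientation distribution. The model is a pair of Gaussians
with a shared width and free amplitudes (Ewald-sphere tilt makes the pair
asymmetric in real patterns) plus wrap replicates at ±360°, which is the
standard wrap-around correction for the 0°→360° seam. The fit returns the
mean fibril angle χ₀ reduced mod 180° (with the raw lobe position kept),
and the angular width w_χ. Near-uniform profiles are flagged isotropic when
the fitted lobe amplitude is below 3× the residual noise — the threshold is
a package choice, stated here because no standard value exists.

**Integrated quantities.** I_total is the trapezoidal area under I(q) over
populated bins. Meridional order-intensity ratios Iₙ/I₅ fit each order in
its own window (halfwidth 0.03 nm⁻¹ by default) with the same model family;
an order whose amplitude is below 3× the residual noise is flagged
"no-peak" but its (tiny) area is still reported so ratios of extinct orders
remain measurable.

## Scan maps

Per-point fit tables (row-major raster, x fastest) are placed on the scan
grid with missing or non-converged points masked. Spacing maps (D, D_IFC)
are thresholded on their companion intensity maps (I_c, I_ifc) to suppress
artefactual spacings where there is no peak; the threshold is monotone and
idempotent. For DIC, maps are rendered to 8- or 16-bit grayscale with a
linear scale over the 1st–99th percentile of valid cells by default (hot
cells would otherwise compress the usable contrast); masked cells render as
0. The two load states share a common gray scale so DIC sees the same
contrast transfer in both images.

## DIC engine

Subset-based correlation with the parameters used for diffraction-contrast
maps: 25 × 25 px subsets with a 3 px step on full-size maps (the pipeline
scales the subset down to 11 px with step 1 on small desk-scale maps, since
a map pixel is a scan point), round weighted windows, degree-6 spline gray
interpolation, and a 7 × 7-subset strain window.

* **Similarity.** Zero-normalized cross correlation (ZNCC), invariant to
  the gain/offset differences expected between exposures.
* **Round window.** Circular support of radius (subset−1)/2 with a
  raised-cosine radial taper (1 at the center, 0 at the rim). The exact
  taper used by commercial packages is unpublished; this one is documented
  and configurable in principle through `round_window_weights`.
* **Search.** Integer-pixel ZNCC search within `search_radius`, optionally
  seeded by a 2× downsampled pre-pass (`pyramid=True`) for large
  deformations, followed by inverse-compositional Gauss–Newton on a
  translation + affine subset shape function. Convergence at an update norm
  below 10⁻⁴ px (translation plus affine terms scaled by the subset radius)
  or 50 iterations; the optimizer is fully deterministic.
* **Interpolation.** scipy caps `map_coordinates` at spline order 5, so the
  degree-6 interpolant is a tensor-product B-spline assembled from two 1-D
  interpolating splines and evaluated with `NdBSpline`; it reproduces
  degree-6 polynomials to ~10⁻¹¹ and the image nodes to ~10⁻¹⁴.
* **Borders.** Images are mirror-padded so subsets near borders remain
  evaluable. Because the mirrored gray levels are fabricated, such subsets
  are best-effort: the field carries an `interior` mask (subset support
  fully inside the frame) and accuracy claims apply to interior subsets.
  On synthetic speckle the interior accuracy is ~10⁻⁴ px RMS for subpixel
  translations; border subsets can err by several tenths of a pixel.
* **Validity.** Zero-variance subsets, diverged iterations, subsets with
  more than half their window weight masked, and final ZNCC below
  `correlation_min` (default 0.5) are invalid; invalid cells are NaN.
* **Strain.** At each subset, u and v are plane-fitted over the
  surrounding strain window (least squares, physical spacing = subset
  step); exx = ∂u/∂x, eyy = ∂v/∂y, exy = ½(∂u/∂y + ∂v/∂x). Cells need at
  least half the window valid and never fewer than 6 subsets.

## Point matching and fibril mechanics

Reference scan points are carried through the displacement field (bilinear
interpolation on the subset grid; points outside the hull fall back to the
nearest valid subset and are flagged) and snapped to the *nearest* deformed
scan point. Snapping rather than interpolating is deliberate: D is a
per-volume fitted quantity and interpolating it would mix physically
distinct tissue volumes. The snap distance is recorded so users can filter;
snaps beyond one scan step are flagged.

Per matched pair: fibril strain ε_F = (D_def − D_ref)/D_ref; reorientation
is the change in the deviation of χ₀ from the loading axis, computed on the
180°-periodic circle (shortest arc), positive toward the axis. The loading
axis defaults to 90° (vertical), matching a vertical tensile geometry.
Distribution summaries use a Gaussian KDE with Silverman's bandwidth (no
standard choice exists for these histograms; Silverman is the conventional
default) and report the mode as the argmax on a 512-point grid.

For populations of orientations the package reports both the circular
standard deviation (180°-periodic) and the RMS deviation from the loading
axis. The latter is the right measure of "narrowing around the axis" when
the orientation field straddles the axis' antipode (0°/180°): each point
can move toward the axis while the circular sd about the circular *mean*
grows, because the compressed distribution becomes bimodal about the axis.

## Synthetic data: what it emulates, and what it does not

`simulate_frame` builds the expected count per pixel as: exponential
diffuse background A·exp(−q·τ); meridional collagen orders n = 1..6 as
Gaussian rings at n·2π/D with angular lobes at χ₀ and χ₀+180°, and order
amplitudes proportional to |cₙ|² of a two-level axial step density with gap
fraction f = 1 − overlap (cₙ = sin(πnf)/(πn), so even orders vanish at
f = ½); IFC rings at orders m = 1, 2 of the interfibrillar spacing with
lobes rotated 90° from χ₀ and the fundamental partly under the beamstop;
then Poisson sampling (photon-counting detector — no read noise) and a
circular beamstop mask. Identical seeds give bit-identical frames.

Default ground truth: D = 65 nm, overlap fraction 0.52 (odd orders dominant,
as in hydrated collagen), χ₀ = 161°, angular spread 25°, collagen ring
width 0.003 nm⁻¹ and IFC width 0.016 nm⁻¹ (the widths quoted for these two
features), IFC spacing 95 nm, and count levels giving a few tens of counts
at the lobe maxima — a realistic 1 s microfocus exposure scale.

Desk-scale geometry keeps the real distance and energy but chooses the
pixel pitch so q ≈ 0.9 nm⁻¹ falls at half the frame: this preserves the q
range that actually carries collagen orders 1–6 and IFC 1–2, and at
256–512 px it leaves the 5th-order ring with adequate radial sampling.
Full-size frames are supported but not the default.

Heterogeneous scans modulate the weights log-normally (CV 0.6) and D, χ₀,
and the IFC spacing with smooth band-limited fields (correlation length
~3 scan steps) — this is the microscale heterogeneity that gives the
diffraction-contrast texture DIC needs. `simulate_deformed_scan` re-rasters
the same lab grid over warped tissue: scan point (i,j) images material
point warp⁻¹(i,j), with field values interpolated bilinearly (orientation
on the doubled-angle circle), the D-period scaled by 1 + ΔD/D, χ₀ pulled
toward the loading axis by a factor, and background-only truth outside the
tissue. The true point correspondence is returned as the matching oracle.

What the generator does **not** emulate: rigorous cylinder form factors and
Ewald-sphere projection of tilted fibrils (3-D orientation effects on peak
intensity), detector flat-field and polarization corrections (the analysis
uses relative intensities only), module gaps, sample absorption gradients,
and non-affine texture evolution between load steps (the deformed map is
the same tissue texture, warped — real tissue also changes intensity
locally as fibrils reorient through the Ewald condition). Passing the
synthetic recovery tests therefore demonstrates the correctness of the
reduction/fitting/DIC chain under the stated noise model, not robustness to
every instrumental artefact of a real beamline.

## Study-scale choices for tests and the acceptance script

Parameter-recovery checks run profile-level simulations over a grid of
truths (D ∈ [64, 66] nm, σ ∈ [0.002, 0.006] nm⁻¹, SNR ∈ [10, 50]) with
0.001 nm⁻¹ radial bins. The end-to-end load step uses a 24 × 24 scan of
256 × 256 px frames, a 20% vertical stretch anchored at the bottom edge
(scans aligned from the reference edge, as in the tensile geometry),
imposed ΔD/D = 0.0015 and reorientation factor 0.6; this is the smallest
configuration at which the map texture, DIC subset statistics and
per-point fit precision are all representative. DIC speckle checks use
128–160 px images with 8 px feature scale, 21 px subsets and a 4 px step.

## Known limitations

* Border DIC subsets rely on mirror-extended gray levels; their
  displacements are reported but carry no accuracy guarantee (see
  `DisplacementField.interior`).
* The IFC 2nd-order fit in its narrow default window has a soft center
  constraint for peaks as broad as 0.016 nm⁻¹; per-point D_IFC scatter of a
  few percent at realistic counts is expected and should be averaged or
  thresholded before interpretation.
* `order_ratios` fits orders independently; heavily overlapping orders
  (very broad peaks or small D) would need a joint multi-peak fit, which is
  out of scope.
* The deformed-scan generator imposes a spatially uniform ΔD/D and
  reorientation factor; spatially varying imposed fields are possible by
  editing the deformed truth array directly, but no convenience API is
  provided.
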