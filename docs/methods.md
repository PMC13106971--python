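# Methods

## Model and conventions

**Spectral phasor.** For a spectrum $I(\lambda)$ sampled on a strictly
ascending (possibly non-uniform) grid, the phasor $(g, s)$ is the pair of
normalized harmonic-$n$ Fourier coefficients over a window
$[\lambda_0, \lambda_0 + L]$. All integrals — phasor numerators and
denominator, filter mean transmissions, band integrals — use trapezoidal
quadrature on the supplied grid. Using one quadrature rule everywhere is
what makes the optical-filter route and the direct spectral transform
agree to machine precision: the filter transmission is an exact affine
function of $\cos\theta$ / $\sin\theta$, and the trapezoid rule is linear.

Orientation: phase increases with wavelength, i.e. a red-shift by
$\Delta\lambda$ rotates the phasor counter-clockwise by
$2\pi\Delta\lambda/L$. Default window: **400–700 nm, harmonic 1** — one
full period spanning all supported reporters, from NanoLuc (~460 nm) to
LumiScarlet-class red emitters. Published phasor plots differ in
orientation conventions; this one is fixed here and used consistently.

**Filter encoding.** The sine/cosine filters are modeled as raised
single-period sinusoids bounded by measured transmission extremes
$(F_{min}, F_{max})$:
$T(\lambda) = F_{min} + (F_{max}-F_{min})\,(1+\mathrm{trig}(\theta))/2$.
With this shape the filtered/reference count ratio of a pixel equals
$F_{min} + (F_{max}-F_{min})(1 + \langle \mathrm{trig}\rangle)/2$, so the
pixelwise equations
$g = 2\,(r_{COS}-F_{COS,min})/(F_{COS,max}-F_{COS,min})-1$ (and the sine
analog for $s$) recover the Fourier coefficients exactly. Physical filter
transmittance curves are not published; the raised-sinusoid model is the
assumption under which the ratio equations are exact, and the central
oracle test quantifies exactly that equivalence.

**Calibration.** Dark stacks (shutter closed) are frame-averaged and
smoothed with a 51×51 median filter (reflection borders) to give per-channel
offset images. Bright stacks of a homogeneous lamp give the splitting maps
$R = (I_{filt,bright}-I_{filt,dark})/(I_{ref,bright}-I_{ref,dark})$ after
the same average-then-median smoothing (averaging before median filtering
is a choice; the two orders differ only at outliers). Pixels with
non-positive reference excess or non-positive $R$ are masked and the count
reported; masked pixels are excluded from all downstream phasor
statistics.

**Correction modes.** The published correction multiplies the filtered
channel by $R$ (`mode="multiply"`, the default, kept for fidelity). Note
that $R$ is itself a filtered/reference ratio, so for an imbalanced
splitter multiplication *squares* the imbalance rather than cancelling it;
`mode="divide"` divides by $R$ instead and is exactly
splitter-invariant when the bright acquisition is taken **without** the
encoding filters — which is the instrument protocol modeled by
`render_calibration`'s default. Both modes coincide for a balanced 50:50
splitter. The splitter-invariance tests and the acceptance run use divide
mode and document that only it achieves invariance. (`render_calibration`
also accepts the filter pair explicitly, to model a bright acquisition
with filters left in the path; then $R$ additionally carries each filter's
flat-source mean transmission $(F_{min}+F_{max})/2$.)

**Processing chain.** Per the standard workflow: per-frame Gaussian
smoothing (σ = 1 px, reflection borders) on all four channels identically,
frame averaging (`n_average`; library default is *all* frames, the CLI
default is 20 — a hard default of 20 would error on shorter stacks),
global user-defined intensity threshold on the sum of the two reference
channels, 8-connected component labeling with an area filter, labels
renumbered by decreasing area (ties by top-left-most pixel, row-major).
Channel registration is integer-pixel translation against the INT(SIN)
reference, estimated by windowed FFT cross-correlation; a shift saturating
the search radius or a normalized correlation peak below 0.2 raises a
possible-failure warning (the weak-peak condition is what makes
structureless inputs warn reliably). Sub-pixel registration is out of
scope.

**Unmixing and clustering.** Two-component unmixing orthogonally projects
each phasor onto the reference chord — the least-squares resolution of the
overdetermined two-equations-plus-constraint system for off-chord (noisy)
points — then clamps the chord coordinate to [0, 1]; the perpendicular
distance is reported as a quality metric. Fractions are relative
*intensity* (photon) fractions; conversion to molar fractions would
require per-reporter brightness and is not attempted. Clustering is a
full-covariance Gaussian mixture (EM) with deterministic k-means++
initialization from the caller's seed and a 1e-8 covariance floor; hard
labels by maximum responsibility; cluster centers are assigned to the
nearest reference phasor (ties broken lexicographically, many-to-one
allowed with a warning). Clustering operates on pixels by default; per-cell
mean phasors can be clustered by passing the per-cell table's (g, s)
columns.

**BRET readout.** A sensor's "BRET efficiency" is defined as the clamped
normalized projection of its phasor onto the donor→acceptor chord (0 =
donor, 1 = acceptor). For mixtures of area-normalized donor/acceptor
spectra this equals the acceptor photon fraction exactly, by linearity —
the quantity actually observable from emission spectra (not a
quantum-yield-corrected FRET efficiency). Per-cell phasors are
**intensity-weighted** means of pixel phasors, equivalent to pooling the
cell's photons; they are therefore invariant to global intensity scaling.
Phase/modulation are the exact polar transform
($\phi = \mathrm{atan2}(s, g)$, $m = \sqrt{g^2+s^2}$; (0,0) → phase 0 by
convention). Time/depth series are assembled by greedy nearest-centroid
matching within a 10-pixel default radius; ambiguous matches (two
candidates in radius) take the nearest and are flagged; absent cells leave
gaps, never imputed values.

## The synthetic microscope

`synth.render_stack` emulates the four-channel rig: each pixel emits
`rate` expected photons per frame toward each camera; a splitter sends
fraction `split_sin` (resp. `split_cos`) through the encoding filter and
the rest to the unfiltered reference sensor. Poisson shot noise acts on
photon counts, then gain, a constant (or per-pixel) dark offset, and
Gaussian read noise per frame. One seed governs a render; independent
sub-streams are derived per frame and channel, so renders are
bit-reproducible. Matching dark stacks (offset + read noise) and bright
stacks (flat lamp through the splitters) are produced by
`render_calibration` with the same noise model.

Key defaults: 20 frames per acquisition and 100-frame calibration stacks
(the acquisition protocol), dark offset 100 counts, read noise 1.5
counts, gain 1, cell photon rates of order 500 photons/pixel/frame so that
a 20-frame stack reaches the ~10⁴ photons/pixel aggregate regime the
method targets. Scenes are disks with uniform interior rate; overlapping
disks add photons, which is how per-pixel two-reporter mixtures with known
fractions are built. The bundled reporter library uses synthetic Gaussian
stand-ins (realistic peak positions and widths, not measured curves).

**What is not modeled:** optical PSF/defocus, depth-dependent scattering
physics, camera nonlinearity, hot pixels, cosmic rays, flat-field spatial
nonuniformity of the lamp, and cell morphology beyond disks. Passing tests
therefore demonstrate correctness of the *analysis chain* under a
photon-limited four-channel model, not robustness to every real-microscope
artifact.

**Depth/scattering surrogate.** Tissue depth broadens phasor signatures
without moving their center. `SpectralBroadening` reproduces this with a
per-pixel zero-mean spectral shift (sd up to ~20 nm, quantized to 33
levels) whose optical throughput is attenuated as a Gaussian in the shift
magnitude (scale 5 nm). The coupling is the substantive modeling choice: a
zero-mean spectral shift alone shrinks the *intensity-weighted* phasor
centroid radially by ≈ $m\,(2\pi\,\mathrm{sd}/L)^2/2$ (~8% of modulation
at sd 20 nm), contradicting the observed fixed center; coupling
attenuation to spectral distortion — strongly scattered photons are also
strongly absorbed — caps the centroid motion (posterior rotation sd ≤
attenuation scale) while the unweighted histogram still broadens with the
full shift sd. Shifted spectra are re-normalized on the window grid, so
support clipped at the window edge is dropped; mid-window reporters should
be used with large broadenings.

## Numerical choices

- Trapezoidal quadrature everywhere; non-uniform grids supported.
- Median and Gaussian filters use reflection padding.
- `spectral_decompose` is non-negative least squares (renormalized to
  fractions summing to 1); collinear references raise rather than return
  an arbitrary split.
- Degenerate inputs: zero-total spectra raise `UndefinedPhasorError`;
  (0,0) phasors get phase 0; duplicated GMM point clouds are handled by
  the covariance floor; empty masks yield empty labelings (warning, not
  error).
- Histogram mass conservation: (g, s) values outside [-1, 1] (possible
  under noise) are clipped into the edge bins so total mass equals the
  masked pixel count.

## Problem sizes used in the validation suite

The acceptance checks run on deliberately small fields so the whole suite
completes in well under a minute on one core: 12–48 px scenes, disk radii
4–14 px, 20-frame acquisitions, 100-frame calibrations, 100 seeded
replicates for the Monte-Carlo criteria (unmixing error, time-course
monotonicity), and a 25-spectrum suite (15 Gaussian + 10 bimodal, 420–650
nm) for the filter-encoding oracle. Accuracy statements are per-pixel or
per-cell and do not depend on the field of view, so these sizes carry the
same information as full-frame runs.

## Known limitations

- The verbatim (multiply) correction mode is faithful to the published
  equations but not splitter-invariant; users with imbalanced splitters
  should use divide mode (the CLI's `simulate` writes configs with
  `correction_mode = divide` for this reason).
- Only two-component unmixing is provided; three or more co-localized
  components are not separable on a single chord.
- Reporters must be spatially separated for reliable phase-only
  discrimination; no spatial regularization of cluster labels is applied.
- No absolute photon-flux calibration or instrument spectral-response
  correction; efficiencies and fractions are photon-weighted quantities
  on the instrument's spectral scale.
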