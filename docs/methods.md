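# Methods

`mechwarp` implements the computational chain of elastic resonator
interference stress microscopy (ERISM) and its video-rate two-wavelength
variant (WARP), as used to map the vertical ground reaction forces (GRFs) of
small soft-bodied animals — the motivating system is the crawling *Drosophila*
larva on a deformable optical microcavity. This note records the models, the
numerical choices, and what the synthetic validation does and does not show.

## The sensor and its forward optical model

The sensor is a Fabry–Pérot microcavity: a soft siloxane elastomer layer
(8–12 µm, Young's modulus 10–30 kPa) between two semi-transparent gold
mirrors on glass (glass / Cr 0.5 nm / Au 10 nm / SiO₂ 50 nm / elastomer /
Au 15 nm / water). Anything pressing on the top mirror changes the local
cavity length `L`, which shifts the cavity resonances.

Reflectance is computed with the standard characteristic-matrix
(transfer-matrix) method at normal incidence. Two deliberate simplifications:

* **Normal incidence only.** The epi-illumination numerical aperture is not
  modelled; the dominant-ray approximation is standard in this kind of
  cavity interferometry.
* **Monochromatic lines.** The 1 nm-FWHM filtered LED lines are treated as
  delta functions; no spectral convolution.

Metal dispersions are tabulated literature values for Au and Cr, linearly
interpolated; dielectrics use constants (SiO₂ 1.46, elastomer 1.41, glass
1.52, water 1.33). The instrument's true optical constants are not public, so
*absolute* thickness accuracy against a physical device is not claimed —
every validation here is a self-consistent round trip through the same
forward model, which is also how the physical instrument is used (it is
calibrated against itself). All constants are overridable in the config.

Internally the matrix formulae follow the `n − ik` sign convention; material
tables supply `n + ik` and are conjugated on entry. Correctness is pinned by
three oracles: the closed-form Airy slab formula, energy conservation
(R + T = 1 to 1e−9 for lossless stacks), and an independently coded recursive
Fresnel summation on random 3–6 layer stacks (agreement to 1e−9).

## ERISM: spectral-scan thickness maps

A spectral scan images the cavity at 550–750 nm in 1 nm steps (201 frames).
Per pixel, resonance minima are detected as interior local minima of the
sampled spectrum and refined to sub-grid precision: a 3-point parabola seeds
a Newton polish on the exact quartic through the surrounding 5 samples. The
quartic step removes the parabola's ~0.05 nm bias on asymmetric dips; ties on
plateaus break toward the shorter wavelength. Minima shallower than half the
pixel's spectral range are discarded — real cavity resonances are deep dips,
while intensity noise creates shallow spurious minima.

Thickness is assigned by matching the observed minima comb against a lookup
table of modelled minima (default step 1 nm, below the instrument's
displacement precision), minimising the mean absolute wavelength discrepancy
against nearest modelled minima. A first-order refinement then exploits
dλ/dL ≈ λ/L to interpolate between table rows. Pixels with no usable minimum
are masked (optionally in-filled by nearest neighbour but still flagged);
single-minimum pixels cannot resolve the resonance order alone and take the
thickness branch nearest the median of the well-determined pixels.

Displacement is thickness minus a reference plane through the four
corner-region means (default corner size 5% × 5% of the image; the corners
are assumed animal-free). The plane fit is a least-squares fit to the four
corner centroids, which makes the operation exactly idempotent.

Round-trip performance at 128×128 px over an 8.5–9.5 µm ramp: RMS ≈ 0.01 nm
noiseless and ≈ 0.02 nm at 1% multiplicative intensity noise — far inside
the 2 nm / 10 nm acceptance bounds, because rendering and reconstruction
share the forward model and the minima-estimator bias cancels in matching.

## WARP: video-rate displacement maps

WARP alternates two illumination wavelengths (λ = 633 nm and λθ = 628 nm,
~90° of round-trip phase apart on 8–12 µm cavities, within one free spectral
range). The normalised ratio `W = (I_λ − I_λθ)/(I_λ + I_λθ)` is periodic in
thickness with period one FSR (≈ 223 nm here; the empirical period differs
from λ/2n by ~1% because of mirror-phase dispersion). Demultiplexing halves
the camera rate: 120 FPS video → 60 displacement maps/s.

**Calibration** uses a region of known thickness gradient spanning ≥ 0.5 FSR.
Pixels are folded by thickness modulo the FSR (estimated by phase-dispersion
minimisation over candidate periods, refined to 0.02 nm steps) and
bin-averaged into a dense periodic response curve (256 knots, light circular
smoothing), which is split into monotone branches; the longest branch is the
canonical strictly monotone W → offset mapping. The calibration also stores
the folded **summed-intensity** response `S(offset) = I_λ + I_λθ`
(median-normalised). S is approximately in quadrature with W, and this is
load-bearing: W alone is two-fold ambiguous within an FSR, and the two W
branches are separated by their predicted S almost everywhere (the S contrast
vanishes only at the folds, exactly where the two candidates coincide).
Masking noise-floor pixels uses a threshold of 1% of the 99th percentile of
the summed intensity.

**Reconstruction.** Per pixel and frame, thickness = anchor + offset(W) +
k·FSR. Within-FSR candidates come from every monotone branch; scoring
combines (i) distance to two temporal references — the last valid value,
which handles motion reversals, and a constant-velocity extrapolation
(exponentially smoothed rate), which handles sustained rates approaching half
an FSR per frame — and (ii) an S-disagreement penalty (1.5·FSR per unit of
normalised S mismatch) that picks the physical branch. The video's intensity
scale is tied to the calibration once, via the median observed/predicted S
ratio on the first frame (border pixels first, then all anchored pixels);
this also absorbs a channel-imbalance gain present in both calibration and
video. A per-frame spatial pass pulls back pixels that left *both* their
3×3 median neighbourhood and their own temporal track by > 0.35 FSR (the
dual condition spares genuinely narrow features such as the tripod contacts).
A candidate further than half an FSR from every reference masks the pixel
for that frame.

The first frame has no temporal reference and is unwrapped by flood fill
from the image border, which is assumed at rest (reference = the baseline
thickness map, e.g. from an ERISM scan of the resting cavity). A pixel is
masked, and does not propagate, when its assigned neighbours disagree by
> 0.45 FSR or its best candidate is > 0.25 FSR from the local reference;
enclosed regions reachable only through masked pixels stay masked rather
than being silently wrapped to the nearest order. A spatial discontinuity of
an *exact* integer number of FSRs between neighbouring pixels is physically
invisible to a two-wavelength measurement (W and S are both periodic) and
cannot be flagged; near-integer but non-exact steps are caught by the
distance gate. This is the same physics that makes mouth-hook regions with
overlapping fringes unresolvable in practice — they are masked, not solved.

Round-trip performance (forward-render → reconstruct): 0.4–0.8 nm RMS with
zero branch errors for single indentations of 800–1000 nm (3.5–4.5 FSR) and
for the full six-protopodium crawl (depths to 1400 nm, >6 FSR), with or
without 1% intensity noise. The
tracking assumes per-pixel thickness rates below ~half an FSR per frame
(≈ 110 nm per frame at 60 maps/s), which bounds the scenario ramp times.

## Stress inversion (elastic layer, Fourier domain)

The elastomer is modelled as a linear elastic layer of thickness `h` bonded
to a rigid base. For a normal surface traction of in-plane wavevector `q`,
the surface displacement response is diagonal in the Fourier domain:

    u_z(q) = C(q) σ_z(q),  C(q) = 2(1 − ν²)/(E q) · g(qh, ν)

with the bonded-layer factor derived from the plane-strain Airy solution
(clamped at z = h):

    g(x) = [(3−4ν) − 4x e^(−2x) + (4ν−3) e^(−4x)]
           / [(3−4ν) + (4x² + 16ν² − 24ν + 10) e^(−2x) + (3−4ν) e^(−4x)]

`g → 1` as `qh → ∞` (Boussinesq half-space) and `C(0) =
h(1+ν)(1−2ν)/(E(1−ν))` (confined compression); both limits are verified
analytically. The form above is numerically stable for all x; a series is
used below x = 1e−4. ν defaults to 0.495 (near-incompressible siloxane).

Inversion is Tikhonov-regularised Fourier division, σ̂ = C û/(C² + α²), with
α expressed relative to max C (the softest mode); the default 1e−3
corresponds to damping consistent with a ~2 nm displacement noise floor on
these maps. Maps are zero-padded ×2 before the FFT. Windowing a field whose
long-range surface bulge is cut off biases the near-DC modes into a uniform
stress background; since a true stress map is zero outside sparse contacts,
the median of the recovered map estimates that background robustly and is
subtracted. GRFs are |∫ negative stress| over a contact ROI, which also
excludes the residual ring artefact at the window frame — mirroring how the
measurement itself integrates per-protopodium regions.

Validation: a forward-generated point load on the default 10 µm layer is
recovered to 0.3%; a closed-form Hertz indentation profile on a
half-space-like layer integrates to the closed-form Hertz force within ~1%
(bounds: 5% and 10%); the Fourier inversion agrees with an explicit dense
impulse-response-matrix solve on 32×32 grids to 1.2% away from the 3-pixel
window frame (both windowed inversions are artefact-dominated on the frame
itself, so the comparison excludes it).

Only vertical stress is recovered; horizontal (shear) tractions are outside
the measurement principle.

## Substrate calibration: height-corrected Hertz fit

AFM force–distance curves with a glass-bead probe (radius ~8 µm) are fitted
to the spherical-indenter Hertz force with the finite-thickness correction
for a bonded, incompressible sample:

    F = (16/9) E √R δ^{3/2} (1 + 1.133χ + 1.497χ² + 1.469χ³ + 0.755χ⁴),
    χ = √(R δ)/h

Young's modulus and the contact point are fitted jointly
(`scipy.optimize.curve_fit`, initial E from the curve end-point, initial
contact point at 5% of peak force). χ > 3 triggers a validity warning. As
h → ∞ the fit reduces exactly to classical Hertz. On synthetic curves
(30 nN max force, 2% force noise, 100 repeats) the median modulus error is
< 1% and every fit has R² > 0.99.

## Kinematics

Landmark speeds are central differences (one-sided at the ends) with
optional moving-average smoothing. Footfall phases use hysteresis
thresholds: swing initiation (SI) at the upward crossing of `v_on` (default
20 µm/s), swing termination (ST) at the downward crossing of `v_off`
(default 10 µm/s), with crossing times refined by linear interpolation and
swings shorter than a minimum duration discarded. The thresholds are
conventions — the original analyses were manual — so only the recovery of
*programmed* event times is asserted (within one frame period), never
absolute latencies of real animals. Anteroposterior latency is anterior
minus posterior event time (positive = posterior row led; the sign flips for
backward waves at SI). Latency–duration relationships use ordinary least
squares. Kymographs sample displacement along an arc-length-parameterised
polyline with bilinear interpolation, width-averaged along the local normal.
Contact-onset latencies are first crossings of a displacement threshold
(default 0 nm, i.e. any indentation; an optional noise margin can be set)
with sub-frame interpolation, reported relative to a reference point.
Event-to-event delays match each source event to the first subsequent target
event within a window (default 2 s), counting unmatched sources separately.

## The synthetic crawl generator

The generator is the test substrate for everything above, so its defaults
*are* the study conditions. A scenario places `n` protopodia (default 6)
along the anteroposterior axis of a 128×192 µm field at 1 µm/pixel.

* **Indentation shape:** each protopodium's stress truth is a Hertzian
  contact-pressure patch, p₀√(1 − r²/a²) with a = √(Rδ); its displacement
  truth is the bonded layer's *own* response to that patch, computed with the
  same discrete Fourier operator the inversion uses (one FFT per patch
  position, cached) and scaled so the peak indentation equals the programmed
  depth. This makes truth stress, truth displacement and the inversion
  mutually consistent on stance frames — GRFs inverted from reconstructed
  video match the generating loads to ~1% — and reproduces the physical
  upward ring around contacts (near-incompressible layer). A closed-form
  half-space Hertz profile (`hertz_indentation_profile`) and an analytic
  Hankel-quadrature layer profile (`layer_indentation_profile`) are kept as
  grid-independent references for validating the inversion itself.
* **Force scale:** peak depths 1000–1400 nm are reverse-engineered from the
  observed per-protopodium GRF range (1–7 µN) on an E = 28 kPa, 10 µm layer
  with an effective R = 100 µm; the defaults produce 1.3–2.6 µN. Truth
  GRF/area/volume are direct summations over the truth maps within
  per-protopodium ROIs (AP strips bounded to ~2 contact radii in ML, so they
  do not collect the spread-out ringing of a windowed inversion) — never the
  inversion pipeline. An optional quadratic GRF–area law rescales the truth
  stress per frame.
* **Footfall cycle:** one forward wave (1.2 s) sweeps posterior → anterior;
  each protopodium lifts over 0.25 s at SI, travels 6 µm, and relands from
  ST with a per-pixel contact-onset field spreading posterior-first along
  AP (50 ms per 3 µm denticle row → ~0.25 s across a protopodium, matching
  the observed anterior-edge delays) and midline-first along ML (30 ms per
  3 µm); the delays grow across the contact disc only, while the elastic
  skirt follows its nearest contact row. During lift and landing the
  displacement is the stance field modulated by the ramp factors, which keeps
  threshold-crossing times exactly at the programmed onsets; transition
  frames are therefore only approximately inversion-consistent (stance
  frames are exact). The series opens with the animal settling onto the
  resting cavity, which gives the video-rate reconstruction the resting
  first frame its flood fill assumes. Scenario validation rejects timings
  whose ramps would overlap (which would create aliasing jumps in the truth
  itself).
* **Tripod:** two papillae beside the terminal protopodium deploy 0.66 s
  before the second segment's lift-off and detach at wave start; optional
  timing jitter reproduces delay statistics.
* **Droplet:** an optional static positive annulus reproduces the carried
  water droplet's upward ring qualitatively; no capillary physics, and it is
  added to displacement truth only.
* **Tracks:** two denticle-row landmarks per protopodium move at constant
  speed during their swing with programmed AP row latencies (SI latency =
  10% of wave duration, posterior-led for forward waves; ST latency 5%).

Everything is deterministic given the scenario seed.

**What the round trips do and do not show.** Passing tests demonstrate that
the implementation inverts its own forward models to specification under
realistic geometry, timing and noise. They do not validate the optical
constants against a physical device, drift or vibration between frames,
camera nonlinearity, shear-sensitive contacts, or fringe-overlap regions
(which real data handles by masking). Scenario ROIs assume protopodia stay
inside disjoint strips, which holds for the default single-wave geometry.

## Orchestration

`run_pipeline` chains simulate → erism/warp → stress → footfall → kinematics
with a validated YAML config (unknown keys rejected), writes HDF5 map
bundles with units and sign-convention metadata (float maps round-trip
bit-identically), multi-page TIFF stacks, CSV tables, and an atomic JSON
manifest (config hash, input digests, per-stage parameters and timings).
Coordinates are 0-based pixel centres, row 0 at the top, x = column; all
physical scaling goes through `pixel_size`. All randomness derives from the
config seed through named substreams. The `mechwarp` command line exposes
each stage thinly over the library.

## Problem sizes used in validation

Round trips run at the sizes the method is used at: 128×128 px spectral
scans (201 wavelengths), 128×128 px videos of ~160 map frames, 128×128
inversion grids (32×32 against the dense oracle, whose explicit matrix is
10⁶ entries), 100-curve AFM populations, and six-scenario latency
regressions.
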