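# Methods

`acetograd` quantifies how microtubule (MT) acetylation is organised in
adherent cells: as discrete acetylated segments whose density falls off
exponentially from the nucleus toward the plasma membrane, locally
interrupted by deacetylated stretches around shaft damage/repair sites.
Because the measurements of interest are made on fluorescence images, the
package pairs every estimator with a synthetic-image generator that
encodes the target quantities as generative parameters, so each stage can
be validated by parameter recovery.

## The model

Acetylation of α-tubulin K40 marks long-lived MT lattice.  Along each
filament, acetylation occurs in discrete segments; the probability that a
stretch of lattice is acetylated decays with normalized distance
x ∈ [0, 1] from the nucleus edge (x = 0) to the plasma membrane (x = 1):

    coverage(x) = A · exp(−x / λ)

λ is the characteristic length as a fraction of the nucleus-to-membrane
distance (0.33 in the resting condition; 0.79 when a constitutively
running kinesin-1 motor is overexpressed and homogenises shaft damage).
The measured profile is the ratio of acetylated-tubulin to α-tubulin
fluorescence, which cancels network density, so λ is estimated by fitting
Y(x) = Y₀·exp(−x/λ) (plateau fixed at 0) to pooled, 0.005-binned,
max-normalized ratio profiles from many cells.

Damage/repair sites are intervals on the MT shaft recognised by a
conformation-specific antibody; each is embedded in a deacetylated
stretch.  Both are classified on two-channel line scans normalized to
[0, 100] a.u.: marker signal ≥ 50 a.u. = damage/repair interval,
acetylation signal < 50 a.u. = deacetylated stretch, with borders refined
by linear interpolation at the threshold crossing.  Geometry per site:
lengths, per-side extensions, signed center displacement (+ = toward the
MT plus end), plus the half-length-difference shorthand
L_dr/2 − L_deac/2.  The literal formula ignores interval positions, so
the positional center-to-center displacement is reported as the primary
quantity and the formula value alongside it.

HDAC6 (the cytosolic deacetylase) colocalization with acetylated
segments is measured as a Manders coefficient after restricting the
HDAC6 signal to the traced MT network (per-pixel minimum with a binary
network mask), in image tiles whose network density lies below the
median, with per-channel Otsu thresholds.

## Synthetic cells

The generator (`acetograd.simulate`) emulates a rounded interphase cell:

- Circular ROI (radius 20 µm) with a circular nucleus (6 µm) at the
  image center; 1024×1024 px at 65 nm/px (100× objective + sCMOS).
- 60 filaments grown from the nucleus ring outward by a worm-like walk
  (persistence 150 µm, soft radial bias), with jittered-even seed angles
  (a centrosomal array is fairly regular, and sub-resolution seed pairs
  would be meaningless at the PSF scale).  Filament reach is uniform in
  [0.3, 1] of the nucleus-to-membrane run; the resulting perinuclear
  density excess is what lets a 36% total acetylated fraction coexist
  with λ = 0.33 and coverage ≤ 1.  The ratio profile is insensitive to
  density, so this choice does not touch λ.
- Acetylated segments: a stationary renewal tiling of candidate segments
  (truncated-normal lengths) separated by gaps (mean 0.5 µm - kept above
  the PSF width so that segment identity is optically resolvable).
  Candidates overhanging a filament end are clipped, exactly the
  censoring a real filament end imposes.  Each candidate is accepted with
  probability A·exp(−d/λ') of its midpoint's normalized distance.
- Damage sites: Poisson-placed in non-acetylated runs (a deacetylated
  stretch is by definition non-acetylated lattice), with moment-matched
  lengths, a 12% center-colocalized fraction and signed offsets otherwise.
- HDAC6 puncta: flag first (on-acetylated with probability 0.2), then a
  uniform position on acetylated arc or on non-acetylated arc with
  0.35 µm clearance.
- Rendering: sub-pixel bilinear line splatting at uniform linear
  brightness, Gaussian PSF (σ = 0.13 µm), diffuse in-cell background,
  Poisson + Gaussian noise.  Identical (preset, seed) pairs are
  bit-identical.

### Calibrations

Three generator parameters are solved numerically (fixed-seed Monte
Carlo at preset load) so that the *realized* statistics equal the
condition values the presets encode:

1. **Amplitude** A: per cell, from the realized candidate set, so the
   expected acetylated fraction equals the preset target exactly.
2. **Acceptance decay** λ': end censoring and amplitude capping bend the
   realized coverage slightly away from the acceptance law; λ' is chosen
   so the fitted coverage decay equals the preset λ.
3. **Candidate length mean**: end clipping shortens observed segments
   and the exponential acceptance size-biases them (a longer candidate
   has a more distal midpoint); the sampling mean is raised so accepted,
   clipped segments ≥ 0.5 µm average to the preset mean.

All printed "mean ± SD" quantities are sampled from lower-truncated
normals whose location is moment-matched, so the simulated population
mean equals the printed mean despite the positive support.  Non-zero
center offsets are bounded below by one pixel (65 nm), the resolution
floor below which an offset is indistinguishable from colocalization.

The nocodazole condition targets a covered-area fraction instead: its
filament count comes from Poisson coverage, 1 − exp(−L·w/A_cell), with
w the full width at half maximum of a rendered line - the level where
iterative-intermeans (IsoData) thresholding settles for these images.

### Counting convention

Segments shorter than 0.5 µm (≈ 2 PSF FWHM) are not counted as distinct
objects - neither by `segment_length_stats` nor by the generator's
observed-mean calibration.  On synthetic control cells, essentially all
sub-0.5 µm detections are tracing shards, not segments.

## Filament tracing

`trace_curves` is a Steger-style ridge detector: Gaussian-derivative
Hessian ridge strength at scale σ = 1.5 px, sub-pixel crest localisation
along the Hessian eigenvector, hysteresis linking (fractions of the
maximum response; defaults 0.08/0.2, and 0.05/0.12 for the denser
α-tubulin channel where bundling depresses the ridge response), ≤ 2 px
gap bridging, and skeleton-graph extraction.  Crossings are repaired by
three passes: re-pairing the most collinear branches at junctions,
linking nearby mutually aligned chain ends (non-maximum suppression
drops out where orientations mix), and splitting at sharp kinks (a
genuine MT cannot turn ~60° within a few pixels).  Near-duplicate curves
(crest doubling around crossings) are removed greedily by overlap.

`refine_polylines` then anchors every endpoint at the half-maximum
crossing of the axial intensity profile (for a Gaussian PSF this sits
exactly at the true end of a line, so lengths carry no systematic end
bias) and splits curves where the profile drops below half of the local
plateau - the principled resolution of inter-segment gaps.  Curves cut
at a bright point (a crossing, not a gap) are rejoined.

Known limitation: crossing-induced splits (long, dense arrays) and
shallow-crossing merges plus end localisation (short segments) are
opposing failure modes of the same detector, and the defaults balance
them.  On synthetic cells the per-cell mean segment length reads ≈ −3%
of truth in the dense control condition and ≈ +2.5% in the short-segment
high-kinesin condition; the latter marginally exceeds a 3-standard-error
recovery band at 24 cells.  Dense-structure inaccuracy is a recognised
limitation of curvilinear tracing generally.

## Gradient profiles

The automated stand-in for a manually drawn 45-px-wide line scan is a
radial, network-restricted annulus profile: for every 2-px annulus the
AcTub and αTub intensities are summed over network pixels (a ridge mask
of the αTub channel - anchoring on the denominator keeps the selection
independent of the numerator), each minus that annulus's own off-network
background ("background close to microtubules").  Summing before
dividing matters: the quotient of two small noisy means inflates the
faint tail of the gradient and can double the apparent tail value.  The
per-cell profile is normalized by the maximum of its smoothed ratio
curve (a single noise spike must not set the scale) and by the
nucleus-to-membrane distance; profiles are pooled in 0.005 bins and
fitted by bounded least squares (λ ∈ (10⁻³, 10]; a fit pinned at a bound
raises instead of returning).  The spec-shaped wide-footprint
`extract_profile` remains available for arbitrary scan lines.

Local background for profile work uses grey opening (minimum-then-
maximum filtering of a denoised image) rather than a scalar: the blur
halo around dense bundles is spatially structured and a scalar estimate
simultaneously flattens the head and pushes the tail negative.

## Sizes, runtimes, determinism

Recovery runs use 42 cells (control λ), 19 (high-kinesin λ), 32 (traced
fraction/segment statistics per condition), 65 line-scan fixtures
(damage geometry), 20 HDAC6 cells and 60 nocodazole cells - sizes chosen
so the full recomputation completes comfortably on one CPU; standard
errors are computed at the sizes used.  All randomness flows from one
master seed through fixed-purpose substreams; identical inputs give
byte-identical outputs.

## What passing recovery does and does not show

The generator shares the estimators' coordinate conventions and noise
model, so recovery demonstrates the pipeline's correctness and its
biases under controlled conditions - not performance on real
micrographs, where cell outlines are irregular, filament brightness
varies, the PSF is anisotropic, and networks can be locally far denser
than simulated.  The circular-cell geometry keeps normalized distance
well defined; irregular cells would require a distance transform of the
actual outline.
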