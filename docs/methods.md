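# Methods

## The assay and what the pipeline measures

In the single-molecule strand-separation assay, biotinylated DNA
scaffolds are immobilized on a passivated coverslip and imaged by TIRF
microscopy as diffraction-limited fluorescent spots. When the
initiator protein DnaA (bound to ATP) separates the duplex, the
fluorescently labelled oligonucleotide diffuses out of the evanescent
field and its spot disappears irreversibly. The quantity of interest
is the per-condition fraction of spots that disappear during a 10-min
time-lapse (121 frames at 5-s intervals).

`spotdrop` implements the analysis chain for such movies: lateral
drift correction, spot detection on a reference image, per-spot
background-corrected intensity traces normalized to initial intensity,
and a run-length drop rule — a spot is called a drop when its
normalized intensity falls strictly below 0.75 for 5 sequential
frames. "Strictly below" means a plateau at exactly 0.75 never
triggers, and a later recovery does not rescind a call: the rule is a
trigger, not a state classifier. Frames invalidated by drift fill are
treated as not-below-threshold so border artefacts cannot create calls.

Photobleaching produces a per-spot signature indistinguishable from
strand separation; the assay handles this with no-protein and
DnaA·ADP control conditions rather than per-spot classification, and
the package mirrors that: the evaluator counts both truth event types
as "should be called" and reports the photobleach-attributable share
separately.

## Synthetic movie generator

Because raw movies for this assay are not generally available, every
stage is validated against a forward model with per-spot ground truth:

- **Geometry.** Spots are immobile, placed uniformly at random on
  integer pixel centres with a hard minimum spacing (default 15.2 µm,
  the mean scaffold spacing of the assay; 0.16 µm/px is the assumed
  pixel scale of a 100× TIRF system, configurable since instruments
  vary) and a border margin that keeps the measurement annulus inside
  the field. Placement is bounded rejection sampling; infeasible
  requests raise an explicit error.
- **Events.** Each spot independently drops with probability
  `drop_probability`. Conditional on dropping, the event time is the
  protein-arrival onset (default 30 s — the first frames are acquired
  before protein is flowed in) plus an exponential waiting time
  (default scale 120 s) truncated to the remaining window. The scale
  is a modelling choice: only end-point counts are reported for the
  real assay, and the memoryless law is the simplest that yields
  callable steps spread over the acquisition. Photobleaching is an
  independent competing exponential (default rate 0: the main dye is
  photostable under oxygen scavenging); the earlier process wins.
- **Rendering.** Each frame is a constant photon background plus one
  integrated-amplitude 2-D Gaussian per live spot (σ = 1.3 px);
  after its event a spot retains `residual_fraction` (default 0 — the
  labelled strand leaves entirely) or 0 (photobleach). Amplitudes are
  gamma-distributed (CV 0.1). Cumulative drift (linear + random walk)
  translates all spots. Pixels are Poisson-sampled, scaled by camera
  gain and given Gaussian read noise — a Gaussian approximation of
  EMCCD excess noise; the full EM-register gamma cascade is omitted
  deliberately because the drop caller operates on normalized traces
  where the extra variance is immaterial. Defaults (2000
  photons/frame/spot over background 100/px) give a peak SNR near 10,
  defined as peak signal over shot noise at the peak.
- **Presets.** Registered condition presets carry the study's
  end-point counts (e.g. ATP 255/330, ADP 48/413, no protein 44/340,
  scrambled boxes 61/609, scrambled trios 82/706, R264A 24/353,
  I190A 23/309, domain III–IV 209/387, double-label 194/235 and
  170/413), so `drop_probability = drops/total` and `n_spots = total`.
- **Determinism.** One master seed is split into child streams for
  positions, schedule and rendering noise; a fixed seed fixes movie
  and truth bit-for-bit.

What the generator does *not* emulate: microfluidic injection
transients, flow-induced spot displacement, non-uniform (TIRF-field)
illumination, fluorophore blinking, sample tilt, or two-colour
acquisition. Passing tests therefore demonstrate the correctness of
the analysis chain under the stated forward model, not robustness to
every artefact of real acquisitions.

## Numerical and design choices

- **Drift.** Estimated by phase cross-correlation with subpixel
  upsampling (default 20, i.e. 0.05-px granularity) in classic
  amplitude-weighted mode: spectral whitening is counterproductive on
  sparse-spot images whose high spatial frequencies carry no signal.
  Default registration is every frame against frame 0 (spots are
  immobilized and total drift is small); a sequential mode accumulates
  frame-to-frame shifts for longer excursions. Correction uses linear
  interpolation; filled border pixels take the frame median and are
  flagged in a validity mask.
- **Detection.** Runs once on the mean of the first 5 corrected frames
  and ROIs are held fixed (no tracking — the assay only loses signal).
  Threshold: median + k·1.4826·MAD with k = 5 by default. Minimum
  distance is enforced greedily, brighter spot first, ties broken by
  lower (y, x). ROI radius defaults to ceil(2σ) = 3 px with a 2-px
  annulus starting 2 px beyond; neither the original ROI size nor the
  prominence was published, so these are declared artifact defaults.
- **Traces.** Raw value = ROI pixel sum − annulus median × ROI area,
  with the background re-measured per frame to absorb slow
  illumination drift. Initial intensity = mean of the first 5 raw
  values (25 s, robust to single-frame noise yet preceding events).
  Traces whose initial intensity is ≤ 3 initial-window SDs above zero
  are excluded as non-spots and counted separately.
- **Summaries.** Drop fractions carry Wilson 95% intervals; replicate
  labels produce per-replicate fractions with mean ± SD (ddof = 1).
  Reported fractions are raw; a control-subtracted difference is
  available but never the default.
- **Plate kinetics.** Background subtraction is per-timepoint (each
  experimental replicate minus the mean of background replicates),
  exact for any shared additive baseline. The "initial rate" is the
  least-squares slope over the first 600 s after protein addition with
  the pre-protein first point excluded — a convention of this package,
  since the source assay reports only qualitative rate comparisons.
  At 1% well noise this slope has a sampling SD around 10–20% of A·k
  on a single triplicate plate (the shared background-mean noise does
  not average away across replicates), so accuracy claims about the
  estimator are made on its mean across simulated plates. Melt
  temperature is the parabolic-refined extremum of the smoothed
  dF/dT, with a sign mode for quench-release (rising) versus
  dye-loss (falling) chemistries.

## Problem sizes used in validation

End-to-end recovery runs the full pipeline on reduced 256×256 fields
with 6-px minimum spacing so that a whole condition's spot count
(330–413) fits a single field of view; detection fidelity uses 200
spots on 320×320. These sizes keep simulation cheap while preserving
spot density, SNR and the full 121-frame time base.

## Known limitations

- The drop rule cannot separate strand separation from photobleaching
  on a single spot; interpretation requires the control conditions.
- Spots appearing after the reference window are ignored by design.
- Registration is translation-only; rotation or focus drift is out of
  scope.
- The rate estimator is biased low by curvature for k·window ≳ 0.1;
  comparisons across conditions are its intended use.
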