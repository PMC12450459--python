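# Methods

## The measurement problem

A desmosome imaged en face in a dSTORM reconstruction shows two parallel,
line-like plaques — one per cell — mirror-symmetric about the junction
midline.  The distance between the plaques (plaque-to-plaque, PtP) is twice
the distance of the labelled protein domain from the midline.  The package
measures PtP per desmosome from a rendered localization image, summarizes
groups of desmosomes, and inverts a rigid-rod geometric model to estimate
the angle between desmoplakin's long axis and the membrane plane.

## Synthetic data model

The generator emulates the statistical structure the measurement assumes,
not the microscope:

* each plaque is a 1D segment of length `plaque_length` (default 600 nm)
  with emitters placed uniformly along it and displaced transversely by
  N(0, `plaque_thickness`²) (default 15 nm);
* the two segments are offset ±separation/2 along the junction normal
  (exact mirror symmetry), with the in-plane orientation drawn uniformly
  in [0°, 180°) unless fixed;
* each localization is the emitter position plus isotropic
  N(0, `localization_precision`²) noise (default 15 nm, a typical
  Alexa-647 dSTORM value);
* background localizations are uniform over a 2×2 µm field with a Poisson
  count at `background_density` (default 2 µm⁻²);
* emitter photophysics (blinking, repeat localizations) is collapsed into
  one `localizations_per_plaque` count (default 200): the pipeline measures
  geometry, not stoichiometry.

Defaults were chosen once, as plausible mid-range values for keratinocyte
desmosomes and dSTORM imaging.  The 600 nm plaque length sits in the range
seen for mature desmosomes (a few hundred nm up to ~1 µm); it also matters
methodologically, because the orientation step requires the junction long
axis to dominate the intensity second moments — with tail-labelled plaques
separated by ~200 nm, junctions much shorter than ~500 nm become nearly
isotropic and fail the anisotropy gate by design rather than measuring
badly.

What the generator does **not** emulate: raw camera frames and PSF fitting,
drift, z-structure, labelling gaps, plaque curvature, or inter-desmosome
heterogeneity in size and brightness.  Passing recovery tests therefore
show the measurement chain is correct and essentially unbiased under the
model's assumptions, not that real micrographs carry no additional
systematics.

Rendering: `histogram` mode increments the containing 4 nm pixel;
`gaussian` mode stamps a unit-integral kernel of width equal to each
localization's precision.  Either way the image total equals the
localization count up to boundary truncation.

## Measurement pipeline

Per desmosome: excise the ROI → estimate orientation → cross-junction
profile → smooth + normalize → find the two plaque peaks.

* **Orientation** is the principal axis of the intensity-weighted second
  central moments, in [0°, 180°).  A principal-axis standard-deviation
  ratio below `anisotropy_threshold` (default 1.5) raises a qc failure
  (`ambiguous_orientation`) — the junction direction would be guesswork.
* **Profile**: the sub-image is rotated so the long axis is horizontal
  (bilinear interpolation) and each row is averaged over the columns that
  originate from real pixels (a rotated mask keeps zero padding out of the
  average).  Rows backed by fewer than `min_profile_columns` (default 10)
  columns are dropped; too few remaining rows → `profile_error`.  Positions
  are signed nm offsets from the profile's intensity centroid, which on a
  mirror-symmetric junction is the midline.
* **Smoothing + normalization**: Gaussian smoothing of FWHM `smooth_fwhm`
  (default 12 nm = 3 pixels) followed by min-max normalization to [0, 1].
  Constant profiles are rejected rather than normalized.
* **Peaks**: local maxima with prominence ≥ `min_prominence` (default 0.2
  of the normalized range); the two most prominent are kept and each is
  refined by a parabola through the three samples around its maximum.
  Failure modes: fewer than two candidates (`too_few_peaks`), the best two
  closer than `min_separation` (default 40 nm, `peaks_merged`), or an
  exact prominence tie straddling the selection cut (`ambiguous_peaks`,
  never silently resolved).  PtP is the distance between the refined peaks;
  half-PtP is reported as PtP/2 exactly, relying on mirror symmetry rather
  than an independent midline estimate.

Group summaries report n, mean and sample s.d. (n−1) over qc-passing
desmosomes only, with per-desmosome values retained.  Averaged two-channel
line scans max-normalize each scan per channel, resample onto a common
grid, and report the per-position mean with a Student-t 95% confidence
interval.

### Known estimator bias

With 15 nm precision and 15 nm plaque thickness the transverse profile of
each plaque is ≈21 nm wide (1 s.d.).  At the smallest measured separation
(70 nm) the two peaks overlap slightly; the continuous two-Gaussian maximum
sits ≈0.3 nm inside each true plaque line, and Poisson noise on the profile
adds a further inward pull of ~1 nm at 200 localizations per plaque (the
inner flank is brighter, hence noisier, and noisy apex samples are selected
preferentially there).  The net effect, ≈−1.5 nm (≈2%) at 70 nm and well
under 1 nm at ≥118 nm, is intrinsic to peak-picking on smoothed line scans;
it shrinks toward the pure overlap term as counts grow.  Recovery
experiments in the test suite bound it against the simulation ground truth.

## Aligned-angle model

Desmoplakin is treated as a rigid head–rod–tail rod of length
L = rod_aa · r + head + tail with head = tail = 16 nm and rise per rod
residue r = 130/888 nm — anchored so that DPI (888-aa rod) has a 130 nm rod
and 162 nm total length, the rotary-shadowing EM dimensions.  This gives
L = 162.0, 97.6 and 74.5 nm for DPI, DPIa and DPII (reported rounded values
are 162, 97 and 75 nm; no single rounding rule reproduces both of the last
two, so full-precision values are used internally and rounding happens only
at report time).

With the head anchored at its measured half-PtP and the rod at angle θ to
the membrane plane, the tail sits L·sin θ farther from the midline:

    θ = arcsin(((PtP_tail − PtP_head)/2) / L)

Infeasible inputs (tail closer than head, or offset exceeding L) raise
geometry errors instead of clamping.  Uncertainty is propagated to first
order from the two group s.d. values,
sd_θ = √((sd_tail/2)² + (sd_head/2)²) / (L·cos θ), and cross-checked
against Monte-Carlo resampling (they agree within 5% at the observed
operating points; the delta method is the reported value).  Note the
first-order propagation gives 5.5°, 7.3° and 8.4° for the three isoforms —
close to, but slightly below, a direct Monte-Carlo of the same inputs and
any higher-order treatment; both numbers are available from the API.

The model deliberately excludes rod flexibility, accordion or bent-rod
geometries: it is the simplest arrangement consistent with a variable tail
position and a conserved head position.

## Statistics battery

Selection logic at preliminary α = 0.05 (configurable, always logged):
two groups → Shapiro–Wilk then unpaired two-tailed Student t-test; three or
more → Shapiro–Wilk per group, Brown–Forsythe (median-centred Levene);
homogeneous variances → one-way ANOVA + Tukey HSD; heterogeneous → Welch
ANOVA + Dunnett T3.  Shapiro–Wilk, Levene, ANOVA and Tukey come from scipy,
Welch ANOVA from pingouin; Dunnett's T3 is implemented here (pairwise Welch
t statistics with Satterthwaite degrees of freedom, referred to a
studentized-maximum-modulus null approximated by the Šidák form
1 − (2·F_t(|t|; ν) − 1)^k).  The approximation is mildly conservative
relative to exact SMM quantiles at small k.  Every preliminary outcome and
the branch taken are recorded in the report's decision trail, making the
procedure a pure function of the data.

Under the null (three normal groups, one distribution) the selected
omnibus rejects at the nominal 5% within binomial tolerance over 1000
simulations — the decision tree does not distort the type-I error
materially.

## Numerical and design choices

* Coordinates: nm, origin top-left, y down, matching array indexing; pixel
  size defaults to 4 nm everywhere.
* ROI excision snaps to pixel boundaries and keeps the absolute origin so
  positions remain traceable.
* Sub-pixel refinement falls back to the sample position when the local
  parabola is not concave; peaks at profile ends are not refined.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-desmosome sub-seeds are drawn from a
  seeded stream keyed by (seed, group label CRC32) so runs are reproducible
  across processes.
* Problem sizes in the bundled demo and recovery experiments (12 desmosomes
  per group in the demo; 50 per condition, 200 localizations per plaque in
  the recovery experiment) were chosen as the smallest sizes at which group
  means are meaningfully constrained; all are parameters.

## Limitations

* The pipeline assumes one junction per ROI, roughly centred; it does not
  detect or segment desmosomes.
* Orientation estimation requires an elongated junction; short or highly
  curved desmosomes fail qc by design.
* The aligned-angle model is an inference about mean geometry from group
  means; it does not constrain per-molecule conformation.
* The Dunnett T3 p-value uses a Šidák approximation to the studentized
  maximum modulus, not exact quantiles.
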