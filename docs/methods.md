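# Methods

`srcconn` implements a source-localized resting-state EEG analysis chain for
three-group (control / tinnitus / chronic pain) studies, together with a
synthetic-cohort generator that plants a known effect structure so that every
stage can be validated by parameter recovery.  This note records the models,
the defaults and the reasoning behind the open design choices.

## Preprocessing and cross-spectra

Recordings are 19-channel 10-20 scalp EEG in microvolts.  The offline chain
is: common-average reference, zero-phase Butterworth bandpass 2-44 Hz
(16th order, forward-backward — steep because the analysis band ends at
44 Hz while mains interference sits at 50 Hz), polyphase resampling to
128 Hz.  The canonical bands are half-open intervals: delta [2, 3.5), theta
[4, 7.5), alpha [8, 12), beta [13, 30), gamma [30.5, 44) Hz; half-open
intervals prevent double counting of shared Fourier bins.

Cross-spectra use non-overlapping 4-s Hann-tapered epochs (0.25 Hz
resolution, so the theta band spans 14 bins — the 4-s default is the
shortest epoch giving multiple theta bins).  Per-band matrices are the
arithmetic mean of the per-bin cross-spectral densities over epochs and
bins.  Per-epoch Fourier coefficients are retained so that the
phase-synchronization variant (unit-modulus coefficients) and
epoch-shuffling surrogates need no second pass over the data.  Artifact
rejection is an amplitude threshold (default +/-100 uV per epoch), an
automatable stand-in for visual review.

## Forward model and solution space

The head is a three-shell concentric-spheres conductor: brain 80 mm, outer
skull 85 mm, scalp 92 mm, conductivities 1 : 1/80 : 1.  The scalp potential
of a current dipole is assembled from the multipole expansion of the primary
dipole field; the per-harmonic transfer coefficients come from solving the
radial boundary-value problem (continuity of potential and radial current at
both interfaces, zero normal current at the scalp) as a 5x5 linear system
per order, summed to order 100.  Two independent oracles anchor this code:
the series reproduces the closed-form infinite-medium dipole potential
q.(r-r0)/(4 pi sigma |r-r0|^3) to machine precision, and with equal
conductivities the transfer coefficients reduce to the known homogeneous
bounded-sphere values (2n+1)/n.

The solution space is a cubic voxel lattice restricted to a spherical shell
inside the brain compartment (keep-the-N-outermost rule, which makes voxel
counts exact and deterministic).  The paper-scale preset has exactly 6239
voxels at 5 mm pitch (shell roughly 57-72 mm); a coarse 450-voxel preset at
12 mm pitch serves routine analysis and tests, and a 500-voxel preset the
localization suite.  Electrode positions are the standard 10-20 template
positions projected radially onto the model scalp sphere.

Seven single-voxel regions of interest approximate the pregenual anterior
cingulate (midline; left/right not distinguished), bilateral auditory,
somatosensory and parahippocampal cortices.  Their coordinates are *fixture
approximations, not atlas reproductions*: they preserve the anatomical
directions but sit in the outer shell with >= 50 degrees of mutual angular
separation, because measured cross-talk of the 19-channel inverse makes
deeper or closer sources unresolvable (cross-talk coefficients approach 1
for a parahippocampal voxel at its anatomically realistic depth).  The
coordinates are config constants and can be overridden with user-supplied
positions.

## sLORETA inverse

With average-referenced lead field `L` and centering matrix `H`, the
minimum-norm inverse is `T = L' (L L' + alpha H)^+`; the resolution matrix
is `S = T L`, and the standardized power of voxel l for measurement phi is
`j_l' [S]_ll^{-1} j_l` with `j = T phi`.  This standardization localizes
noise-free point sources exactly (verified exhaustively on every grid
preset), which is the property that makes the operator testable.  The
default regularization is alpha = 1e-2 times the mean eigenvalue of L L'
(an SNR-agnostic default; alpha = 0 with a pseudoinverse is the
exact-localization regime used in tests).

ROI features follow the relative-power convention: per band, voxel power
(squared current magnitude over the three orientations, band-filtered with
the same zero-phase filters as preprocessing) is normalised across the grid
to sum to one at every time step, averaged over time, and natural-log
transformed.  Each ROI value is therefore the log fraction of whole-grid
power at one voxel — invariant under global amplitude scaling.  Because the
band filter is linear, it commutes with `T`; the implementation filters the
19 scalp channels per band and projects afterwards, which is algebraically
identical to filtering every voxel series and two orders of magnitude
cheaper (the equality is asserted in the tests).

## Lagged phase coherence

Complex coherency c = S_xy / sqrt(S_xx S_yy) is computed from band-averaged
cross-spectra (convention S_xy = E[X conj(Y)]: positive phase means the
first channel leads).  The lagged component

    LC = Im(c)^2 / (1 - Re(c)^2)

discards the instantaneous part of the dependence, which is exactly the
part volume conduction can produce; it is zero for purely real coherency
and bounded in [0, 1).  Both the coherence form (raw coefficients) and the
phase-synchronization form (unit-modulus coefficients, the default) are
available.  Band values are computed on band-averaged cross-spectra, not as
means of per-bin values.

Significance defaults to epoch-pairing surrogates (the epochs of one
channel are re-paired at random, destroying cross-channel phase relations
while preserving each channel's spectrum; 500 shuffles).  A chi-square
asymptotic approximation (2 m LC ~ chi2(1), m = epochs x bins) is available
but is conservative when a strong instantaneous component is present, which
is why the surrogate route is the default at desk scale.  Calibration and
the defining contrast (instantaneous mixtures of one source: ordinary
coherence^2 > 0.5, lagged coherence non-significant in >= 90 % of runs) are
asserted in the acceptance suite.

## Granger causality

Directed coupling is the log-ratio of reduced (own past only) to full (own
plus other's past) autoregressive residual variances.  MVAR models are fit
by least squares on demeaned segments with boundary samples excluded from
the design; `order="auto"` minimises BIC over p in [2, 20].  The
least-squares fit is cross-checked against an independent VAR
implementation in the tests.  Band-restricted values use the Geweke
spectral decomposition of the bivariate model averaged over the band's
frequencies — not band-pass filtering before fitting, which is known to
distort causality estimates.  Negative estimates (possible at finite
samples) are floored at zero and flagged.  The canonical roster has 22
directed links: pgACC to/from the six sensory and parahippocampal ROIs
(12), within-hemisphere auditory/somatosensory to/from parahippocampus (8),
and the interhemispheric parahippocampal pair (2).

The pipeline's effective-connectivity stage runs on theta-band first
principal components of the ROI currents with a fixed order p = 5: the
planted interaction lag (3 samples) lies well inside p = 5, and a fixed
small order keeps the 22-link x cohort fit affordable; `fit_mvar` retains
automatic order selection for standalone use.  A conditional (all-ROI)
time-domain variant is available behind a flag.

## Theta-gamma phase-amplitude coupling

For each ROI the three orientation series are band-filtered (theta, gamma)
and reduced to their first principal component (sign convention: positive
correlation with the largest-variance raw component).  The Hilbert
transform yields the theta phase (zero at the theta peak) and the gamma
envelope; one second is trimmed at each end against analytic-signal edge
artifacts.  Coupling is the normalized mean vector length

    MVL = | mean a(t) exp(i theta(t)) | / mean a(t),

chosen over the modulation-index alternative (provided behind a flag)
because the planted envelope model a = (1 + m cos theta) has the closed-form
expectation MVL = m/2, giving the estimator an analytic oracle.  With a
flat envelope the MVL does not vanish exactly: its sampling noise scales as
one over the square root of the number of theta cycles (~0.02 at 5 min),
which bounds what "no coupling" can mean at finite duration.  Significance
uses circular time-shifts of the envelope (>= 200 shifts of at least 1 s),
z-scored against the surrogate distribution; the null rejection rate at
|z| > 1.96 is calibrated to [0.03, 0.08] in the acceptance suite.

## Group inference

Three routes mirror the whole-brain and ROI analyses:

* **Permutation max-statistic.**  Voxelwise one-way F (stored as ln F)
  between groups; group labels permuted (default 5000 permutations in the
  API, 1000 in the desk-scale pipeline default, 500 in the calibration
  suite), the maximum statistic across *all* features and bands per
  permutation forming the null; corrected p = (1 + #{max >= observed}) /
  (n_perm + 1).  Familywise error is verified against the binomial interval
  under a global null.
* **Conjunction.**  Patient-minus-control contrasts are converted to signed
  Z via the permutation null of the per-feature mean difference; the
  conjunction statistic is the elementwise minimum of the two Z maps,
  thresholded at 1.96 (both contrasts must be active — the
  minimum-statistic conjunction).
* **MANOVA step-down.**  Declarative nested families (e.g. the 12 pgACC
  links, then per-pair 2-link subfamilies).  The multivariate test is
  Pillai's trace (robust to covariance heterogeneity; Wilks' lambda behind
  a flag) with its standard F approximation; a significant family gates its
  subfamilies; the univariate one-way ANOVAs of all leaf features reached
  under one top-level family are Holm-Bonferroni corrected together; where
  the corrected test survives, all three pairwise two-group contrasts are
  reported with eta^2 = SS_between / SS_total.  Families larger than the
  smallest group are refused (the pipeline records, rather than silently
  drops, such families).

### The loop report and volume conduction

Instantaneous leakage of the 19-channel inverse mixes the ROI series, and
pairwise Granger causality on mixtures inflates *both* directions of a
coupled pair — in particular the direction that carries no planted
interaction.  Comparing each direction against controls therefore
overstates reverse links, and no estimator variant tested (bivariate or
conditional, theta-filtered or broadband spectral) removes this at
19-channel resolution.  Since the inflation is common to both patient
groups in expectation, the pipeline reports directionality through the
between-group contrast of the within-pair asymmetry

    Delta_X = GC(PHC -> X) - GC(X -> PHC),   X in {AUD, SOM},

pooled over hemispheres.  Because the hypothesised pattern is a double
dissociation (each patient group unidirectional toward its non-dominant
modality), the omnibus test is the group x modality interaction on these
asymmetries — a two-sample comparison of D = Delta_SOM - Delta_AUD between
tinnitus and pain.  A significant interaction selects one of the two
mirrored configurations, and both modality assignments follow from its
sign (the per-modality contrasts are reported alongside as detail; letting
each modality's assignment float independently can contradict the omnibus
at small n).
Per-direction elevation flags against controls are still reported honestly
(including leakage-elevated reverse links), with this caveat documented
here.

## Synthetic cohorts

Each subject has seven band-limited sources at the ROI voxels.  Narrowband
components are white noise zero-phase filtered into each band (not pure
tones, so AR and coherence estimators face realistic spectra) with
per-band amplitudes: delta 0.5, theta 1.0, alpha 1.5 (the resting
eyes-closed dominant rhythm), beta 0.5, gamma 0.5 (arbitrary units).
Directed theta edges add a lagged linear influence (strength 0.7, lag 3
samples at 128 Hz ~ 23 ms) solved recursively; stability is checked via
the companion-matrix spectral radius and coupled components are
renormalised to unit variance (Granger causality is scale-invariant, so
renormalisation leaves the planted directionality intact).  Gamma is
nested on the ROI's own theta phase with envelope
(1 + m cos theta)/sqrt(1 + m^2/2).

Templates: control — no edges, nesting depth m = 0.1 everywhere.  Both
patient groups raise pgACC theta amplitude x1.8, sensory gamma amplitude
x2.5, and nesting depth to m = 0.5 at the sensory and parahippocampal
ROIs.  Tinnitus plants PHC<->AUD in both directions plus PHC->SOM;
pain the mirror image.  Forty additional background sources at random
non-ROI voxels carry the baseline spectrum at half the ROI sources' total
power: they emulate distributed resting activity, and without them the
whole-grid relative-power normalisation is dominated by the seven ROI
sources, which caps how much a planted elevation at four sensory ROIs can
move the *relative* gamma power (the denominator rises almost as fast as
the numerator).  Inter-subject variability is log-normal
multiplicative jitter (CV 20 %) on amplitudes, coupling strengths and
nesting depths; a jittered subject's edge strengths are rescaled jointly
whenever the draw would push the companion spectral radius to 0.95 or
above, so every simulated system stays stationary.  Per-subject seeds
derive deterministically from the master seed.  Scalp data are the lead-field projection of the sources
(instantaneous volume conduction), rescaled to 20 uV RMS, plus independent
Gaussian sensor noise (SD 2 uV); a plain mixing matrix can stand in for
the lead field in fast unit tests.

Defaults are calibrated for detectability at n = 25 per group — the
desk-scale cohort used by the recovery suite — since the source study
reports no effect-size-calibrated generative parameters; the amplitude
factors give standardized group differences around d ~ 1 for the relative
power features after volume conduction, deliberately larger than the small
effects (eta^2 ~ 0.05) of the real cohort.  What the generator does *not*
emulate: non-stationarity (drowsiness, arousal drift), ocular/muscle
artifacts, inter-subject head-geometry variation, realistic cortical
geometry, and 1/f broadband structure beyond the five-band mixture.  Passing recovery tests therefore show
that the estimators recover the planted structure through volume
conduction and sensor noise at realistic SNR — not that effects of this
size exist in real patients.

## Problem sizes and numerics

The validation suite runs at desk scale by design: the recovery cohort is
n = 25 per group, 5 min per subject at 128 Hz on the 450-voxel grid with
1000 permutations; calibration suites use 100-200 replicates and 200-500
surrogates/permutations.  Numerical choices worth knowing: half-open band
intervals; pseudoinverses (not plain inverses) wherever average-referencing
makes systems singular; GC values floored at zero with a flag; the
degenerate lagged-coherence case |Re c| = 1 defined as 0 with a warning;
the EDF writer scales by the header-truncated physical range so round-trips
are exact to 16-bit quantization; all randomness flows through explicit
integer seeds and `numpy.random.default_rng`.

## Known limitations

Spherical geometry and template electrode positions, not individual
anatomy; single-voxel ROIs at approximated positions; pairwise GC on
inverse solutions carries the volume-conduction confound described above;
the asymptotic lagged-coherence threshold is approximate at small epoch
counts (the surrogate route is the default); no covariate adjustment or
artifact subspace removal.
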