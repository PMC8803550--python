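# Methods

This note documents the models behind `opmtools`: what each suppression
stage assumes, what the simulator emulates and deliberately does not, the
numerical choices that matter, and the limits of what the validation
suite shows.

## The interference problem

A wearable magnetometer array measures brain fields of order 100 fT on
top of (i) a quasi-uniform remnant field drift inside the shielded room,
(ii) artifacts generated by the rigid head+array moving through the
static remnant field and its spatial gradient — very large and
concentrated below a few hertz, (iii) narrow-band interferers (mains at
50/100 Hz, camera LEDs, sources of unknown origin), (iv) physiological
fields (blinks, heartbeat), and (v) ~15 fT/√Hz white sensor noise. Every
stage in the package targets one of these by exploiting either its
temporal structure (filters, spectral interpolation), a measurable
covariate (motion pose, reference channels), or its spatial structure
(HFC, SSP, ICA, beamforming).

## Stage models and assumptions

**Windowed nuisance regression.** Each scalp channel is fitted by OLS
onto an intercept plus the regressors (6-DOF pose, or band-split
reference channels), independently in overlapping windows, and the fit
is subtracted; window residuals are blended with a raised-cosine
cross-fade so the output is continuous. The windowing is the point: the
coupling between pose and field is only locally linear (rotations enter
through trigonometric factors; the remnant field map is not globally
linear), and reference coupling drifts. Defaults: 10 s windows for
motion, 100 s for gradiometry, 50 % overlap. Regressors are demeaned per
window and standardised internally before the least-squares solve —
tesla-scale regressors next to a unit intercept column otherwise fall
below the rank-revealing cutoff of the solver. The fitted coefficients
define a linear operator; `RegressionReport.apply` re-applies it to any
other matrix, which is how ground-truth components are pushed through a
fitted regression for exact attenuation accounting.

**Homogeneous field correction.** Models interference as a spatially
constant field vector: the only inputs are the sensitive-axis unit
normals, so calibration of sensor positions is not required. The
projector removes exactly the 3-dimensional uniform-field subspace (rank
deficit 3, which downstream covariance users are told about). It cannot
represent field gradients; those are handled by motion regression and
beamforming. Brain-signal loss depends on how closely a dipolar pattern
resembles a uniform field on the given array: on the default 86-channel
dual-axis whole-head array the simulated auditory pattern loses well
under 1 dB.

**Synthetic gradiometry.** Assumes the references see the same
interference time course as the scalp channels (true for spatially
uniform sources) and none of the brain signal. Reference channels are
split into 2–20 and 20–80 Hz bands before regression because the
low- and high-frequency interference couple differently. Interference
invisible to the references — a scalp-only coupling, or a field
orthogonal to the reference axes — is untouched by construction, and
movement artifacts are untouched because the references do not move
with the head.

**Spectral interpolation.** Full-record DFT; bins within ±0.5 Hz of a
target frequency have their amplitude replaced by the mean amplitude of
the ±1 Hz flanking bands, phase preserved; conjugate symmetry is kept by
operating on the one-sided spectrum. Chosen over a notch because the
interferers' amplitude drifts, and over sine-fitting because no
parametric form is assumed. Phase preservation makes the operation
nearly idempotent; out-of-band content is bit-for-bit untouched.

**Filters.** Bidirectional (zero-phase) Butterworth: 5th-order 2 Hz
high-pass and 6th-order 40 Hz (evoked) or 80 Hz (beta) low-pass,
reflective padding of at least three impulse-response time constants.
Applied only to continuous data; the epoching API comes later in the
pipeline by design. Trigger channels bypass all temporal operations.

**SSP.** `P = I − UUᵀ` with `U` the top principal directions of an
empty-room noise covariance. Valid only while the array's position and
the noise field are the same as during the noise recording — the reason
it is not part of the mobile pipeline.

**ICA.** FastICA (50 components, fixed seed 454 by default) on
high-passed continuous data. The unmixing matrix is estimated on a
3×-decimated view and applied at the full rate; tolerance 1e-3 —
artifact topographies are broadband and coarse, and tighter tolerances
cost minutes for no change in the flagged set. Components are flagged by
(a) low-frequency dominance (power fraction below 5 Hz > 0.6), (b)
absolute correlation > 0.5 with a supplied template (pseudo-ECG/EOG), or
(c) explicit indices, mirroring how components are chosen by eye.
Removal is the linear map `I − A_f W_f`, exposed for truth accounting.

**LCMV beamforming.** Covariance from unaveraged single-trial data in
the 0–0.5 s post-stimulus window (mean of per-trial covariances by
default; concatenation available). Regularisation `λ = 0.1 %` is
implemented as `C + λ·(tr C/n)·I` — the toolbox convention of reading
the percentage against the mean eigenvalue — and doubles as the handling
of projector-induced rank deficits. Bilateral evoked sources are
strongly correlated, which makes a single-source beamformer cancel them;
the dual-source model constrains both locations jointly. In a spherical
conductor each source's lead field is rank 2 (radial moments are
silent), so the constrained system is solved with a pseudo-inverse and
unit gain holds on the non-silent moment subspace. The three orientation
time courses are collapsed by the dominant singular vector of the
trial-averaged 3×time matrix, sign-fixed so the analysis-window peak is
positive.

**Evoked statistics and TFRs.** Per-timepoint one-sample t-test across
baseline-corrected trials; SNR gain of a pipeline is the dB ratio of
peak |t| in the 80–120 ms window after vs before preprocessing.
Time-frequency analysis uses a single sliding 500 ms Hann taper at
1–41 Hz in 2 Hz steps (50 ms step), power averaged over single trials
(so evoked and induced activity both contribute), edges trimmed by
500 ms, and dB conversion against a 1.5 s pre-stimulus baseline.

## The forward model

A current dipole in a homogeneous conducting sphere (radius 9 cm,
sensors 1 cm off the sphere). The closed-form solution has the two
properties the pipelines rely on — volume currents add no radial field,
and radial dipole moments are externally silent — while requiring no
anatomy. Sensors are placed on a Fibonacci lattice over the cap
z > −0.25 ("evenly around the head"; a strict upper hemisphere
under-samples low temporal sources and artificially inflates the overlap
between dipolar and uniform fields). Bilateral "auditory" sources sit at
(±0.054, −0.022, 0.004) m — canonical auditory-cortex coordinates read
as sphere-frame metres, a documented convention, not anatomy — with
moments along the tangential direction closest to superior, the typical
orientation of auditory and sensorimotor sources.

## What the simulator emulates — and what it does not

Emulated: dual-axis/triaxial scalp arrays with off-head dual-axis
reference pairs (axes oriented to span all three field components);
uniform drift `B0(t)` as 1/f-weighted sinusoids below 5 Hz scaled to a
~500 pT peak; movement artifacts from the exact rigid-body transform of
each sensor through a static field `B_c + G·r` (|B_c| ≈ 2 nT, ‖G‖ ≈
1.5 nT/m, traceless symmetric), with the rest-pose value subtracted
because sensors are nulled at rest; narrow-band interferers with slow
amplitude drift, each either a uniform field (reference-visible) or a
random scalp-only coupling (reference-invisible, like the 21/41.5 Hz
lines that gradiometry cannot touch); 15 fT/√Hz white noise; sporadic
0.2–0.5 s biphasic blinks with frontal coupling (~3 pT) and a
quasi-periodic QRS wavelet train with lateral coupling (~2 pT, ±3 %
period jitter); a biphasic M100-like evoked response (Gaussian peak at
100 ms minus a smaller Gaussian trough at 180 ms) scaled to 220 fT peak
sensor field; and a 13–30 Hz band-limited sensorimotor oscillation whose
envelope drops to 0.5 during tapping and rebounds to 1.5 afterwards.

Not emulated: spatially structured brain noise (the background is white,
so beamformer and ICA face an easier separation than on real data);
sensor non-linearities, cross-talk, railing and calibration error; field
gradients above first order; non-rigid motion; and real line-noise
topographies (couplings are random but fixed per seed). Passing tests
therefore demonstrate algorithmic correctness under the stated noise
model — exactness of HFC, selectivity of gradiometry, calibration of the
estimators — not performance on any particular real recording.

Conservation is exact by construction: the emitted recording is computed
as the ordered sum of the stored truth components, so `data − Σ
components` is identically zero bit for bit, and any linear stage can be
attributed component by component.

## Validation problem sizes

The validation suite runs desk-scale sessions: 86-channel evoked
sessions of 45–135 s (80–250 trials instead of the full 570), tapping
sessions of ~155 s (20 trials instead of 100), all at 1000 Hz. Two
sizes are load-bearing and documented as such: the dual-source
virtual-channel correlation is trial-count-limited (≈0.89 at 120 trials,
≈0.94 at 250 across seeds), and gradiometry coefficient noise needs more
than one 100 s window to average out (single-window sessions scatter
28–53 dB of line attenuation; 2–3 windows give ≥31 dB across seeds).
Null-statistic calibration uses 100 trials × 10⁵ channel-time points.

## Numerical choices

* Internal unit is tesla throughout; ASDs are reported in fT/√Hz and
  field changes in pT.
* Head frame: right-handed, origin at the sphere centre, +z through the
  vertex, metres. Euler convention for pose: intrinsic ZYX
  (yaw-pitch-roll), degrees.
* Motion sync uses the first crossing of half the trigger channel's
  maximum; pose is linearly interpolated inside the observed span,
  linearly extrapolated just outside, and clamped to the edge pose
  beyond 0.5 s.
* Welch: Hann taper, 50 % overlap, one-sided, 10 s windows.
* Raised-cosine blend weights carry a 1e-6 floor so window edges never
  divide by zero.
* Rank decisions use relative eigenvalue thresholds of 1e-10.
* Degenerate inputs fail loudly: empty channel selections, rank-deficient
  orientation matrices, all-zero regressor matrices, sources at the
  sphere centre, windows longer than the record. A perfectly still
  session passes through motion regression unchanged rather than
  erroring on its all-zero regressors.

## Known limitations

* The sphere forward model ignores anatomy; source positions are
  conventions. Localisation accuracy claims cannot be made, only filter
  algebra.
* HFC removes uniform fields only; first-order gradient interference
  survives it (by design — that is what motion regression and
  beamforming are for).
* FastICA may emit a convergence warning at the default tolerance; the
  flagged component set is stable well before formal convergence, but
  the exact component ordering is seed-dependent as with any ICA.
* The acceptance metrics quantify suppression against simulator ground
  truth. On real recordings the equivalent numbers depend on the site's
  interference mix and can only be bounded, not predicted, from these.
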