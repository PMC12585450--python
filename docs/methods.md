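# Methods

`coordgait` quantifies intersegmental coordination of the lower limb during
high-speed running from sagittal-plane joint-angle time series and a
synchronized vertical ground reaction force (GRF) channel. This note records
the models, conventions and numerical choices the package implements, and
what its synthetic-data tests do and do not demonstrate.

## Coupling angles (modified vector coding)

For a joint pair (proximal = hip or knee, distal = ankle) the trajectories
are drawn in an angle-angle plane with the ankle on the X axis and the
proximal joint on Y. The coupling angle at step *t* of a 101-point
normalized cycle is the orientation of the vector joining consecutive
points, relative to the right horizontal:

  θ(t) = atan2(Δθ_prox(t), Δθ_dist(t)) mod 360°,  Δθ(t) = θ(t+1) − θ(t).

The single-argument arctan-of-ratio form sometimes printed for this
quantity cannot distinguish opposite quadrants; since coordination patterns
are defined over the full circle, the quadrant-preserving two-argument
arctangent is the only self-consistent reading, and is what the package
computes. Steps where neither joint moves (Δθ_prox = Δθ_dist = 0) have no
defined direction; they are marked missing and excluded from all circular
statistics rather than being imputed.

Pattern classes tile the circle in eight 45° sectors repeating every 180°:
in-phase proximal dominancy (0–45°, 180–225°), in-phase distal (ankle)
dominancy (45–90°, 225–270°), anti-phase distal dominancy (90–135°,
270–315°), anti-phase proximal dominancy (135–180°, 315–360°). Sector
membership is left-closed/right-open (45.0° classifies as in-phase distal);
the choice only matters on a measure-zero set. The labelling follows the
convention of the vector-coding literature for this axis assignment even
though a vector near 0° geometrically points along the distal axis; the
classes are internally consistent and are what the field reports.

## Circular statistics

Coupling angles are directional, so averages use the complex mean
z = (1/n) Σ exp(iθ_k): the mean direction is arg(z) and the mean resultant
length R = |z| ∈ [0, 1]. Coordination variability is the circular standard
deviation

  var_coord = sqrt(−2 ln R) · 180/π  (degrees).

When R = 0 (antipodal cancellation, e.g. {0°, 180°}) the mean direction is
undefined: the package returns NaN for the mean and +inf for the SD rather
than an arbitrary number. R below 1e−12 is treated as zero.

Two aggregation pathways are deliberately separate, since they answer
different questions:

- **Subphase coordination angle** — coupling angles are computed from the
  across-stride ensemble-mean joint trajectories, then circularly averaged
  over the steps of each subphase. This characterizes the average pattern.
- **Coordination variability** — coupling angles are computed per stride;
  at each cycle step the circular SD across strides is taken, and the
  subphase value is the arithmetic mean of per-step SDs inside the window
  (the dominant convention). The alternative — circular SD of per-stride
  subphase means — is available via `method="stride_means"`; it is always
  smaller because within-stride step noise averages out first.

Pre/post changes of angular outcomes are minimal signed circular
differences in (−180°, 180°]; for all realistic values (well inside one
revolution) this coincides with plain subtraction.

## Preprocessing

- **Gap filling** precedes filtering. Interior runs of missing kinematic
  samples up to 10 frames are filled by quintic-spline interpolation
  (degree-5 B-spline through the observed samples); longer or edge gaps
  raise, because occlusion gaps beyond that length should not be trusted to
  interpolation. Quintic interpolation reproduces degree-5 polynomials
  exactly, which is the oracle used in tests.
- **Filtering** is a third-order low-pass Butterworth applied
  forward–backward (zero phase, so events are not shifted; effective
  attenuation is the squared magnitude response). Cutoffs: 10 Hz for joint
  angles, 50 Hz for the GRF (to preserve sharp force onsets for event
  timing). Reflect-padding is sized at ~10 periods of the cutoff frequency
  so DC and linear trends pass with unit gain to machine precision.
- **Event detection**: stance is where the filtered vertical GRF exceeds
  20 N. Contact is the first sample of each maximal supra-threshold run,
  toe-off the first sample after it. Runs shorter than 50 ms — spikes above
  or dropouts below threshold — are merged into their neighbours (spikes
  removed first, then interior dropouts bridged); real stance phases at
  this running speed are ~5× longer, so the debounce cannot swallow one.
  Runs touching the record boundary are incomplete and discarded.
- **Segmentation**: a cycle runs contact to ipsilateral contact. Contact
  times from the 1000 Hz force grid are snapped to the nearest 120 Hz
  kinematic sample (sub-frame alignment is below kinematic resolution), and
  each channel is cubic-spline resampled onto 101 evenly spaced points
  (0–100% of the cycle). Cycles whose toe-off is not at 40 ± 5% of the
  cycle are flagged but kept: the four analysis subphases are fixed percent
  windows — first half stance 0–20%, second half stance 21–40%, first half
  swing 41–70%, second half swing 71–100% — not per-stride re-anchored
  windows. Coupling step *t* (point *t* to *t*+1) belongs to the window
  containing point *t*.
- At least **8 strides** are required before variability is reported
  (`require_min_strides`); the statistic itself accepts fewer so that
  small worked examples remain computable.

## Group statistics

Each outcome (coordination angle or variability, per pair and subphase)
enters a 2×2 mixed ANOVA: group (sprain history vs control) between
subjects, time (pre vs post) within. The sums-of-squares decomposition is
explicit: the between-effect error term is subjects-within-groups
(df = N − 2); time and interaction share the time×subjects-within-groups
error term (df = N − 2). With two within levels sphericity holds trivially.
Subjects missing either time point are excluded listwise per outcome and
reported, which is what moves the error df (e.g. 22 → 21 for N = 24 with
one exclusion). Unbalanced groups use group-size-weighted cell means,
identical to the standard decomposition when balanced. Angles enter the
ANOVA as linear values — standard practice for these outcomes — and the
pipeline logs a warning whenever a cell's circular mean lies within 20° of
the 0/360° wrap, where that linearization is least trustworthy.

Effect sizes are partial eta-squared, η²ₚ = SS_effect/(SS_effect +
SS_error), labelled small/medium/large at 0.01/0.06/0.14 (below 0.01:
negligible). 95% CIs invert the noncentral-F CDF in the noncentrality λ
(bisection via Brent's method; λ clamped at 0, so the lower bound is 0
whenever the central F already exceeds the α/2 quantile). Two λ→η²ₚ
conversions circulate: λ/(λ + df₂), used by the SPSS-style scripts whose
output this package reproduces, and Smithson's λ/(λ + df₁ + df₂ + 1). The
default is `conversion="error_df"` (the former); they differ in the second
or third decimal at these dfs. Demographic comparisons use the two-sided
pooled-variance t-test; degenerate zero-variance-equal-means input returns
(t, p) = (0, 1) by definition rather than erroring.

## Synthetic data generator

No motion-capture recordings ship with the package; every downstream stage
is validated against generated data with known ground truth.

`generate_trial` emulates the study conditions: a five-second capture with
≥ 8 strides (default 8; tests typically use 10), joint angles at 120 Hz,
GRF at 1000 Hz, stride duration 0.62 s with 2% multiplicative Gaussian
stride-to-stride variation, stance occupying 40% of the stride, GRF peak
2 kN. Joint waveforms are truncated Fourier series (smooth, periodic,
differentiable, parameterizable per joint); their default shapes are
loosely modelled on high-speed running but are not athlete data. The GRF is
a single half-sine stance bump rescaled so it equals 20 N exactly at the
stance boundaries and exceeds it strictly inside — the only property event
detection depends on; its shape is otherwise irrelevant to the pipeline.
The stance fraction default of 0.40 aligns the generator with the 0–40%
stance convention of the analysis windows; true sprint stance is shorter,
but window alignment is what matters for testing. Optional per-stride von
Mises jitter on the harmonic phases (`coupling_noise_kappa`) injects
stride-to-stride coordination noise into full trials; this is a modelling
convenience, not a calibrated noise process.

`generate_coupled_pair` is the precise ground-truth instrument: each cycle
step is a unit step in the angle-angle plane whose direction is drawn from
von Mises(profile(t), κ), so the recovered coupling angles are exactly the
draws, their circular mean converges on the profile, and the across-stride
circular SD converges on the analytic von Mises circular SD
sqrt(−2 ln(I₁(κ)/I₀(κ)))·180/π. κ = ∞ reproduces the profile to floating
point. `simulate_cohort` builds two-group pre/post cohorts from per-cell
profiles plus a persistent per-subject normal offset (default SD 8°, a
moderate between-subject spread) and is the basis of the end-to-end tests.

What passing these tests shows: the pipeline recovers known coordination
structure, its statistics are calibrated (interaction type-I error ≈ 5%),
and prescribed group×time shifts are localized to the right subphase. What
they do not show: behaviour on real marker-derived angles (soft-tissue
artefact, non-stationary waveform shape, correlated multi-joint noise,
treadmill-speed drift are all absent from the generator).

## Numerical and design choices

- All file formats and reports are in degrees; radians appear only inside
  computations.
- Simulation problem sizes in the test and acceptance suites (10–20 strides,
  12 subjects per group, 2000 null simulations, 5 cohort replicates) match
  the study design where one exists and otherwise keep every property a
  many-sigma statement at small cost.
- The directional end-to-end check asserts on means over replicate cohorts:
  a single null draw of η²ₚ at df = (1, 22) has expectation ≈ 0.043 and
  exceeds 0.14 about 7% of the time, so "no effect elsewhere" is only
  meaningful in expectation.
- Determinism: all randomness flows through `numpy.random.Generator` seeded
  explicitly; identical config + seed reproduce trials bit-for-bit, and the
  pipeline writes identical tables on rerun.

## Known limitations

- Joint angles are treated as given; no marker processing or inverse
  kinematics.
- Sagittal plane only; one joint-pair coding scheme (joint-level, not
  segment-level); no continuous relative phase.
- The ANOVA is the classical mixed-model decomposition, not a multilevel
  model; no multiple-testing correction is applied (matching the analysis
  it mirrors).
- Circular outcomes are linearized for the ANOVA; the wrap-proximity
  warning flags, but does not fix, couplings whose group means straddle 0°.
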