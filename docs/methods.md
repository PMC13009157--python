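# Methods

This note documents the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinate and table conventions

Positions are millimetres in a right-handed body frame: x longitudinal
(anterior positive), y lateral (animal's left positive), z vertical (up
positive). Angles are degrees; for the thorax–coxa joint, increasing
rotation, adduction, and flexion correspond to inward rotation, medial
translation, and flexion. Frames are 0-based and intervals over frames
are half-open `[start, end)`. All tables are UTF-8 CSV with one header
row; identifiers are opaque strings. These are interchange conventions of
this package, not claims about any upstream tracker's native layout.

## Connectome analysis

A `SynapseGraph` is a directed multigraph over annotated neurons with
positive-integer synapse counts; duplicate edges are summed on load.
Neuron signs derive from neurotransmitter: acetylcholine +1; GABA and
glutamate −1 (glutamate acts on inhibitory GluCl receptors in the fly
ventral nerve cord); unknown 0.

**Motor impact.** The score is the sum of an input-normalized
monosynaptic weight and a signed di-synaptic weight (README). Choices
that were genuinely open:

- *First factor of the di-synaptic term.* The hair-plate-to-premotor
  count is normalized by the **premotor neuron's total input synapses**,
  mirroring the input normalization used at the motor-module hop. The
  alternative — normalizing by the hair plate's total output — is
  available via `motor_impact(..., presyn_norm="output")`.
- *Denominator of the module terms.* "Total input" counts synapses from
  **every annotated neuron**, including fragments labeled `other`, not
  only fully reconstructed cells.
- *Thresholding.* The ≥ 4-synapses-per-upstream-neuron average rule is
  applied when building two-layer circuit diagrams, but **not** inside
  the impact score; `apply_threshold=True` can impose it.
- Premotor neurons with unknown neurotransmitter contribute 0 to w2 and
  are counted in a diagnostics field, as are premotor neurons with no
  recorded input synapses (paths skipped). Glia are valid postsynaptic
  targets for output fractions but never enter circuits or scores.

Dispersion across the axons of a hair plate uses the sample SD (ddof 1).

## Kinematics

**Velocity.** Tarsus velocity is the central difference of longitudinal
position times the frame rate, convolved with a truncated Gaussian
(± 4σ, reflected edges). σ defaults to 2 frames (~6.7 ms at 300 Hz):
enough to suppress single-frame tracker jitter without blurring a 15 ms
swing. Negative velocity means posterior movement.

**Swing/stance.** Swing iff v > +5 mm/s or v < −25 mm/s, else stance.
Isolated one-frame runs are then flipped in a single left-to-right pass;
because the labels are binary, a flip merges the frame with both
neighbours, so one pass leaves no one-frame runs and the operation is
idempotent. Alternating patterns (s,w,s,w) therefore resolve
left-to-right.

**Steps.** A cycle spans one swing onset to the next and requires a
stance frame immediately before the onset. AEP is the tarsus position at
the first stance frame; PEP is the position at the last stance frame
before the swing — the sub-frame ambiguity (last stance frame vs first
swing frame) is resolved to the stance side and amounts to at most one
frame of tarsus travel. Swing distance is the 3-D path length accumulated
from the PEP frame through the AEP frame (so it can never undercut the
straight PEP→AEP chord); the straight-line displacement is reported
alongside. Retained steps satisfy 5–20 steps/s, 15–75 ms swing, and
< 200 ms stance; each violated bound is counted separately in the
rejection report. Note the bounds are arithmetically coupled: a stance
longer than 200 ms at an in-bounds swing duration necessarily also drops
the cycle below 5 steps/s, so such a step carries both reason counts.

**Behavior.** Tethered-ball: forward walking iff ball forward velocity
> 5 mm/s and |rotational velocity| < 25 deg/s; left turn iff
−50 < rot < −25 deg/s; right turn mirrored. Treadmill: forward walking
iff body forward velocity > 5 mm/s and |heading| < 15 deg. Rest requires
body and all tarsi below 5 mm/s. Front-leg grooming uses a
proximity-plus-velocity rule with package defaults (front tarsi within
0.5 mm of each other / the head region, tarsus speed > 5 mm/s), since
only the form of the rule, not its constants, is standard.

**Swing trajectories.** Each swing is resampled to 100 points by linear
interpolation in time; the longitudinal coordinate is mapped to progress
0→1 between the fly's mean PEP and AEP, and the lateral coordinate is
re-interpolated onto a uniform progress grid (progress is made monotone
by a running maximum before inversion). The grand mean is the unweighted
mean of per-fly means with a 1.96·SEM band across flies.

**Phases.** An other-leg swing onset inside reference cycle
`[t_k, t_{k+1})` gets phase `(t − t_k)/(t_{k+1} − t_k)`; the circular
mean and vector strength are reported. The onset-in-cycle definition is
an explicit convention of this package.

**Posture.** Body height is thorax z above the substrate plane (the mean
resting tarsus z unless given); pitch is the head–abdomen axis angle
against that plane; the stance polygon is the shoelace area over the six
tarsi ordered L1, L2, L3, R3, R2, R1. Frames with an untracked tarsus
are skipped and counted.

## Calcium processing

The GCaMP/tdTomato ratio cancels gain fluctuations shared by both
channels (vertical motion of the nerve cord). The baseline of a trial is
the ⌈0.10·n⌉ smallest ratio values (ties resolved by stable sort order);
z-scoring uses the baseline mean and **sample** SD (ddof 1). A constant
ratio raises a degenerate-baseline error rather than returning
infinities.

Upsampling uses a natural cubic spline from the volume rate (default
8.26 Hz; volume *i* is timestamped at the middle of its acquisition
interval) to the tracking rate (default 300 Hz), followed by a centered
moving average of 0.2 s. The averaging window is rounded to the nearest
**odd** frame count (61 at 300 Hz) and shrinks symmetrically at the
edges, so constants and linear ramps pass through unchanged at every
frame; an even window would shift a ramp by half a frame.

Tuning curves bin activity against angle in 5° bins aligned to multiples
of the bin width; bins with fewer than 10 frames per fly are flagged
empty (NaN), never zero-filled. The pooled 1-D curve is the unweighted
mean of per-fly bin means (pooling frames across flies would weight flies
by recording length); the pooled 2-D map takes the per-bin maximum across
flies, and each fly's argmax bin is reported with ties broken to the
first occupied bin in row-major scan order (rotation outer). Peak-
activity behavior probabilities use a default threshold of z = 2 baseline
SDs; angle densities per behavior use a Gaussian KDE with Scott's-rule
bandwidth, scaled to unit maximum. Masked frames are excluded before any
binning, density, or probability.

## Statistics

- **Mixed model**: value ~ group with a random intercept per fly, fitted
  by REML (statsmodels `MixedLM`). Only fly identity is a random effect —
  no random slopes. Inference on the group effect is Wald, referenced
  against a t distribution with (number of flies − 2) degrees of freedom:
  the contrast is a between-fly effect, and a normal reference is
  anticonservative at 10–20 flies per group (empirically ~6.6% null
  rejection at α = 0.05 versus ~4–5% with the t reference). With a single
  observation per fly the random intercept is unidentifiable and the
  comparison degrades, with a warning, to a Welch t-test on per-fly
  values.
- **t-test**: Welch (unequal variance), two-sided, on per-fly means;
  Bonferroni factor 2 when swing duration and swing distance are both
  tested.
- **Kuiper two-sample**: V = sup(F₁−F₂) + sup(F₂−F₁) over the empirical
  CDFs, evaluated at all sample points. V is invariant under any common
  circular rotation of both samples, which is why it, and not
  Kolmogorov–Smirnov, is used for step phases. The p-value uses the
  asymptotic Kuiper tail series with the Stephens small-sample correction
  at effective size nm/(n+m), truncated when terms fall below 1e−10; a
  permutation option enumerates all splits when their number is ≤ 2·10⁵
  and otherwise uses seeded Monte-Carlo permutations. Bonferroni factor 5
  when five leg pairs are compared. Note that on the line V < 2 strictly:
  two point masses at distinct positions give V = 1 (one-sided maxima of
  1 and 0), and V is nonetheless rotation-invariant.

## Synthetic data

**Connectome.** A `CircuitSpec` lists hair plates (cell counts), premotor
neurons (hemilineage, transmitter, input budget, module outputs), motor
modules (sizes, background input), and direct hair-plate→module counts.
Counts are distributed as evenly as possible across member cells;
background fragments (class `other`) supply the remaining input so every
denominator is controlled. Ground-truth impact is computed from the
target counts by the same two-term formula before realization; realized
counts are Poisson about the targets (or exactly the targets with noise
"none", which makes recovery exact). Everything is a pure function of
(spec, seed).

**Gait.** Tripod coordination ({L1,R2,L3} vs {R1,L2,R3}, phase offset
0.5) at 10 steps/s, 30 ms swing, 300 Hz by default. Within a cycle the
tarsus moves linearly PEP→AEP during swing (with half-sine vertical lift
and an optional Gaussian-profile medial bow for synthesizing a medial
deviation near the swing-to-stance transition) and linearly AEP→PEP
during stance, which keeps stance velocity (~ −17 mm/s) inside the
stance classification band and swing velocity (~ +40 mm/s) well above
threshold. Ground-truth swing labels cover frames onset..onset+n_swing
inclusive of the touch-down frame — exactly what threshold classification
of the central-difference velocity yields on the noiseless trajectory, so
label disagreement measures genuine pipeline error, not a convention
mismatch. The ground-truth step table records both the true extreme
positions (for exactness of injected AEP shifts) and the positions at the
analysis-convention frames (first stance frame, last stance frame before
swing), which differ by one frame of travel. Between-fly variability is a
per-fly offset of all extreme positions (SD 0.02 mm by default);
measurement noise is iid Gaussian on every coordinate, added only after
ground truth is recorded. A cohort-level AEP shift vector emulates a
silenced genotype; its magnitude is a free parameter for power testing,
not an estimate of any real effect size.

**Calcium.** The limit detector is tonic: rate = max_rate ·
σ(k_rot(θ_rot − θ0_rot)) · σ(k_add(θ_add − θ0_add)) with default limits
θ0 = 25° (rotation) and 20° (adduction) and slopes 0.4/deg. The
indicator kernel is a single exponential with τ = 0.5 s (a GCaMP7f-scale
choice; the kernel form is not measured here), applied as a unit-gain
causal filter. Both channels share a multiplicative log-normal AR(1)
motion-artifact gain — precisely the disturbance the ratio step removes —
and per-volume Gaussian photon noise; only GCaMP carries the activity
signal on top of a baseline fluorescence f0. The default angle sweeps are
slow sinusoids with incommensurate periods (peak speed < 20 deg/s, slow
relative to τ so up- and down-sweep hysteresis averages out) whose ranges
top out a few degrees past the limit angles, emulating passive platform
movement that drives the leg to, but not far beyond, its range limit.
Because the tuning surface is monotone, the location of the 2-D activity
maximum is informative about the limit angles only under such
near-limit exploration; trajectories sweeping far past the limit would
park the maximum at the trajectory extreme instead.

**What passing these tests does not show.** The generators use piecewise
-linear gait with exact periodicity, isotropic Gaussian tracking noise,
a separable logistic tuning surface, and a single-exponential indicator.
Real data add tracking outliers and gaps, step-to-step variability in
timing and amplitude, non-separable and possibly hysteretic tuning,
indicator nonlinearity, and behavior-label noise. Recovery results here
bound algorithmic error under the stated conditions; they are not
field-accuracy claims.

## Problem sizes

Default verification runs use 10 flies × 100 steps × 6 legs for gait
recovery, 5 synthetic flies × 60 s for tuning recovery, 50 random graphs
(≤ 30 neurons) plus 200 Kuiper instances for oracle agreement, and 1000
null / 100 power simulations for test calibration — sizes at which every
quantity is stable across seeds while the whole verification completes in
well under a minute each.

## Known limitations

- No ≥ 3-hop pathway scoring, electrical synapses, or activity dynamics:
  the impact score is a static, synapse-count-weighted prediction.
- No pose estimation or ball-tracking: the pipeline starts at 3-D
  keypoints/angles and ROI-mean fluorescence traces.
- The LMM uses Wald t inference with a between-fly df heuristic, not
  Satterthwaite/Kenward–Roger; with very unbalanced designs the df choice
  matters more than it does here.
- The grooming classifier constants are package defaults, not measured
  values, and should be tuned to the rig before use on real data.
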