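# Methods

`slipgait` estimates three-dimensional walking kinetics — per-leg ground
reaction forces (GRF), centre-of-pressure (CoP) trajectories and
lower-limb joint torques — from a single accelerometer worn at the
sacrum. This note documents the models, the synthetic world the package
is validated in, the numerical choices, and what a passing test does and
does not establish.

## The compliant walking model

The mechanical core is a three-dimensional spring-loaded inverted
pendulum (SLIP): a point mass `m` on massless linear springs (stiffness
`k`, rest length `l0`), one per leg, walking with alternating single and
double support and no flight phase. Axes are `x` mediolateral (ML), `y`
anteroposterior (AP), `z` vertical. A stance leg is described in
spherical coordinates with the AP axis as zenith: length `l`, polar
angle `θ` from the AP axis (`θ⊥ = θ − π/2` is the deviation from
vertical in the sagittal plane) and azimuth `φ` of the projected leg in
the `z–x` plane.

The foot is a moving point: the AP CoP progresses under each foot as a
logistic function of time since heel strike,
`y_f(t) = c_f·[σ(rate·(t−a)) − σ(−rate·a)]`, zero at touchdown, with
half-way time `a` and excursion `c_f`; the ML CoP excursion is zero (it
is small compared with the AP progression and the reduced model keeps
only the latter). The spring force is **positive under compression** —
`F = k(l0 − l)·û` with `û` pointing from foot to mass — so a loaded leg
pushes the body up. The equation of motion is
`m·q̈ = Σ F_legs − m·g·ẑ`.

Events: a new leg touches down, at the prescribed angles `(θ_td,
±φ_td)`, when the CoM descends through `l0·sin(θ_td)·cos(φ_td)`; the
trailing leg takes off when its length returns to `l0` while unloading.

### Small-angle affine maps

Linearising the stance geometry about vertical, the augmented state
`r = [l, θ⊥, φ, l·θ⊥, l·φ]` is an affine function of the augmented CoM
input `q_t = [x_m, y_m, z_m, f_sigmoid(t−a)]`; the GRF is affine in
`r`; and the CoP is affine in `(q_t, F)`. Composing the three gives one
affine map from CoM position (plus the CoP clock) to the stacked
five-vector `[F_x, F_y, F_z, x_f, y_f]`. This is the structural reason a
single sacral sensor plus a one-hidden-layer network suffices for
kinetics estimation: in the small-angle regime the target is already a
weighted sum of the inputs. The map constants (`z_hs`, the anchor, the
logistic scale `d = c_f`) are evaluated at the heel-strike
configuration of each stance; the constant logistic tail at `t = 0` is
absorbed into the AP anchor term so that `y_foot = y_hs + d·f_sigmoid`
holds exactly.

Two printing conventions are worth recording: the force map as usually
printed is negative under compression while the CoP map only composes
consistently with the compression-positive sign (we use the latter
throughout, making the composition identity exact), and the CoP map's
`z_hs/(k(z_hs − 1))` constant presumes lengths in units of `l0`; the
implementation carries `z_hs/(k(z_hs − l0))` with explicit units.

### Periodic gaits and the per-speed schedule

Periodic walking is found by shooting on one step with left/right
mirror symmetry: unknowns are the CoM velocity at touchdown, the
trailing-leg anchor and age, and the polar touchdown angle; residuals
are closure of the mirrored step-to-step map plus the average-speed
constraint. `scipy.optimize.least_squares` (LM) solves it with finite
differences stepped above the integrator noise floor.

The model's periodic solutions live on branches. The branch used here —
the "shallow" branch, with double-humped per-leg vertical GRF, peak
vertical force ≈ 1.03 body weight and small vertical touchdown velocity
— was traced by numerical continuation over stiffness, touchdown angle,
CoP excursion and CoP timing. Walking speed turns out to be controlled
mainly by the CoP clock and excursion, not by the touchdown angle; the
branch folds at a minimum dimensionless speed `v/√(g·l0) ≈ 0.246` and a
maximum ≈ 0.64 no matter how the other knobs are moved. The defaults
therefore follow a **dimensionless per-speed schedule** (stiffness
`k·l0/(m·g)` 27→22, CoP excursion `c_f/l0` 0.095→0.35, CoP half-way
time and rate, and a touchdown-angle warm start 107°→112°) anchored at
solutions between 0.69 and 1.78 m/s. Because the SLIP equations are
scale-invariant, a subject's gait is an exact rescaling of the nominal
one; warm starts transfer and the per-subject search converges to the
target speed to ~1e-14 in a few seconds.

Two consequences shape the synthetic world. First, the rest length is
`l0 = 0.85 ×` anatomical leg length (the CoM rides above the hip, so the
effective pendulum is shorter than the leg); with 0.9 the slow end of
the protocol (0.7 m/s) would be unreachable for taller subjects.
Second, sampled leg lengths are kept in [0.77, 0.945] m by resampling
the segment-ratio noise only, so every subject admits periodic gaits at
all four protocol speeds while the height distribution stays unbiased.

Long bouts are synthesised by restarting each step from the converged
fixed point (mirrored and translated), so a bout is periodic by
construction and the open-loop lateral instability of the walker cannot
accumulate; a free-running mode exists and drifts < 1e-6 per stride
from a converged fixed point over five strides.

## The synthetic cohort

The pipeline's reference experiment (17 participants, treadmill, force
plates, motion capture) is not publicly deposited, so evaluation uses a
virtual cohort with the same statistical structure: heights
N(166.7, 7.8) cm and masses N(60.1, 8.9) kg (draws beyond 2.5 SD
resampled), foot length 0.152·height ± 5%, leg length 0.53·height ± 3%.
Default protocol: 8 subjects × {0.7, 1.0, 1.3, 1.6} m/s × 10 stance
phases per trial (both legs contribute; 40 stances per subject, as in
the reference protocol).

### What the IMU model emulates

The sacral accelerometer signal is the CoM acceleration resampled to
148 Hz plus three disturbance layers:

1. **Heel-strike transient** — a biphasic dip-then-peak shock at each
   touchdown (total width 80 ms, amplitude 2.5 m/s² scaled by the
   square of walking speed, capped at 4×). This is the signature the
   20 Hz event-detection channel relies on; a smooth SLIP acceleration
   alone has no local minimum at heel strike. Under the default
   ("shod") disturbance model each step's shock is absorbed with
   probability 0.55 and, when present, arrives with a −30 ms mean lead
   and 45 ms per-step scatter relative to the force-defined heel
   strike — the mechanisms the reference work itself gives for its
   large heel-strike errors. This degrades HS detection (MAE ≈ 20 ms
   on the default cohort) above TO detection (≈ 20 ms, dominated by a
   systematic lag of the AP-acceleration minimum), reproducing the
   reported HS-worse-than-TO ordering, though only narrowly: the
   last-minimum detection rule self-corrects early-scattered shocks in
   this smooth world, so the wide real-data gap (50 vs 13 ms) is not
   reproduced.
2. **Mounting misalignment** — a constant per-trial rotation (pitch SD
   0.04 rad, roll SD 0.01 rad). The sensor measures the rotated
   specific force and the pipeline subtracts nominal gravity, so tilt
   leaks a constant fraction of `g` into the horizontal channels — the
   dominant local-vs-global-frame error. Constant offsets do not move
   filtered extrema and are annihilated by the stride-wise drift
   removal, which is why the pipeline tolerates them.
3. **Sensor/soft-tissue noise** — white, 0.08 m/s² horizontal and
   0.35 m/s² vertical. With the misalignment this calibrates the
   per-axis local-frame NRMSE to ≈ [10.0, 9.5, 3.2]% (ML/AP/vertical)
   against the ≈ [9.5, 8.0, 2.3]% reported for real data.

The sacrum is identified with the CoM; known sacrum-vs-CoM amplitude
and lag discrepancies are not modelled.

### Joint-torque ground truth (a stand-in)

Real inverse dynamics needs marker-based segment kinematics, which the
synthetic world does not have. Instead, each stance leg is a massless
geometric chain — ankle fixed relative to the foot anchor, hip along
the ankle-to-pelvis direction at the anatomical thigh+shank length
scaled by the spring-compression ratio, knee from two-link inverse
kinematics displaced forward — and the seven torque channels are the
GRF moment about each joint projected on the laboratory axes (hip
Ab/Ad, E/F, ER/IR; knee Ab/Ad, F/E, ER/IR; ankle PF/DF). Channels are
linear in the GRF, zero for a force line through the joint, and scale
with body mass; magnitudes come out ≈ 0.3–1.6 N·m/kg, in the
physiological range. This preserves exactly the torque–GRF–CoP
geometry a network must learn, but none of the inertial (segment
acceleration) content of real inverse dynamics — torque accuracies
measured here say nothing about inertial-torque fidelity.

## The processing chain

All series are brought to 100 Hz (polyphase). Filtering is fifth-order
zero-phase Butterworth (forward–backward, doubling the effective
order). Event detection follows the acceleration-signature rules:
mid-stance marks one third of the way between consecutive minima of the
5 Hz AP acceleration; per step window, TO is the AP minimum and HS the
last 20 Hz-vertical local minimum before the window maximum, moved to
the previous minimum until it precedes the TO. Stances pair each HS
with the last TO before the next ipsilateral HS. In this world the TO
estimate lags the true toe-off systematically by ≈ 20–25 ms (the AP
minimum falls just after takeoff); HS is sharp when the shock transient
survives and falls back to the single-support valley when it does not.

Integration is stride-wise (ipsilateral HS to HS): cumulative
trapezoids with linear drift removal at both levels
(`v̂(t) = v(t) − (v(T) − v(0))·t/T`, a projection), constants fixed by
steady-state walking — zero-mean ML/vertical velocity and displacement,
AP mean velocity equal to the walking speed. The walking speed is the
belt speed during training and, at application time, the regression
`v0 = (a1·f + a2·A + a3)·h·g` on stride frequency and mean acceleration
magnitude, always refit on training subjects. The ML side is unified by
the displacement sign at 50% of stance (ties unflipped); output ML
channels are mirrored consistently. Each stance is linearly resampled
to 201 points of `(t, position, velocity, acceleration)`.

## The estimation networks

Two single-hidden-layer networks (10 inputs, 20 tanh hidden units,
linear outputs; 5 outputs for GRF+CoP, 7 for torques). Inputs are
min-max scaled to [0, 1] per channel on the pooled training folds only
(time passes through; out-of-range test values are not clipped);
outputs are divided by body weight (forces), foot length (CoP) and body
mass (torques).

Training is full-batch Levenberg–Marquardt on the MSE: the
Gauss–Newton normal equations are assembled analytically from the layer
structure (no explicit Jacobian; an epoch on ~3·10⁵ residuals costs a
fraction of a second), damping ×10 on failure and ÷10 on success, early
stopping when the validation MSE fails to improve strictly for 20
epochs, returning the best-validation weights. The assembly is verified
against a numeric-Jacobian oracle, a frozen teacher network is
recovered to normalized MSE < 1e-6, and with the hidden layer frozen to
identity the trainer reproduces ordinary least squares.

Evaluation is leave-one-subject-out: per held-out subject, three
validation subjects are drawn by seeded RNG and the rest train; with n
subjects the folds are (n−4)/3/1, preserving the reference 13/3/1
structure at n = 17. Accuracy is NRMSE (RMSE over the measured
amplitude of each stance phase, in percent) and R² about the per-stance
mean, computed per stance and then averaged — never on concatenated
records. The synthetic ML CoP is identically zero, so that channel is
excluded as degenerate rather than reported.

## Numerical choices

- ODE integration: RK45, rtol 1e-10 / atol 1e-12, event localisation
  for touchdown/takeoff/fall; the tight tolerance keeps shooting
  residuals (~1e-14) and free-run drift (<1e-6/stride) well inside the
  acceptance bounds.
- Shooting: LM with `diff_step = 1e-6`; smaller steps sit in the
  integrator noise and stall the search.
- Local minima on discrete series: strict neighbours, plateau
  midpoints, endpoints excluded.
- Early stopping requires strict improvement (ε = 1e-12); LM damping
  capped at 1e10.
- HDF5 containers are written without timestamps, so identical seeds
  give byte-identical files.

## What a green run establishes — and what it does not

The synthetic world shares the pipeline's structural assumptions
(SLIP-consistent CoM kinetics, near-affine kinetics maps, steady-state
strides), so held-out errors here are a *calibration floor*, not a
reproduction of real-data accuracy: on seeded 8-subject cohorts the
held-out NRMSE comes out ≈ 6–9% vertical GRF, 6–7% AP GRF, 14–15% ML
GRF and 9–14% AP CoP — the same ordering as, and close to, the
real-data values (6.7/9.2/15.6/8.2%). Missing from the world: soft-tissue artefact
spectra, sacrum-vs-CoM discrepancies, true inverse-dynamics torques,
footwear/marker variability, and any non-steady walking. The torque
stand-in and the shod transient-dropout rate are documented choices,
not measurements.
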