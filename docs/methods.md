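# Methods

## The model

The package's default fixture is a sagittal-plane biped with ten coordinates:
pelvis translation (x, y) and pitch, trunk pitch, and hip, knee and ankle
flexion per side. Segment masses are standard anthropometric fractions of a
76.2 kg total (head, arms and trunk lumped into one trunk segment); lengths
are representative adult values (thigh 0.45 m, shank 0.43 m). A planar model
at this scale exists to exercise the method end-to-end, not to reproduce any
individual's anthropometry: full 3-D musculoskeletal models are out of scope,
and the model description is config-driven (YAML) so richer planar topologies
can be declared without code changes.

Muscles are Hill-type with rigid tendons by default: the musculotendon force
is `F_max (a · f_L(l̃) · f_V(ṽ) + f_pas(l̃)) cos α`, with the smooth
Gaussian-sum active force-length curve, exponential passive curve, and
log-form force-velocity curve that are standard in gradient-based muscle
simulation. Curves are normalized so `f_L(1) = f_V(0) = 1` exactly, which
gives clean identity points for testing; the raw published coefficients put
these values within 0.2% of 1 anyway. Activation dynamics are first order
with τ_act = 15 ms and τ_deact = 60 ms defaults and a tanh-blended switch
(gain 50) between the two time constants so the right-hand side is smooth.
Muscle paths are constant moment arms per coordinate — the standard planar
reduction — with moment-arm magnitudes (hip flexors ≈ 4 cm, vasti ≈ 4.5 cm,
tibialis anterior ≈ 3.5 cm) and strength parameters taken at representative
adult magnitudes. Muscles outside the stimulation set are omitted entirely,
including their passive properties (they are not contracting, and their
passive contribution is taken as negligible).

The muscle set mirrors an implanted/surface stimulation system: iliopsoas,
vasti (modelled as a two-element group to exercise the synergy cost), and
tibialis anterior bilaterally, plus right sartorius, right biceps femoris
short head, and left tensor fasciae latae. The symmetric six-group subset is
used in the symmetric solve stages; the asymmetric muscles only enter the
final, full-stride stage. At this desk scale the "reduce to iliopsoas,
vasti, tibialis anterior" cascade edit is a no-op, because the symmetric
subset already is that set; the edit is retained in the stage bookkeeping.

Ground contact uses three spheres per foot (heel, metatarsal, toe; radius
2 cm). The normal force is Hunt–Crossley, `k δ^1.5 (1 + 1.5 c δ̇)`, evaluated
on a softplus-smoothed penetration (scale 0.1 mm) and with the dissipation
factor smoothly clamped positive, so the force is C¹ everywhere — the
property gradient-based solvers need. Stiffness defaults to 1e5 N/m^1.5:
deliberately an order softer than a hard Hertzian value, trading ~2 cm of
static penetration for a much better-conditioned nonlinear program at this
problem scale. The force at zero penetration is ≤ 0.1% body weight. Friction
is tanh-regularized Coulomb (transition velocity 0.05 m/s) plus a viscous
term.

Reserve actuators sit on all ten coordinates: pelvis reserves represent
walker support, the trunk-pitch actuator represents volitional trunk and arm
effort (weighted as a normal control), and the limb-joint reserves represent
the user's preserved volitional control of the stance limb while also aiding
solver convergence. All reserves except the trunk actuator carry a ten-fold
effort penalty so the solver shifts work to the muscles.

## Costs, constraints, transcription

The six cost subterms (marker tracking, contact tracking normalized by body
weight, within-group synergy, distance-normalized control effort,
abdominal-channel energy penalty, auxiliary-derivative penalty) are evaluated
by trapezoidal quadrature on the trajectory grid in the analysis/reporting
surface. Inside the transcription the objective uses composite-Simpson
weights on the node/midpoint grid instead: trapezoid is inconsistent with
Hermite–Simpson defects, and the mismatch is exploitable (the measured
double-integrator optimum comes out 10.84 instead of 12 with a trapezoid
objective). With Simpson weights the discrete optimum of the smooth oracle
problems equals the continuous one to machine precision. The two quadratures
agree on constant densities and to O(h²) generally; cost reports may
therefore differ from the solver objective in the last digits.

Weights default to 1.0 per subterm with a reserve penalty of 10× (config).
The composed cost's units are mixed; the weights absorb units.

Half-stride symmetry maps left and right channels by name and exempts the
travel coordinate's position, all reserve/volitional actuator channels, and
any sided muscle without a contralateral twin. Knee-extension-at-double-
stance is imposed inside the transcription as variable bounds (default
tolerance 1°) at the cycle endpoint nodes, which are double-stance onsets by
the cycle definition used here (the cycle runs from double stance to double
stance); the standalone checker instead detects onsets from the contact
forces (trailing-foot normal force crossing 5% body weight). Initial rest,
joint-speed bounds and final-time bounds are also applied as variable
bounds; speed bounds are symmetric — ± the stated percentage of the
reference speed-range magnitude per coordinate, intersected with the
coordinate's physical speed range — so the rest condition always lies
inside them. Leg clearance is the planar (anterior-posterior, lateral) distance
between shank midpoints with fixed lateral offsets (±10 cm) — a sagittal
model cannot cross legs laterally, so in the fixture this constraint is
structurally feasible; its residual generator is fully exercised with
configurable geometry in the unit tests. Default minimum gap: 5 cm.

Transcription is separated Hermite–Simpson: states and controls are decision
variables at mesh nodes and interval midpoints, dynamics enter as Hermite
and Simpson defects, and the final time is a decision variable when bounded
(otherwise pinned). Variables are affinely scaled to O(1) by kind; defect
rows are scaled by fixed per-state physical scales so violation units do not
drift across cascade stages. Derivatives are grouped forward finite
differences (greedy column coloring; step 1e-6 scaled); every color's
perturbation is evaluated in one batched dynamics call. The NLP is solved by
SciPy's `trust-constr` (optimality tolerance 1e-4, feasibility 1e-6 by
default, both config), followed by a damped Gauss–Newton feasibility polish
on the constraint residuals (sparse LSQR on the free variables, step
halving): the trust-region method routinely stops at its iteration budget
with residual infeasibility around 1e-3–1e-4, and the polish projects the
iterate back onto the constraint manifold with negligible objective change.
Warm starts carried across cascade stages are projected the same way before
the solve. The predictive effort normalization 1/d gets a smooth 5 cm floor
on the CoM travel d (C¹, exact to ~1e-5 relative at walking distances):
without it the 1/d gradient explodes while the iterate still crawls and the
trust-region subproblems overflow.

The tracking stage uses the midpoint of the variable bounds as its initial
guess (the documented cold-start policy; coordinate ranges are chosen so the
midpoint is a plausible standing pose). Each later stage warm-starts from
its predecessor, resampled in normalized time. Tracking stages fix the final
time to the reference half-stride duration.

## The cascade

Stage sequence: tracking at 10 mesh intervals, tracking at 50, then
Predict1–Predict6 (drop tracking and add clearance/rest/average-speed
0.4 m/s/final-time [0.4, 0.6] s with speed bounds relaxed to 100%; add
straight knees; reduce to the symmetric muscle set with speed 0.1 m/s and
[0.9, 1.1] s; raise the reserve penalty ten-fold; raise speed to 0.2 m/s;
switch to the asymmetric muscle set with full-stride symmetry and
[2.0, 2.2] s). The reduced cascade used by the automated checks runs
tracking → Predict1 → Predict2 entirely at 10 mesh intervals with per-stage
iteration budgets of 3000/2000/1500 (the cold-started tracking stage needs
the most) — the problem sizes chosen for a single-workstation run; the full
sequence is available through `default_cascade` / the `solve-cascade` CLI. The cascade driver treats a
stage as converged when its raw violation is at most 1e-4 — the dynamic-
consistency target documented for the cascade — while `solve()` keeps the
stricter 1e-6 default for standalone use.

## Pattern compilation

Left-side excitations are extracted from the first half of the cycle and
right-side from the second; within each half the stance portion (foot loaded
above 5% body weight) is discarded when contact information is available.
Group elements are averaged, resampled to 22 points by linear interpolation,
and mapped through `PW = e·Sat + Thresh`, clamped to the 0–255 µs device
range. Left pulse widths are multiplied by 1.2 (then re-clamped); the right
time base is stretched by 1.5. Frequency starts at 16 Hz, doubles after
0.15 s for every channel except the vasti, and on the right side returns to
16 Hz for the final 30% of the pattern ("approximately 30%" is implemented
as exactly 30%, config-overridable). Charge per swing counts the cathodic
phase only: amplitude × pulse width summed over pulses placed from t = 0 at
the instantaneous inter-pulse interval, with a partial trailing interval
delivering no pulse. Percent reduction is `100 (1 − optimized/manual)`;
increases are reported with sign; the summary mean/min/max cover the muscles
showing a reduction.

## Gait-trial analysis

Signals are zero-lag filtered (2nd-order Butterworth, 6 Hz cutoff,
forward–backward). Step time is footstrike-to-footstrike per side; stance is
footstrike→toe-off; swing the remainder; step length is the anterior-
posterior distance between the heel markers at the leading foot's strike
(heel rather than toe — the choice is documented, not prescribed). Outlier
steps are removed by Tukey fences (k = 1.5) on medial-lateral walker
velocity and anterior-posterior toe travel, with fences computed once on the
full step set. Joint traces are stride-normalized to a 101-point
percent-cycle grid and ensemble averaged (sample SD). Upper-extremity effort
is the norm of the summed left+right handle force vectors (norm-then-sum
available behind a flag), with peaks and time averages per gait cycle and
per swing. Comparisons use the unequal-variance (Welch/Satterthwaite) t-test
and the Wilcoxon rank-sum (exact for small tie-free samples, normal
approximation otherwise); usability ratings are summarized by median and
IQR per question. The ECDF-vs-normal-CDF sup distance is reported as a
normality aid, never used as a gate. Manual curation (spasm interference,
foot crossing) is represented only as a user-supplied exclusion list.

## Synthetic data

The reference generator produces smooth periodic joint-angle templates
(truncated Fourier series; hip ±0.25 rad, knee 0–0.7 rad bumps, ankle
±0.15 rad at a 0.4 m/s, 120 steps/min slow pace by default) pushed through
the model's forward kinematics, so the tracking target is kinematically
consistent with the model; per-foot vertical ground reactions are
double-bump profiles whose summed vertical impulse per stride is normalized
to body weight × stride time. Reference joint-speed ranges stand in for ranges computed from inverse
kinematics of the recorded reference: they are the template-speed extremes
times a calibration factor (default 10), reflecting that raw differentiated
IK carries high-frequency content roughly an order of magnitude above the
smooth underlying motion. This calibration is what lets the documented
10%-of-range tracking bound admit the reference motion itself, the role it
plays in the staged solve.

The trial generator realizes requested per-side step times, step lengths and
swing/stance ratios exactly before noise: heel markers dwell through stance
and advance one stride during swing with a zero-end-slope smoothstep, and
footstrikes are snapped to the marker sampling grid, so the analyzer
recovers the spatiotemporal parameters to machine precision on noiseless
data. Defaults mirror slow FNS-assisted stepping with long double-stance
pauses (step times ≈ 17 s, step lengths ≈ 0.54 m, ratios 0.13–0.15). Handle
forces are a vertical baseline plus sin² swing bumps with stated peaks.
Noise is additive Gaussian on markers (typical motion-capture magnitude
2 mm) and forces (2 N), off by default; all randomness flows from one seed
per call. What the generator does not emulate: marker occlusion and soft-
tissue artefact, spasm-interrupted steps, asymmetric walker loading,
ground-reaction horizontal transients — so passing recovery tests shows the
analysis pipeline is correct, not that it is robust to every artefact of
real recordings.

## Known limitations

* The planar fixture cannot express circumduction, hip hiking or
  medial-lateral balance; kinematic strategies the 3-D problem discovers are
  out of reach.
* `trust-constr` is a general-purpose NLP solver: on the tracking stage it
  typically consumes its iteration budget before reaching interior-point
  quality optima, so cascade objectives should be read as good feasible
  solutions rather than certified minima.
* Rigid tendons are the default; the compliant-tendon path (normalized
  tendon-force states, auxiliary-derivative cost) is represented in the data
  model and costs but not in the shipped fixture's solve stages.
* Charge accounting assumes the cathodic phase of the biphasic pulse only.
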