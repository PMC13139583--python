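# Methods

`seqaccum` implements two classes of firing-rate circuit models that
accumulate evidence through choice-selective neural sequences, the
behavioral task that drives them, and the statistical pipeline that
distinguishes the models' evidence-coding signatures in (synthetic)
neural sessions.

## The task

A virtual T-maze traversed at constant speed v = 50 cm/s: 30 cm precue
region, 200 cm cue region, 100 cm delay. Tower cues appear on the left
and right with Poisson counts (defaults: means 2.3 and 7.7, the
higher-rate side randomized per trial) at positions uniform over the cue
region subject to a 12 cm within-side minimum spacing. The correct
choice is the side with more towers; the signed accumulated evidence is
e = #right − #left cues seen so far. Position and time are
interchangeable via p = v·t − 30.

**Spacing enforcement.** Spaced uniform positions are drawn with the
order-statistics construction (n uniforms on the region shrunk by
(n−1)·12 cm, sorted, plus i·12 cm). This is exactly the uniform
distribution conditioned on the spacing constraint, never rejects, and
leaves the Poisson count marginals intact; counts are clamped only at
the physical packing limit (18 cues per side). We chose this over
whole-set rejection sampling because at the task rates rejection fails
so often that counts would be biased visibly downward.

**Input noise.** The sensory-noise protocol keeps each cue independently
with probability 0.33 (the subject "misses" 67% of cues); simulation
uses the reduced cue sets while psychometrics are computed against the
original counts. Sessions draw 150 trials without replacement from a
pool; the default protocol is 25 sessions.

## Competing chains (mutually inhibiting)

Two chains of units, one per side. Unit i of the left chain obeys

    dr_iL/dt = −a r_iL + [ b r_iL + c r_(i−1)L − e r_iR
                           + f·1_left(t) + P_i(t) − T ]⁺

with defaults a = 50, b = 10, c = 50, e = 40 s⁻¹, f = 100, T = 15000,
X = 500 Hz/s. The square position gate P_i = T + X on
[20i, 20(i+1)) cm partitions the 330 cm maze into 17 sections (34 units
total). The cue indicator 1_left is 1 when a left cue lies strictly
within 0.5 cm of the current position, so a cue is a 1 cm (20 ms) pulse.

Two identities make the model a perfect sequence integrator:

* within the active pair, the difference D = r_L − r_R obeys
  dD/dt = (−a + b + e) D + … = 0·D + f(1_left − 1_right), so each cue
  adds exactly f·(1 cm / v) = 2 Hz to D;
* at a handoff the new pair integrates c·D_prev while the old pair
  decays at rate a, giving transfer gain c/a = 1.

The baseline rate of the active pair is X/(a − b + e) = 6.25 Hz, so
accumulation saturates when the nondominant chain reaches 0 Hz (at
|e| ≈ 6); X = 1000 Hz/s removes the saturation over the observed range
(linear-tuning variant). Saturation clips magnitude but never flips the
sign of D, so noise-free task performance is perfect either way.

**Choice** is the sign of the final pair's rate difference at maze end;
exact ties are fair seeded coin flips. **Initial rates** are zero (the
gate's X drive establishes the baseline); no initial condition is
prescribed for the chains, and the symmetric zero start preserves
mirror symmetry.

**Variants.**

* *Unstable:* b_i = b0 + 0.5·i s⁻¹, making the difference mode unstable
  by b_i − b0 at position i; evidence tuning sharpens into choice tuning
  along the maze.
* *Choice readout cells:* r = α(sgn(r_L − r_R + ξ) + 1) with α = 5 Hz,
  ξ ~ N(0, 2 Hz), and i + 1 cells per choice at 0-based position i.
* *Uncoupled:* no cross-inhibition; cues enter push–pull
  (+f own side, −f other side). No full equation set is prescribed
  for this variant, so it is instantiated from its qualitative
  description with the constraints that make it integrate: e = 0
  requires b = a for a non-leaky chain, the gate must equal the
  threshold exactly (X = 0) to avoid integrating the gate, and the first
  pair starts at a 10 Hz baseline so opposing cues can push activity
  below baseline. Each net cue is worth 2f·(1 cm/v) = 4 Hz of
  difference here because both chains move.

**Gates.** Besides the square gate: a Gaussian gate
α·exp(−(p − μ_i)²/β) with α = 60 Hz/s, β = 1250 cm², μ_i = 20i − 10,
used with a lowered threshold T = 1100 Hz/s; and a heterogeneous-width
square gate whose transition points are drawn uniformly over the maze
(12 per chain), with any gap under 5 cm repaired by incrementing the
later point by exactly 5 cm, re-checking left to right (re-applied until
stable); the last section extends to the maze end.

## Position-gated bump attractor

17 layers (positions) × 35 evidence levels (−17..17), 595 units:

    dr_ij/dt = −a r_ij + F( Σ_k W_jk r_ik + b r_(i−1)j
                            + c (I_i,j+1,L + I_i,j−1,R) + P_i − T )

with F(x) = q(1 + tanh(γx))/2, W_jk = ω₀(cos(θ_j − θ_k) + ω₁) on evenly
spaced angles, shifter rates I_ijL = r_ij·1_left, I_ijR = r_ij·1_right,
and defaults a = 55, b = 0.088, c = 0.2, ω₀ = 0.12 s⁻¹, ω₁ = −1,
T = 300, X = 0.04, q = 1250 Hz/s, γ = 1 s/Hz. Layer 0 starts with
15/17.5/15 Hz at levels −1/0/+1; everything else at 0.

Local (relative) excitation plus the saturating output sustains a
stereotyped ~9-unit bump; multiplicative shifter gating moves it exactly
one level per 1 cm cue pulse (right cues toward higher j); the square
gate plus same-level feedforward hands the bump to the next layer.
Because evidence is not periodic, the nominally ring-shaped evidence
axis is severed at the ends (out-of-range neighbors contribute
nothing); the bump never approaches the ends in normal trials, so this
differs from the periodic seam only in degenerate cases.

**Choice** is the sign of the evidence label of the most active
final-layer unit; a peak at level 0 is a fair coin flip. An argmax-index-below-half-the-layer rule cannot tie
for an odd layer with integer indexing, so the label-sign rule with a
random tie-break at 0 is the working interpretation. The argmax is taken at
the last grid point.

A traditional (ungated, single-layer) bump attractor and a traditional
two-population accumulator are provided as the no-sequence baselines.

## Numerics

All models are integrated with a stiff-capable adaptive solver (LSODA
via `scipy.integrate.solve_ivp`) with an enforced maximum step of
0.01 s (0.5 cm), piecewise between *breakpoints* — the positions where
the right-hand side is discontinuous (square-gate transitions, cue
window edges, perturbation windows). Within a segment the cue
indicators and gate drive are constant, so no 1 cm pulse can be stepped
over and the integrator never crosses a discontinuity. Trajectories
are reported on a 0.1 cm position grid (3301 points); the dense-output
interpolant's ~1e−13 undershoots below zero are clamped. Tolerances
rtol = 1e−6, atol = 1e−8. Simulations are deterministic given the
trial; the only randomness is in tie-breaking readouts, noise protocols
and synthetic-data generation, all driven by seeded generators (one
global seed expands into named substreams).

**Perturbations.** A subthreshold drive O is added inside the
rectification bracket (chains; O = 25 Hz/s mutual, 12.5 uncoupled) or
inside F (bump; O = 0.2 Hz/s) to one unit while the subject is in that
unit's active window, on a cue-free trial. The control trajectory is
integrated with identical segment boundaries so perturbed and control
runs are bitwise identical before stimulation onset; "unaffected"
units (earlier positions; the opposite chain in the uncoupled model)
differ from control only through shared adaptive step selection, at
≤ ~1e−6 Hz against real effects of order 1–5 Hz.

## Analysis pipeline

**Binning.** Rates are averaged in 5 cm position bins per trial
(−30..300 cm, 66 bins); a bin's evidence is the signed cue count
strictly before the bin start.

**Joint position×evidence fit.** Per neuron, on correct trials, rates
min-max normalized to [0, 1], the separable model
FR = a·exp(−(p−μ_p)²/2σ_p²)·exp(−(e−μ_e)²/2σ_e²) + b is fit by bounded
trust-region least squares (bounds −50 ≤ μ_p ≤ 350, 0 ≤ σ_p ≤ 200,
0 ≤ σ_e ≤ 30, 0 ≤ a ≤ 10, 0 ≤ b ≤ 1), alternating a position block
(μ_p, σ_p, a, b) with an evidence block (μ_e, σ_e, a, b) and ending on
a position update. The μ_e bounds are recomputed each iteration as
[min − 1, max + 1] of the evidence observed within 5 cm of the current
μ_p; a neuron whose final μ_e falls outside its re-derived bounds is
flagged ineligible for normalized-parameter analysis. The evidence
Gaussian may peak beyond the observed range — that is how monotonic
tuning shows up (normalized peaks near ±1).

Numerical choices: 3 alternations with early stop at parameter change
< 1e−3; initialization μ_p at the peak bin, σ_p = 30 cm, μ_e the
rate-weighted mean evidence near the peak, σ_e = 5, a = 1, b = 0;
observations sharing a (bin, evidence) pair are collapsed to weighted
means (identical normal equations, ~20× fewer residuals), with the
within-group sum of squares restored when reporting the MSE; constant
neurons return a zero-amplitude fit rather than an error; analytic
Jacobians throughout.

**Pseudosession significance.** Null sessions pair the true firing with
evidence from freshly generated trial sets (whole-trial resampling);
each neuron is refit against each of n = 50 pseudosessions. The
default decision rule is the empirical rank of the observed MSE in the
null, p = (1 + #{null ≤ obs})/(n + 1), which has exact type-I control
under exchangeability (measured false-positive rate ≈ 4% at α = 0.05
on evidence-blind position-tuned neurons). A one-sample t-test of the
null MSEs against the observed MSE (one-sided) is available as
`method="ttest"`; note that under exchangeability its statistic is
approximately N(0, n+1)-distributed, making it strongly anticonservative
(measured ≈ 33% false positives) — which is why it is not the default.

**Normalization.** μ_e < 0 is divided by max|e| over negative
observations near μ_p, μ_e > 0 by the max positive observation, σ_e by
the full observed range; μ_e = 0 maps to 0.

**1-D tuning curves.** Observations within 0.5 σ_p of μ_p (clipped to
0–300 cm), averaged per integer evidence level, fit to both a Gaussian
a·exp(−(e−μ)²/σ²) + c and a logistic a/(1 + exp(−k(e−x₀))) + c
(bounds −1 < k < 1, −15 < x₀ < 15); winner by MSE on the averages, no
complexity correction (equal parameter counts).

**Cue kernels.** Ridge regression (λ = 1, unpenalized intercept) of the
right-minus-left preferring population difference on cue-onset
indicators (onset 10 cm before the tower) convolved with a clamped
cubic B-spline basis with 7 degrees of freedom (3 evenly spaced
interior knots) over a 300 cm kernel support; optional splits by prior
|evidence| (widths 300/200/200 cm) or cue position (300/230/160 cm).

**Evidence-vs-choice regression.** Per neuron and bin, on correct and
incorrect trials, FR = β₀ + β₁e + β₂c by OLS (c: left = 0, right = 1 —
only significance is interpreted, so the coding is immaterial);
one-sided partial F-tests (F = t², F(1, n−3)) at the 1% level; a
neuron is active at p when |p − μ_p| < σ_p. The OLS core is vectorized
across neurons sharing a design and verified against `statsmodels` in
the tests.

**Linear decoding.** Per bin, correct trials, two ridge decoders
(evidence ≥ 0 and ≤ 0; strict variants > 0 / < 0 exclude the
sign-of-evidence shortcut), nested 5-fold CV with the regularization
chosen from {1e−4 … 1e3} in the inner folds, scored by the Pearson
correlation between decoded and actual evidence on the outer test
folds; shuffle controls permute evidence within sign, 5 repeats.
Zero-variance branches report missing values.

**Population maps.** Mean rates in position × preferred-evidence bins
(left-preferring neurons' evidence axes reflected), with a neuron
contributing to a bin only with ≥ 3 observations and bins sampled in
< 10% of sessions masked; cross-sections at 50/100/150/200/250 cm.

## Synthetic sessions

The generator emulates the data structures the pipeline consumes:
30 Hz frames during constant-velocity traversals, synchronized
position/trial indices, per-trial choices. Model-driven sessions
resample simulated circuit units onto frames (optionally with additive
Gaussian or Poisson-count noise); parametric sessions draw separable
ground-truth fields FR = A·P(p)·E(e) + B with Gaussian position tuning
and Gaussian, logistic, choice-only or null evidence tuning. Choices
follow the majority side with a lapse probability decaying in |e|
(logistic; scale 0.4), so error trials exist — required for separating
evidence from choice coding. Spike smoothing uses the unit-sum
Gaussian window (1 s, sd 0.25 s) or its causal half-Gaussian variant.

Deliberately not emulated: calcium dynamics and spike inference (the
pipeline starts at spikes/rates), view-angle and speed variability,
behavioral trial exclusions, and cross-neuron noise correlations.
Passing tests on these sessions validate the pipeline's statistics and
recovery properties, not its robustness to those real-data features.

## Problem sizes in the shipped tests

The test suite runs the study conditions at reduced scale to stay
fast: 200 noise-free trials per model for the perfect-performance
check; 6 noise sessions × 50 trials for the psychometric comparison;
100-trial chain sessions and 60-trial bump sessions (52 units spanning
4 positions × 13 evidence levels) with 25 pseudosessions for the
signature analyses. The chains *monotonic-signature* session uses the
linear-tuning parameterization (X = 1000 Hz/s): at the saturating
default the tuning is flat beyond |e| ≈ 6, so on sessions that sample
evidence to ±14 the fitted evidence peak is not identifiable at the
extreme (normalized peaks ≈ 0.6–0.8), whereas in the linear regime all
peaks pin at the observed bounds; 3000 null neurons for the F-test calibration and
120 for the pseudosession calibration. The acceptance script uses
100,000 null neurons at one bin for the false-positive target. The
protocol defaults in the package itself (25 sessions × 150 trials,
50 pseudosessions) match the study conditions.

## Known limitations

* The uncoupled-chains variant is reconstructed from a verbal
  description; its parameters are a minimal integrating instantiation.
* The bump readout's exact-tie case cannot occur with odd layer
  sizes; the sign-of-label rule used here is an interpretation.
* "Exact zeros" for unaffected units in perturbation experiments are
  exact only before stimulation onset; afterwards they hold to solver
  tolerance because all units share one adaptive integration.
* The pseudosession t-test variant is
  anticonservative (see above); the calibrated rank test is the
  default, and analyses that quote significant fractions depend on
  this choice.
* Gaussian-gate and heterogeneous-gate chains reuse the square gate's
  neuron indexing for perturbation windows.
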