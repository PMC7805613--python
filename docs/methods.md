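# Methods

## The layered model

The plant is a planar two-link arm (upper arm; forearm + hand) in the
sagittal plane, gravity along −y.  Generalized coordinates are
q = (φ, ψ): elbow flexion φ (0 = straight arm) and shoulder flexion ψ
(0 = hanging).  The equations of motion are the standard double-pendulum
manipulator form M(q)q̈ + C(q, q̇)q̇ + G(q) = T + Jᵀ F_ext with a symmetric
positive-definite mass matrix; a small passive joint damping
(0.05 N·m·s/rad, soft tissue) is included.  Segment parameters describe a
generic adult male (upper arm 2.1 kg / 0.31 m, forearm+hand 1.7 kg /
0.34 m); they are plausible literature-scale values, declared
approximations, and fully exposed in the YAML config — not reproductions of
any specific subject.

Six muscle–tendon units actuate the arm: monoarticular shoulder
flexor/extensor and elbow flexor/extensor, plus a biarticular flexor and
extensor pair.  Muscle paths use a constant-radius pulley with mild angle
dependence, moment arm r(θ) = r₀·cos(γ(θ−θ_c)) (γ = 0.5 rad⁻¹; γ = 0 gives
constant arms), so the MTU length is a closed-form integral and
∂l/∂θ = −r(θ) holds exactly — the property the finite-difference tests
check.  Flexors have r₀ > 0 (length shortens with flexion).

Each MTU is a four-element Hill model:

* **CE** — active force F_max · a · f_l(l_CE) · g(l̇_CE), with a Gaussian
  force–length curve (width 0.45, maximum at l_opt) and a hyperbolic Hill
  force–velocity curve (curvature 0.25, v_max = 10 l_opt/s, eccentric
  plateau 1.5 F_max, slope-matched at v = 0);
* **PEE** — parallel elastic, slack at/below l_opt, quadratic above;
* **SEE** — tendon, quadratic in strain, F_max at 4 % strain, plus a serial
  damping element (0.3 F_max/v_max).

Fiber velocity follows from the CE+PEE vs damped-SEE force equilibrium.
Because both force–velocity branches are hyperbolic, that equilibrium is a
quadratic per branch and is solved in closed form (branch chosen by the sign
of the net force excess at v = 0; a "yielding" branch caps active force at
zero when the demanded shortening exceeds v_max).  The tendon force is
clamped at zero — it cannot push.

Activation is a Hatze-type first-order process
da/dt = m·(a_∞(u, l_CE) − a) with rate m = 11.3 s⁻¹ and a stationary
activity a_∞ = (a_min + y)/(1 + y), y = (k·u·l_CE/l_opt)^ν (k = 3, ν = 3,
a_min = 0.005): saturating in the stimulation u, increasing in fiber
length.  The closed-form inverse u(a_∞) is used when planning
equilibrium-point commands and in the tests.

## The controller

The hierarchy has three command layers above the muscles.  `u_central` is
the integer index of the active equilibrium-point (EP) segment — a single
piecewise-constant timing signal.  `u_topdown` are the twelve
muscle-specific piecewise-constant commands (six open-loop stimulations
u_open, six desired fiber lengths λ); all twelve switch at the same sample.
The motor command per muscle is

```
u_i(t) = { u_open_i + k_p · (l_CE_i(t−δ) − λ_i)/l_opt_i + u_cpg_i(t) }₀¹
```

clamped once, to the full sum.  The feedback is a simplified mono-synaptic
spindle reflex: fiber lengths, delayed by δ = 10 ms, compared against λ with
the stretch-reflex sign (a stretched fiber receives extra drive) and a gain
normalized by the optimal fiber length.  k_p defaults to 0.2: with the 10 ms
delay and the ~90 ms activation lag, gains above ≈ 0.5 drive the loop into a
limit cycle, while 0.2 settles every hold to ‖q̇‖ < 10⁻³ rad/s and completes
the reaches without overshoot beyond 10°.  The CPG term is
û·sin(2π f t + φ₀) with û = 0.1, φ₀ = 0 for flexing and π for extending
muscles, active only in the excitation window 0–4 s of the oscillation
protocol.

**EP planning.**  For a desired posture q\*, all muscles start at a baseline
co-activation (0.12 — high enough that antagonist stiffness damps the EP
dynamics), and the loaded monoarticular muscle of each joint is raised by
bisection until the isometric muscle torques balance gravity at q\*.
λ is set to the steady-state fiber lengths there and u_open to the
stimulation whose stationary activity matches; the spindle feedback then
vanishes exactly at q\*, making the planned posture a true equilibrium of
the closed loop.  This is the root-finding-on-statics construction the
tests verify (reaches end within 2° of the planned target).

## Movement protocols (what the generator emulates)

* **Point-to-point** (CPG off, no rod): three EPs — start, peak-elbow,
  target — switched at 0, 0.7 and 1.3 s; 3 s per run, the arm starting at
  the start-EP equilibrium.  Natural trial-to-trial variability is emulated
  by jittering the EP angles (start and target in both joints, the peak in
  the elbow only) with σ = 2°, truncated at ±2σ, redrawing postures outside
  the joint range.  Only the muscle-specific top-down commands differ
  between repetitions, mirroring how repeated human trials of one movement
  differ.
* **Oscillation** (rod attached): one EP held (elbow 90°), CPG at
  f ~ U(3.6, 4.0) Hz for 0–4 s, 6.5 s per run.  The rod is a point mass
  (0.1 kg) on a linear spring–damper along the vertical lab axis, tuned to
  3.8 Hz resonance with quality factor ≈ 20.  The mass is deliberately
  light: the rod also loses energy *through the hand* into the damped
  muscles, and a light rod keeps the post-excitation ring-down above 25 %
  of the driven amplitude over 4–6 s, which is the behavior of the hand-held
  training rods the protocol emulates.  Rod displacement amplitudes
  (~0.3 m) stand for the tip flexion of a long elastic rod, not a rigid
  translation.

What the generator does **not** emulate: sensor/motor noise in the clean
runs (trajectories are smooth by construction — which is exactly why the
stimulation-noise experiment exists), 3-D shoulder kinematics, wrist and
grasp dynamics, motor-unit structure, fatigue, or measurement noise of
motion capture.  Passing tests therefore show that the *estimator and the
orderings* behave as expected under these idealized dynamics, not that the
absolute bit values would match any specific experimental recording.

**Noise runs.**  Uniform zero-mean noise with total width 40/300 (medium) or
80/300 (high) of the per-muscle stimulation range is added per sample to the
clean u-trace, re-clamped to [0, 1], and *replayed* through muscles and
skeleton with the feedback loop severed, so activity, forces and angles
respond to the noise while the top-down commands stay clean.

**Discrete benchmarks.**  Markov processes with exactly known MC validate
the estimator: `independent` (w′ depends only on a; MC = 0), `copy_world`
(w′ = w, W uniform, A independent; MC = H(W) — since every state of the copy
kernel is absorbing, transition samples are drawn i.i.d. from the stationary
ensemble rather than as one frozen trajectory), and `general` (random
Dirichlet kernel; MC computed exactly from the kernel and the chain's
stationary distribution).  The plug-in estimator's bias at the benchmark
sizes (alphabets ≤ 8, T = 10⁵) is below 0.01 bits.

## Quantifying MC

Traces are sampled at 1 kHz.  Each channel is binned into uniform-width bins
over its observed range in the **full trace** (left-closed/right-open,
maximum in the last bin; constant channels collapse to one bin); a
multi-channel state's symbol is the combination of per-channel bin indices.
The joint p(w_{t+1}, w_t, a_t) is a frequency count over the T−1
transitions, MC_W the probability-weighted log-ratio sum (log2; bits), and
the state-dependent MC_W(t) evaluates the same log-ratio per transition.
MC_W is clamped at 0 against −10⁻⁹-scale rounding; a genuinely negative
value raises, since the quantity is a KL divergence.

Binning resolution (the one methodological free parameter, config-exposed):

* the actuator side always uses 30 bins per channel.  A only conditions;
  refining A can only improve the action-only prediction and never
  manufactures MC, so it gets the full resolution the sample supports;
* the world side uses 30 bins in selected mode (≤ 3 observable channels,
  the situation of an experimenter discretizing recorded signals), and in
  accumulated mode the occupancy rule max(2, min(30, ⌊(N/5)^(1/n_total)⌋))
  evaluated at the **full** hierarchy dimension n_total (41–42 channels),
  i.e. 2 bins per channel at our run lengths.  Using one resolution for
  every cut of a trace keeps the cut-to-cut comparison about the dynamics
  rather than about changing bin counts.

When MC is evaluated on a time window (the 2–4 s resonance phase vs the
4–6 s ring-down), the window selects transition samples only; the bins stay
those of the full trace.  A control signal that is steady *relative to its
full-trace excursion* then remains a steady symbol, which is precisely the
contrast the phase analysis measures — per-window re-binning would zoom
into the microscopic feedback ripple and erase it.

Level splits: selected mode takes one hierarchy level as A and the
observable state q (+ rod) as W; accumulated mode cuts the hierarchy,
A = everything at/above the cut, W = everything strictly below.  q and the
rod position are never part of A; cutting at q is an error.

## Statistics

Each run yields one MC_W per level; runs are subjects of a fully repeated
one-way design.  Shapiro–Wilk screens each level group at α = 0.1 (liberal
on purpose: failing to detect non-normality is the risk here).  The
repeated-measures ANOVA is computed from sums of squares,
F = MS_level / MS_{level×run}; Greenhouse–Geisser-corrected p is reported
alongside the uncorrected one (the uncorrected value is the headline
number).  Post-hoc: pairwise paired two-sided t-tests, Bonferroni-adjusted
by the number of pairs (capped at 1); levels linked by non-significant pairs
at α = 0.05 form the reported groups.  All-zero difference columns (e.g.
u_central vs u_topdown, identical by construction since the twelve top-down
channels switch with the central clock) are assigned p = 1.

## Numerical choices

* Fixed-step classical RK4, dt = 0.5 ms, one global 18-dimensional state
  (q, q̇, rod, six activities, six fiber lengths).  A fixed step makes the
  10 ms delayed feedback trivial (dense per-step history, linear
  interpolation) and runs bit-reproducible.  Halving dt changes joint
  trajectories by < 10⁻³ rad and every reported MC_W by < 0.01 bits.
* Activities are clipped to [0, 1] and fiber lengths floored at 0.05 l_opt
  after every step; divergence (non-finite state or |q| > 20 rad) raises
  with the partial trace attached for diagnosis.
* Isometric fixed points use 100-step bisection (machine-precision
  lengths); if the tendon is slack over the whole admissible range, the
  slack boundary (zero force) is returned.
* EP feasibility: postures whose gravity torque exceeds the available
  muscle torque at 90 % activation raise a config error; jittered postures
  outside the joint range are redrawn.
* Symbolization enumerates observed bin-index combinations
  (lexicographic); alphabet sizes are counts of observed symbols.

## Problem sizes

The shipped studies use three point-to-point and three oscillation runs for
the ordering analyses and five seeded seven-run point-to-point studies for
the statistics — enough repetitions for every ordering to be evaluated
per-run and for the post-hoc grouping to stabilize, at a few minutes of
total compute.  Larger designs (the CLI defaults: 7 reaches, 14
oscillations) only narrow the confidence intervals; they do not change any
reported ordering.

## Known limitations

* Absolute MC values depend on the discretization policy and the sampling
  rate; only comparisons under one policy are meaningful.  The defaults are
  choices, not measurements.
* The finite-sample plug-in estimator is biased upward for rich alphabets;
  at the top cut (A nearly constant) MC_W partly reflects trajectory
  richness relative to the run length.  This is inherent to the
  frequency-count approach; the benchmark suite quantifies the bias where
  ground truth exists.
* The spindle feedback is length-only (no velocity or force feedback), the
  activation model is first-order, and muscle paths are pulley
  approximations; parameter values are generic defaults, so subject-specific
  predictions are out of scope.
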