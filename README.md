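# neuromc

Morphological computation across a hierarchical neuro-musculoskeletal model
of human arm movements.

## The scientific problem

Voluntary arm movements emerge from a cascade of control layers: a central
timing signal selects equilibrium postures, muscle-specific top-down commands
set open-loop stimulations and desired fiber lengths, spinal circuits add
delayed proprioceptive feedback, muscle biochemistry turns stimulation into
activity, and Hill-type contraction dynamics turn activity into force,
torque, and finally motion.  Part of the "computation" needed to produce a
smooth movement is done not by neurons but by the physics of the body — the
viscoelastic muscle properties acting as zero-delay *preflexes*, the
skeleton's passive dynamics, a hand-held oscillator ringing at its resonance.
This contribution is **morphological computation (MC)**, and it can be
quantified in bits.

For a world state *W* (the physical system) and actuator state *A* (the
control signal at some hierarchy level), the world-dynamics kernel
α(w′|w, a) describes how the next world state depends on the current one and
on the action.  If the current world state were irrelevant — α̃(w′|a) — the
controller would be doing everything.  The divergence from that assumption is
the morphological computation

```
MC_W = Σ p(w′, w, a) · log2 [ p(w′|w, a) / p(w′|a) ]   (bits)
```

which equals the conditional mutual information I(W′; W | A) of the
discretized trajectory.  `neuromc` simulates two movement protocols
(point-to-point reaches; rod-oscillation at the rod's 3.8 Hz resonance,
driven by a sinusoidal central-pattern-generator signal with amplitude 0.1)
and evaluates MC_W at **every** level of the control hierarchy, under two
splits:

* **selected** — A is one hierarchy level, W is the observable mechanical
  state **q** (joint angles, plus the rod position);
* **accumulated** — a clean cut: A is everything at or above a level, W is
  everything below it.

The package is for computational motor-control and bio-robotics researchers
who want to ask *where* in a layered controller the physics takes over.

## Worked example

```python
import numpy as np
from neuromc import (generate_discrete_benchmark, mc_w, mc_by_level,
                     sample_ep_variations, run_point_to_point)
from neuromc.mc import estimate_joint_from_triples

# 1) validate the estimator on a process with known MC:
#    w' = w with W uniform over 4 symbols => MC = H(W) = 2 bits
b = generate_discrete_benchmark("copy_world", 4, 4, 100000, seed=3)
print(mc_w(estimate_joint_from_triples(b.w_next, b.w, b.a)))
# 1.9999 (finite-sample estimate of the analytic 2.0)

# 2) three point-to-point reaches with naturally jittered equilibrium
#    postures, MC_W per hierarchy level under the accumulated split
schedules = sample_ep_variations(3, seed=11)
traces = [run_point_to_point(s, seed=11) for s in schedules]
print(mc_by_level(traces, "accumulated").round(3))
```

which prints (bits; columns ordered from the most central level down):

```
     u_central  u_topdown      u      a   F_CE  F_MTU    T
run
0        2.438      2.438  0.379  0.083  0.024  0.023  0.0
1        2.652      2.652  0.446  0.071  0.041  0.041  0.006
2        2.340      2.340  0.178  0.015  0.002  0.002  0.0
```

Read row-wise: when the cut is placed at the very top (A = the central
timing signal alone), almost everything about the next state is carried by
the body and the lower control layers — MC_W ≈ 2.4 bits.  Moving the cut
down the hierarchy transfers those layers into A, and MC_W falls
monotonically to ≈ 0 at the torque level: the full signal set predicts the
joint angles almost perfectly.  The same call with `"selected"` reproduces
the torque exception (MC at level T higher than at F_MTU, because two torque
channels carry less information than six force channels).

The command line mirrors the library: `neuromc simulate p2p --reps 7 --seed 1`,
`neuromc simulate osc --reps 14 --seed 1`, `neuromc bench --kind general
--sizes 4 4 -T 100000`, `neuromc quantify trace.csv --mode accumulated`,
`neuromc analyze mc_table.csv`, `neuromc config dump`.

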