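# babblereach

Emergent reaching and pointing from motor babbling: a neural-network model
of how an infant-like agent can acquire target-directed arm movements
without ever being shown a target.

## The problem

Infants reach toward visible objects from 3–5 months of age, reach
successfully without watching their own hand by about 7 months, and extend
an arm toward *out-of-reach* objects — primitive, not-yet-communicative
pointing — before the end of the first year. `babblereach` models a
computational route to all three: through spontaneous random movement
(*motor babbling*) paired with intermittent vision of the hand, an agent
can learn a **forward transformation** (motor command → predicted visual
consequence) and an **inverse transformation** (visual position → the
command that produces it). Coupled into a loop, the two transformations
implement feedback control with an internal state estimate — reaching in
the dark, with no explicit target representation anywhere in the learner.

## The model

A two-joint arm moves in the horizontal plane: shoulder angle α, interior
elbow angle β (180° = full extension), both in [0°, 180°], unit segment
lengths, commands (Δα, Δβ) clipped at the joint limits. Vision reports the
hand in body-centered polar coordinates (r, θ).

Motor commands and visual positions are *place-coded* by populations of
broadly tuned units (truncated-cosine tuning, e.g. 90° azimuth half-width)
whose preferred vectors tile twice each variable's definition range —
10×10 = 100 motor units over Δ ∈ [−20°, 20°] per joint, 10×20 = 200 visual
units over r ∈ [0, 3], θ ∈ [−90°, 90°].

Two three-layered logistic networks (400 hidden units each, no biases)
learn online by backpropagation (η = 0.05, summed-squared error between
population codes):

    forward:  h_f(t) = σ(W_mu u~(t) + W_vy y~(t) + W_hh h_f(t−1))
              y*(t+1) = σ(W_hy h_f(t))
    inverse:  u*(t) = σ(V_u σ(V_y y~(t+1) + V_h h_f))

The forward network is a simple recurrent network: when vision is absent
(availability 0.8 during babbling; always, during reaching) its hidden
layer carries the position estimate forward. The inverse network reads
that hidden state — "where the hand was" — plus the seen outcome, and
postdicts the command. After learning, presenting any visual position as
if it were the hand's outcome makes the inverse emit a command toward it;
looping inverse → forward (hand vision removed) chains small commands into
a reach, including toward distances the arm cannot attain and babbling
never visited.

## Worked example

```python
import babblereach as br

cfg = br.TrainConfig(n_iterations=200_000, seed=0)   # scaled; default is 1.2M
params, log = br.train(cfg)
motor, visual = br.grids_from_config(cfg)
print(log.last)
```

The final checkpoint on the fixed 25-probe grid (posture (30°, 60°),
commands {−20,−10,0,10,20}° per joint) prints:

```
forward_error_mean 0.0656   # mean Cartesian error of the decoded one-step
                            # prediction, arm-segment units (arm length = 1)
inverse_joint_error_mean 2.20          # mean |decoded − true| command, degrees
inverse_direction_cosine_mean 0.9931   # decoded commands point at the target
```

One-step forward predictions versus reality (first rows):

```python
for cmd, actual, pred in br.test_forward(params, motor, visual)[:3]:
    print(cmd, (actual.x, actual.y), (pred.x, pred.y))
```

```
cmd (-20,-20): actual (x,y)=(+0.119,+0.674) predicted (+0.062,+0.767)
cmd (-20,-10): actual (x,y)=(+0.219,+0.816) predicted (+0.142,+0.837)
cmd (-20,+0):  actual (x,y)=(+0.342,+0.940) predicted (+0.241,+0.963)
```

Closed-loop reaching toward seven targets at distance 2 (4 loop
iterations, posture (20°, 40°), no hand vision):

```python
from babblereach.interface import reach_summary
within = [br.reach(params, motor, visual, br.ReachSpec(target=t, n_loop=4))
          for t in br.default_targets(2.0)]
print(reach_summary(within))
```

```
mean_initial_distance 1.709   mean_final_distance 0.789
mean_final_distance_ipsilateral 0.638   contralateral 1.075
```

The hand closes most of the distance to every target, more accurately on
the arm's own (ipsilateral) side — the same asymmetry seen in early infant
reaching. One trajectory, toward (r, θ) = (2, +60°):

```
 step  alpha    beta     x     y  d_alpha  d_beta
    0 20.000  40.000 0.000 0.684
    1 15.068  63.100 0.297 1.003   -4.932  23.100
    2 10.513  85.902 0.731 1.150   -4.555  22.801
    3 11.291 105.642 1.057 1.193    0.778  19.740
    4 14.733 118.136 1.199 1.227    3.442  12.494
```

The elbow extends step by step and the hand tracks toward the target. With
targets at distance 3 (out of reach, 7 iterations) the arm extends to
nearly full length and orients toward each target's side — the model's
account of primitive pointing.

## Command line

```sh
babblereach train --config cfg.yaml --out model.npz
babblereach test-forward --model model.npz --out forward.csv
babblereach test-inverse --model model.npz --out inverse.csv
babblereach reach --model model.npz --target 3 60 --loops 7 --out traj.csv
babblereach suite --seed 1 --out results/       # everything, plus report.json
```

An empty (or absent) YAML config reproduces the default study conditions;
any field can be overridden per section (`arm`, `coding`, `network`,
`training`, `experiments`, `output`) — see `docs/methods.md`.

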