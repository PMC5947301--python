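# Methods

## The model in brief

`babblereach` implements a developmental model of how reaching — and, toward
out-of-reach objects, primitive pointing — can emerge from *motor babbling*
alone: random arm movements paired with intermittent visual observation of
the hand, with no target ever presented and no representation of "error to a
goal" anywhere in the system.

The plant is a two-joint arm in the horizontal plane. Two three-layered
networks of logistic units learn, simultaneously and online:

* a **forward transformation** (simple recurrent network): from the
  population-coded motor command u~(t), the population-coded visual hand
  position y~(t), and its own previous hidden activation h_f(t-1), predict
  the visual population y*(t+1) after the movement;
* an **inverse transformation**: from the population-coded visual position
  y~(t+1) and the forward network's hidden state — an internal
  representation of where the hand was *before* the movement — postdict the
  motor command u*(t) that produced it.

After learning, feeding the inverse network a visual position that is *not*
the hand makes it emit a command "toward" that position; closing the loop
(inverse output → forward input, hand vision removed) generates a sequence
of small commands that carries the hand to within-reach targets and extends
the arm toward out-of-reach ones.

## Plant

Shoulder at the body center (body width neglected), two unit-length
segments. `alpha` is the shoulder angle counterclockwise from the rightward
(+x) axis; `beta` the interior elbow angle, 180° = full extension; the
forearm direction is `alpha + 180° - beta`. This is the unique simple
convention under which the model's canonical correspondence —
(alpha, beta) = (30°, 60°) ⇔ Cartesian (0, 1) ⇔ polar (r, θ) = (1, 0) —
and the maximum reach of 2 segment lengths both hold with joint ranges
[0°, 180°]. Commands are joint displacements, each clipped independently so
a joint "stops at the edge" of its range. Vision reports polar (r, θ) with
θ measured from straight ahead, positive toward the modeled (right) arm's
side; behind-body positions (|θ| > 90°) are representable and are passed to
encoding unmodified (only the joints clip, never vision).

## Population coding

Both signals are place-coded by broadly tuned units on regular lattices of
preferred vectors:

| grid    | dims                 | units   | definition range     | lattice span (2x)    | half-width |
|---------|----------------------|---------|----------------------|----------------------|------------|
| motor   | (Δalpha, Δbeta)      | 10 x 10 | [-20, 20]° per joint | [-40, 40]°           | 20° / joint|
| visual  | (distance, azimuth)  | 10 x 20 | [0, 3] x [-90, 90]°  | [-1.5, 4.5] x [-180, 180]° | 1.5 units, 90° |

The tuning curve is a truncated cosine per dimension, combined
multiplicatively: `g(δ; w) = cos(90°·δ/w)` for |δ| < w, else 0. The visual
azimuth half-width (90°) is the one printed broad-sensitivity value; the
other half-widths follow the same "half the definition-range length" rule.
The lattice spans *twice* each definition range (endpoints included) because
units preferring out-of-range values are needed to represent inputs at the
edge: without them every responding unit prefers a more central value and
the decoded vector shifts inward (quantified in the acceptance tests by
comparing a doubled against a non-doubled grid at azimuth ±90°).

Decoding is the center-of-gravity population vector,
`Σ aᵢ pᵢ / Σ aᵢ` — plumbing the model needs for reporting and for driving
the physical arm, not part of the learned system. On the interior of the
definition range the decode∘encode error is below half a lattice spacing;
outside the definition range it can grow (documented, not asserted).
Teacher signals for learning are these same encodings: errors live between
population representations, never between raw vectors.

## Networks and learning

Layer sizes 100 (motor) / 200 (visual) / 400 (hidden, each network). No
bias nodes, no momentum, no Fahlman offset. Loss is the summed squared
error of the output population against its teacher; updates are one online
gradient step per observation with fixed learning rate η = 0.05 through
logistic derivatives.

Design choices where the design was genuinely open:

* **Recurrence** is Elman-style: the context h_f(t-1) enters as a frozen
  input; there is no backpropagation through time. The forward model is a
  predictor, not a sequence learner.
* **Inverse gradient stopping**: the inverse error updates V_u, V_y, V_h
  only; it never propagates into the forward network through the hidden
  connection. This keeps the forward model purely predictive.
* **Which hidden state the inverse sees**: the inverse trains on the hidden
  state as it stood when the babbled command was issued — the internal
  representation of the *pre-movement* hand position — paired with the
  post-movement visual input and the command as teacher. Feeding it the
  hidden state computed *after* integrating the command instead lets
  gradient descent find a shortcut — reading the command straight back out
  of the hidden layer — after which the inverse ignores the visual input,
  its outputs collapse to near-zero displacement at test time, and reaching
  fails. The pre-movement wiring is also what the closed reach loop
  supplies: there the hidden state handed to the inverse always represents
  the current position estimate, before the next command.
* **Weight initialization**: independent Uniform(-0.1, 0.1), seeded. A
  small symmetric init is the natural choice with no bias parameters; the
  scale is configurable.
* **Update order within a step**: forward update first, then the inverse
  update computed from pre-update activations, so one iteration is
  order-independent.

Weights are stored Fortran-ordered and updated in place through BLAS
rank-1 (`ger`) calls; float32 (default) and float64 are both supported and
the update rule is identical (float32 halves the memory traffic of the
400 x 400 recurrent updates, which dominate the run time; a unit test pins
the float32 update to the float64 one at single precision).

## Training loop

Per iteration: draw u(t) with each joint i.i.d. Uniform(-20°, 20°); move
the (clipping) arm; draw visual availability (probability 0.8,
independently per step); propagate the forward network with the *previous*
step's observation as visual input (a zero vector if it was unobserved —
the same convention used for "in the dark" reaching); then, only if the new
position is observed, update the forward network (teacher: the observed
position's code) and the inverse network (inputs: that code and the
pre-movement hidden state; teacher: the command's code). Unobserved steps
perform no update at all — availability gates the teacher, and both
teachers need the post-movement observation. The hidden state carries over
every step.

Babbling is one continuous random walk: the posture is never reset by
default (episodic resets, which also clear the hidden state to its resting
value 0.5 and redraw the posture, exist behind `episode_reset_every` and
are off). The initial posture is drawn uniformly from the joint range; over
the default 1,200,000 iterations the walk covers the workspace, so the
start does not matter. The initial view of the hand is subject to the same
availability draw as every later step. Everything is reproducible from
(seed, config).

Checkpoints (default: every n/20 iterations) evaluate a fixed 25-probe
grid — the one-step test set: posture (30°, 60°), all command combinations
of {-20, -10, 0, 10, 20}° per joint — recording the mean decoded forward
prediction error (Cartesian, arm units), the mean per-joint inverse command
error (degrees), and the direction cosine between the hand movement the
decoded inverse command actually produces and the required movement
direction (zero-displacement probes excluded).

## Experiments

All experiments first settle the network state: 20 propagations with
vision fixed to the initial hand position and the motor input fixed to the
zero command, after which the hidden layer holds an internal representation
of the starting position.

* **One-step forward test** — posture (30°, 60°), the 25-command grid, one
  propagation per command with vision still fixed to the start; the decoded
  prediction is compared with the true post-movement position. Predictions
  are least accurate for commands at the range limits (edge commands decode
  against fewer, more truncated tuning curves).
* **One-step inverse test** — targets are the 25 positions reached by that
  same command grid; each target's code plays "the hand after the
  movement" and the decoded output command is executed to see whether it
  moves the hand toward the target.
* **Reaching loop** — posture (20°, 40°); 7 targets at distance 2 with 4
  loop iterations (within reach) and at distance 3 with 7 iterations (out
  of reach). Per iteration the inverse postdicts a motor population from
  the target code and the current hidden state; its *raw population* feeds
  the forward network (decode→re-encode is available behind a flag but
  double-quantizes), while its decoded value drives the physical arm; the
  forward network runs with zeroed visual input. Hand vision is never
  computed inside the loop — the movement is performed in the dark, steered
  by the internal prediction.

Target azimuths are {-90, -60, -30, 0, 30, 60, 90}°: seven symmetric,
evenly spaced directions spanning the visual azimuth range (the exact
values are configurable). In the reaching analyses "lateral" targets are
those with |azimuth| ≥ 60°, and ipsilateral/contralateral means
azimuth > 0 / < 0 (right arm modeled).

## Problem sizes used by the test suite

The shipped tests and acceptance checks train **3 seeds x 200,000
iterations** (float32, all other conditions at their defaults), the
package's scaled study size; each run takes on the order of a minute on one
CPU core. Qualitative claims (learning-curve descent, positive inverse
direction cosine, within-reach approach, ipsilateral advantage, out-of-reach
extension and lateral orientation) are asserted as a majority over the three
seeds. The full 1,200,000-iteration condition is the library default and
runs in under ten minutes (`babblereach suite`); it sharpens the same
behaviors but is not required by any test.

## What the synthetic conditions do and do not show

The "data" here are entirely self-generated: an idealized kinematic plant
observed through noiseless, delay-free polar vision. Passing tests show
that the learning architecture extracts both transformations from random
movement and that the closed loop produces target-directed behavior under
those idealized conditions. They do not speak to intrinsic neural noise,
sensory delay, muscle/torque dynamics, 3-D redundancy, or retinotopic-to-
body-centered remapping — all outside this model's scope. The rightward
trajectory bias and poorer contralateral accuracy arise from the asymmetric
joint geometry (a right arm), not from any asymmetry in the networks.

## Numerical notes

* Logistic nonlinearity: `scipy.special.expit` (stable at large |x|).
* Degenerate inputs: an all-zero population raises on decode; encoding
  rejects non-finite vectors; training raises a divergence error naming the
  iteration if weights become non-finite at a checkpoint.
* Zero-displacement probes are excluded from direction-cosine averages
  (the direction of a zero vector is undefined).
* Joint clipping stays active during reach — it is a property of the
  plant, not of the controller.

## Known limitations

* The inverse model is trained only on one-step consequences; multi-step
  reaching quality therefore degrades with distance and laterality, which
  is the developmental point rather than a defect.
* Decoded commands from a trained inverse carry a small magnitude shrinkage:
  logistic outputs never reach 0, so the center-of-gravity readout is pulled
  slightly toward the lattice centroid (zero displacement).
* Behind-body visual positions are representable but sparsely covered by
  the (doubled) azimuth lattice; round-trip fidelity is only guaranteed on
  the interior of the definition range.
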