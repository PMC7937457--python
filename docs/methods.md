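# Methods

This note records the modelling choices behind `lungcad`, the reasoning
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Layer semantics

**Convolution.** Forward passes use *valid-mode cross-correlation* (no
kernel flip, no padding): an `H×W` map under a `K×K` kernel yields
`(H−K+1)×(W−K+1)`. Connectivity is full — every output map sees every
input map — and each output map carries a single additive bias. The
backward formulas are stated in the orientation that makes the analytic
gradient agree with central differences; a numerical oracle, not any
particular convolution idiom, is the arbiter of correctness, and the test
suite enforces agreement to 1e−6 (sigmoid) / 1e−4 (ReLU, off-kink) over
30 seeds per configuration.

**Pooling.** Non-overlapping tiles, window = stride = 2 by default,
anchored top-left; sides must divide exactly (no padding). Mean mode is
LeNet-style learned subsampling `f(β·down(x)+b)` with trainable per-map
β and b; in max mode β ≡ 1, b ≡ 0 and the activation defaults to
identity, since rescaling after a maximum is nonstandard and the mean-
mode gradient formulas (∂E/∂β = Σ δ∘down(x)) do not transfer cleanly.
Max-pool ties go to the first occurrence in row-major order, and the
winner index is cached so the backward pass routes the whole δ to that
cell. Mean-mode upsampling divides by the window area — the Jacobian of
the mean — rather than bare Kronecker expansion.

**Output head.** The head is a linear layer into a numerically stabilized
(max-logit-subtracted) two-way softmax. The default loss pairs the summed
squared error `E^N = ½ΣΣ(t−y)²` with that softmax. An elementwise
`f′(u)∘(y−t)` output delta is ill-defined for softmax, whose Jacobian is
not diagonal; the implementation uses the full form
`δ = (diag(y) − y yᵀ)(y − t)`, verified numerically. Cross-entropy
(δ = y − t) is available via `TrainConfig(loss="cross_entropy")` but off
by default.

**ReLU at the kink.** The subgradient at 0 is taken as 0 (strict
inequality in the derivative mask). Gradient checks with ReLU perturb
random continuous inputs, so exact kink hits have measure zero; the
looser 1e−4 tolerance absorbs near-kink finite-difference error.

## Training semantics

**One iteration = one full pass** over the training set, with a seeded
permutation cut into consecutive mini-batches (last batch may be short).

**Summed-batch gradients.** The update applies the gradient of the batch
loss `E^N` itself — a *sum* over the batch — not the batch mean. `E^N` is
defined as a sum, and the reference learning rate η = 0.0005 is quoted
together with batch size 200, which under sum semantics is an effective
per-sample step of 0.1, the regime where sigmoid/ReLU networks of this
size actually move. (Under mean semantics η = 0.0005 leaves the network
at chance indefinitely; we verified this empirically before fixing the
semantics.) The consequence — η and batch size trade off — is documented
in `lungcad.training`.

**Momentum.** "Gradient descent with elastic momentum" is implemented as
classical heavy-ball, `v ← m·v − η·g, θ ← θ + v`, default m = 0.9; the
description (damped oscillation, faster convergence, escapes local
minima) matches heavy-ball, and m = 0 reduces exactly to plain descent.
Per-weight learning rates η_ij are deliberately not implemented; a single
global η is used.

**Initialization.** Uniform on ±√(6/(fan_in+fan_out)) per layer, biases
zero, seeded. Any bounded zero-mean rule passes the gradient oracle; the
fan-balanced rule keeps activation variance roughly constant across
depth.

**Divergence.** A non-finite gradient or epoch loss aborts the run with
the last finite state attached to the raised exception; nothing is
silently clamped.

## The phantom generator

Normal phantoms: background 0.15, two axis-aligned elliptical lung
fields at 0.55 (centers (0.50, 0.32)/(0.50, 0.68), semi-axes
(0.30, 0.17) of the side), additive Gaussian noise σ = 0.05, clipped to
[0, 1]. Abnormal phantoms add one disc of radius uniform in 3–8 % of the
side, +0.35 intensity, centered uniformly inside a randomly chosen lung
ellipse shrunk so the disc fits entirely. The normal generator burns the
abnormal branch's random draws so a (normal, abnormal) pair with the same
seeds shares its noise field — useful for paired tests, and it makes the
zero-contrast abnormal image bitwise equal to its normal twin.

The generator reproduces the *statistical roles* the experiments need —
two balanced classes, a small bright localized lesion against global
anatomy-like context, tunable difficulty via contrast and noise — and
nothing else. It has no organ texture, no partial-volume effects, no
scanner artifacts, no inter-patient variability. Passing results
demonstrate that the framework's optimization and evaluation machinery
behave as designed, and that published *directional* findings (momentum
≥ plain GD; a two-layer network cannot exceed chance on symmetric
classes) replicate on a controlled task. They do not certify clinical
performance on real CT data, and the published absolute accuracies on the
private hospital set are out of reach by construction.

**Preprocessing.** Bilinear resize (Pillow) to the target side; optional
per-image min–max normalization to [0, 1], with constant images mapped to
zeros by fiat.

## Desk-scale experiment sizes

Experiments run at a fifth of the original scale: 400+400 training and
100+100 test phantoms at 32 px, against the original 4000/1000 at 64 px.
The reduced model is `C6@5×5 → P2 → C12@5×5 → P2 → F64 → softmax(2)`
(~25 k parameters). Two defaults differ from the full-scale baseline,
both chosen before the acceptance checks were frozen:

* **ReLU feature layers.** The activation-function experiment in the
  source material shows sigmoid needing ~150 passes to converge versus
  ~3 for ReLU; the desk-scale budget of 30 passes makes ReLU the only
  viable default. `default_config()` keeps the sigmoid baseline.
* **Batch 100.** Under summed gradients the total parameter movement per
  pass (η·N) is batch-invariant, so batch size is purely a stability
  choice; 100 (effective per-sample step 0.05) was the most stable of
  {40, 50, 100, 200} in a pilot across seeds.

With these defaults the reduced network reaches ≥ 90 % test accuracy
within 30 momentum passes at η = 0.0005 on all three tested seeds, and
momentum reaches plain GD's 15-pass loss in 3–6 passes.

## Evaluation conventions

The positive class is NORMAL (label 0), following the study's explicit
definition — the reverse of clinical convention; reports label the fields
accordingly. Undefined ratios (absent class, zero marginal) are reported
as NaN — or 0 for MCC's zero-marginal "random prediction" reading — and
always accompanied by a flag string, never silently zeroed. MCC is
computed in exact integer arithmetic before the final square root.
Published-table comparisons round half away from zero to 2 decimals,
matching the tables' formatting. The registered 32-px resolution row's
MCC recomputes to 0.48 against a printed 0.47; the verification report
carries it as a known published rounding mismatch rather than a failure.

## Known limitations

Single-threaded numpy execution (no GPU); two classes only; square
inputs only; no padding, strides, dilation, overlapping pooling, weight
decay, dropout, or learning-rate schedules. The sweep runner asserts
only directional claims that are dataset-independent; absolute
recognition rates on phantoms say nothing about CT images.
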