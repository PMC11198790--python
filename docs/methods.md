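# Methods

## The optimization model

`baoscnn` implements Atomic Orbital Search (AOS) and its Lévy-flight
boosted variant (BAOS) for minimising a black-box objective over a mixed
continuous/discrete box, and applies them to CNN hyperparameter
neuroevolution for patch-based habitat image classification.

### Candidate representation

A candidate ("electron") is a real vector of length *d*. Continuous
hyperparameters live in native units; each discrete hyperparameter is
embedded on the unit interval and decoded lazily to one of its *n*
ordered categories via

    alpha = 1 + n·R,   beta = min(floor(alpha), n),   value = K_beta,

which maps uniform R to uniform categories and clamps R = 1 onto the last
category. The optimizers move in this continuous embedding; decoding
happens only when the objective is evaluated. Boundary repair is
coordinate-wise clamping and is idempotent.

### AOS dynamics

Each iteration the population (size *m*) is sorted by energy (objective
value, lower = better) and partitioned into a uniformly random number of
concentric layers (1 to `layer_max`, default 5); layer sizes follow a
discretised standard-normal profile over the layer index, so the inner
(better) layers hold more electrons. Each layer *k* has a binding state
`BS_k` (position centroid) and binding energy `BE_k` (mean energy); the
population has global `BS`/`BE` and a best-so-far candidate `LE`.

Per electron, fresh uniform vectors α, β, γ ∈ [0,1]^d and a scalar
φ ∈ (0,1) are drawn. With photon rate `PR` (0.1 in plain AOS):

* φ ≥ PR and E_i ≥ BE_k — global pull, damped by layer depth:
  `X += α ⊙ (β·LE − γ·BS) / k`;
* φ ≥ PR and E_i < BE_k — layer-local pull using the layer's best
  candidate: `X += α ⊙ (β·LE_k − γ·BS_k)`;
* φ < PR — a small uniform walk, `X += r ⊙ span` with
  r ∈ [−0.05, 0.05]^d.

Proposals are repaired, evaluated, and accepted greedily (keep the better
of old/new). A rejected proposal increments the electron's limit counter;
a strict improvement resets it.

### The Lévy boost

BAOS modifies AOS in two ways.

1. **Photon-rate updates.** Each iteration every electron's PR is
   re-drawn as `clamp(c·|ℓ|, 0, 1)` with ℓ a Lévy(β = 1.5) step from
   Mantegna's algorithm and *c* calibrated (once, from a fixed internal
   stream) so the median PR is 0.1 — the canonical AOS interaction rate,
   now with heavy-tailed fluctuation.
2. **Stagnation restarts.** An electron whose limit counter exceeds the
   threshold (default 5) is relocated by a Lévy jump from `LE`,
   `LE + rand(d) ⊙ Lévy(β) ⊙ scale`, accepted unconditionally, replacing
   its regular move that iteration so the evaluation budget stays exactly
   m·(1 + iterations) per run.

The restart scale is landscape-adaptive, and this choice matters in
practice:

* On smooth landscapes the scale is the electron's coordinate-wise
  distance from `LE`, floored at 0.001 span — the convention of
  Lévy-flight cuckoo search. Restarts are global while the population is
  spread and anneal into local refinement as it converges; with a fixed
  absolute scale instead, endgame restarts churn the population and final
  precision on a d = 5 sphere degrades by roughly an order of magnitude.
* An exact energy tie between an electron and a rejected proposal is
  taken as evidence of a plateau — on the piecewise-constant landscape a
  discrete space induces on its embedding, within-cell refinement is
  pointless. Once an electron has seen a tie since its last strict
  improvement it restarts immediately (threshold 0) at full-span scale
  (4 spans before the Lévy/uniform factors), with the jump folded back
  into the box by reflection so that long jumps do not pile up on the
  boundary as clamping would cause. Ties cannot occur on smooth
  objectives, so this leaves continuous benchmarks untouched while
  roughly doubling the discovery rate of the global cell on small
  all-discrete spaces.

Setting the limit threshold to infinity disables restarts entirely; with
photon-rate updates also disabled, BAOS reproduces AOS trajectories
bitwise under a shared seed — a property the test suite checks.

Random draws per electron are made in a fixed order from one generator
per run; per-run seeds derive from the master seed by unit increments.
All three algorithms (AOS, BAOS, budget-matched random search) report
best-so-far traces, per-run records and exact evaluation counts.

## The Lévy module

The closed-form density is the one-sided Lévy law
`L(s; γ, μ) = sqrt(γ/2π) · exp(−γ/(2(s−μ))) · (s−μ)^(−3/2)` for s > μ
(0 otherwise), whose far tail falls as s^(−3/2). General-β step sampling
uses Mantegna's ratio `u/|v|^(1/β)` with the standard σ_u formula; the
magnitude survival function then has power-law exponent ≈ β, which the
package's estimator recovers by log–log regression over the top decade of
magnitudes (ending at the 99.9th percentile). Raw steps are clipped at
100 dimension spans before repair to keep extreme tail draws finite in
downstream arithmetic.

## CNN fitness

An assignment decodes to a blueprint: `Nc` blocks of same-padded
convolution (kernel `Ks`, `Nf` filters, ReLU) each followed by `MPs`-fold
max pooling where feasible, then flatten, dropout `Dr`, and a dense
softmax head; training is minibatch SGD with momentum (`Lr`, `Mr`, batch
`Bs`) on cross-entropy. Geometry never fails: kernels are clipped to the
current spatial extent and pooling is skipped once it would shrink a
spatial dimension below one pixel, so every point of the search space is
trainable. Gradients are clipped by global norm (5.0); without this,
learning rates at the top of the searched range occasionally throw a
fresh network onto the dead-ReLU plateau in the first minibatches, which
is a retrain-stability rather than a search problem.

Fitness is the mean held-out accuracy of stratified K-fold
cross-validation (K = 5), each fold trained with early stopping on
validation loss (patience 20) and capped at `min(Ne, epoch_cap)` epochs;
the reported fold accuracy is taken at the best-validation-loss epoch.
The best fold index is recorded alongside. Divergent training (non-finite
loss) yields fitness 0 with a flag rather than an exception. A caching
evaluator serves repeat assignments without retraining — on all-discrete
spaces converged populations revisit cells constantly. The optimizers
minimise 1 − fitness, preserving the energy vocabulary.

The tensor work is done by a compact NumPy backend (im2col convolution
over BLAS matmuls, inverted dropout, analytic backprop verified against
finite differences in the test suite). The networks searched at desk
scale are a few blocks on ≤ 32 px patches, where this is entirely
adequate on one CPU.

## Search spaces

`default_seagrass_space()` is the full nine-dimensional space of the
habitat study: conv layers 1–20, kernel 1–30, filters 1–500, epochs
1–400, batch 10–200 (step 10), pool 1–20, dropout 0.20–0.65 (step 0.05),
learning rate 0.001 then 0.006 stepping by 0.005 to 0.096 with 0.1
appended (the printed endpoint, which the raw step does not land on),
momentum 0.05–0.95 (step 0.05). Integer hyperparameters are consecutive-
integer category lists.

`desk_space()` keeps the same nine hyperparameters, ordering and
character — wide all-discrete grids in which most combinations are poor
(undertrained, underparameterised, over-regularised) and good cells must
be searched for — at sizes where every candidate trains in seconds:
conv 1–3, kernel {1,3,5,7}, filters {2,4,8}, epochs {2,4,6,8}, batch
{16,32,64}, pool {2,3}, dropout {0.2,0.35,0.5,0.65}, learning rate
{0.005,0.01,0.02,0.05,0.1}, momentum {0.05,0.3,0.6,0.9}.

## Synthetic data

The generator emulates four visually distinct habitat morphotype classes
as parametric grayscale textures: oriented sinusoidal gratings
(strap-like leaves), bright elliptical blobs on dark ground (oval
leaves), recursive branching segments (ferny stems), and low-frequency
noise with speckle (background substrate). Additive Gaussian pixel noise
(default sd 0.02 on unit intensity at desk scale) controls difficulty.
Whole images carry the class label; slicing into a rows × cols grid
(default 6 × 6, row-major, 1-based) produces patches that inherit the
parent label and tile the parent exactly. Overlay rendering tints each
grid cell with its class colour (blue/yellow/purple/maroon by default)
and emits a class → colour legend.

What the generator does *not* emulate: real underwater optics (colour
attenuation, turbidity, illumination gradients), mixed-class images,
scale variation, or label noise from the whole-image labelling protocol.
Passing tests therefore demonstrate the search and evaluation machinery
end to end on a learnable task, not field-data performance.

## Desk-scale protocol and chosen sizes

The full study protocol (population 30, 20 iterations, 10 runs, K = 5,
patience 20, 400 × 400 patches) is available via `--paper-scale` /
`paper_scale=True` but is GPU-class work. The desk profile used by the
tests and the reproduction script runs population 8 for 5 iterations
(48 evaluations), K = 5, epoch cap 15, on 240 synthetic images (60 per
class, 24 × 24 px) split 75/25 into training and held-out test. The
winning blueprint is retrained on the training split with early stopping
against a 15% validation slice, taking the better of two initialisations
by validation loss, and scored once on the test split. Benchmarks and
optimizer property checks use sphere/Rastrigin/Ackley/Rosenbrock on
their conventional boxes.

## Numerical choices and edge cases

* Sample (n − 1) standard deviation in multi-run summaries; display
  rounding to 4 decimals.
* Precision/recall/F1 defined as 0 on zero denominators; multiclass
  accuracy is trace/total (equivalent to the one-vs-rest binary formula
  at N = 2).
* Greedy acceptance uses strict improvement; exact ties leave the
  electron in place but mark the plateau flag.
* Discrete dimensions with a single category decode to that category for
  every R.
* Layer partition guarantees at least one electron per layer and caps
  the layer count at m.
* The PR calibration constant is cached per β from a fixed internal
  stream, so it does not consume user-visible randomness.

## Known limitations

* The backend is single-threaded NumPy; paper-scale blueprints (hundreds
  of filters, 400 px patches) are out of desk reach by design.
* One shared filter count/kernel/pool per network, as the space defines
  one value per hyperparameter — no per-layer schedules.
* The desk comparison between BAOS and random search is at a 48-
  evaluation budget where uniform sampling is a strong baseline on small
  spaces; the measured BAOS margin comes from exploitation within the
  good region, and narrows as the budget grows.
* An undefined auxiliary parameter update step that appears in the
  source algorithm listing ("C2") has no definition anywhere and is not
  implemented.
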