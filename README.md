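# baoscnn

Boosted Atomic Orbital Search (BAOS) — the Atomic Orbital Search
metaheuristic augmented with Lévy-flight photon-rate updates and
stagnation restarts — applied to deep neuroevolution: searching the mixed
discrete/continuous hyperparameter space of small convolutional
classifiers with stratified cross-validated accuracy as the fitness, for
patch-based benthic habitat (seagrass morphotype) image classification.

## Who this is for

Researchers working on patch-based underwater habitat mapping who want to
automate CNN architecture/hyperparameter choice without transfer
learning, and anyone studying Lévy-flight-boosted population
metaheuristics who wants a tested, seedable reference implementation of
AOS/BAOS with analytic benchmarks and a budget-matched random-search
baseline.

## The method

AOS treats candidates as electrons orbiting a nucleus. Each iteration the
population is sorted by energy *E* (the minimised objective) and split
into random concentric layers; layer *k* has binding state **BS**ₖ
(centroid) and binding energy **BE**ₖ (mean), the population has global
**BS**/**BE** and best-so-far **LE**. Per electron, with uniform draws
α, β, γ ∈ [0,1]^d and φ ∈ (0,1) against photon rate PR:

- φ ≥ PR, Eᵢ ≥ BEₖ:  X ← X + α ⊙ (β·LE − γ·BS)/k
- φ ≥ PR, Eᵢ < BEₖ:  X ← X + α ⊙ (β·LEₖ − γ·BSₖ)
- φ < PR:            X ← X + r ⊙ span,  r ∈ [−0.05, 0.05]^d

with greedy acceptance and per-electron limit counters. BAOS re-draws PR
each iteration from a scaled |Lévy(β=1.5)| step (median 0.1) and
relocates stagnant electrons by a Lévy jump from **LE** — distance-
annealed on smooth landscapes, full-span and reflection-folded once an
exact-tie plateau is detected.

Discrete hyperparameters move on a [0,1] embedding and decode through
α = 1 + n·R, β = min(⌊α⌋, n), value = K_β. CNN fitness is mean stratified
5-fold cross-validated accuracy with early stopping (patience 20); the
optimizer minimises 1 − accuracy.

See `docs/methods.md` for the full model description, parameter tables
and limitations.

## Worked example

Run a desk-scale search on the bundled synthetic four-class morphotype
dataset (240 images, 24×24 px; population 8, 5 iterations, 5-fold CV
fitness) and compare with a budget-matched random search:

```bash
baoscnn search --seed 2 --algorithm baos --out runs/demo
```

prints

```json
{
  "best_assignment": {
    "n_conv": 1,
    "kernel_size": 5,
    "n_filters": 8,
    "n_epochs": 6,
    "batch_size": 16,
    "pool_size": 2,
    "dropout": 0.35,
    "learning_rate": 0.05,
    "momentum": 0.9
  },
  "test_accuracy": 0.95
}
```

meaning: within a 48-evaluation budget the search settled on a single
wide-kernel conv block with 8 filters trained 6 epochs at learning rate
0.05, whose cross-validated fitness won the search, and which — retrained
on the full training split — classifies 95% of the 60 held-out test
patches correctly. `runs/demo/` contains the resolved config, a log with
per-run seeds and evaluation counts, the best assignment with per-run
statistics (best/worst/mean/sd), the convergence trace as CSV, and the
test metrics report (per-class precision/recall/F1 plus the confusion
matrix).

Benchmarks and data tooling:

```bash
baoscnn benchmark --name rastrigin --d 10 --seed 0   # aos vs baos vs random
baoscnn generate-data --per-class 50 --size 24 --out data/synthetic
baoscnn overlay --image img.png --labels grid.csv --out tinted.png
```

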