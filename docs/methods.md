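# Methods

## Model

The classifier is a generalized additive model over M numeric features
with labels encoded +1 (case) / −1 (control):

    y~(x) = β₀ + Σ_j f_j(x_j · g(φ_j))

* **Gates.** `g(φ) = 1` iff `σ(φ) ≥ 0.5`, equivalently `φ ≥ 0`; the tie at
  `σ = 0.5` resolves to alive. We define the gate through the `φ ≥ 0` test
  rather than a rounding routine, which avoids round-half-to-even
  ambiguity and makes the conventional init `φ = 0.05` alive. In the
  backward pass the gate behaves as the smooth sigmoid (straight-through
  estimator), so the gate logit receives gradient even though the forward
  value is a step function.
* **Shape networks.** Each `f_j` is `tanh(θ⁽³⁾ relu(θ⁽²⁾ relu(θ⁽¹⁾ z)))`
  with channel width C and **no bias terms at any layer**. Bias-freedom
  gives `f_j(0) = 0` exactly, so a dead gate nulls its feature's
  contribution identically — the additivity, nullity and (−1, 1)
  boundedness of contributions are structural identities, not
  approximations, and are tested as such.
* **Prediction.** Hard labels are `+1` iff `y~ > t` (strict), default
  `t = 0`, which is the symmetric choice for ±1 targets with bounded
  contributions. ROC/AUC sweep all thresholds, so AUC is unaffected by `t`.
* **Regression mode** keeps the identical architecture including the tanh
  (which then caps the sum of contributions at ±M — a known structural
  limitation); a `use_tanh=False` toggle exists for the ablation.

## Objective and training

    E[ L(y~, y) + λ₁ R₁ + λ₂ R₂ ],   R₁ = mean_batch Σ_j f_j(z_j)²,   R₂ = Σ_j g(φ_j)

optimized by plain SGD. Reference hyperparameters (defaults of
`TrainingConfig`): learning rate 0.01, batch size 16, 40 epochs, C = 128,
λ₁ = 1, λ₂ = 0.005, L2 weight decay 1e-3, φ init 0.05. R₁ reduces over the
batch by mean and over features by sum. R₂'s forward value is the alive
count; its backward pass is the sum of sigmoids, giving each logit a
constant pruning pressure `λ₂ σ'(φ)`. Weight decay applies to the shape
weights and intercept but **not** to φ: decaying φ would drag logits
toward the alive/dead boundary at 0 regardless of merit. Classification
training draws each epoch's row indices from an inverse-class-frequency
sampler with replacement (expected positive fraction 0.5); regression
reshuffles. No early stopping; the alive set is read at the final epoch.

Two design choices here were genuinely open and deserve their rationale:

* **Near-zero output-layer init.** Hidden layers init uniform
  ±1/√fan_in; the output layer inits uniform ±1/fan_in (= ±1/C). With a
  full-scale output init and M ≈ 100, the initial score is a sum of ~100
  random bounded terms and R₁ is of order M·E[f²]; the resulting gradient
  shock drives every gate logit below 0 within the first epoch, before
  any shape can align with the outcome — feature selection never happens.
  Starting the shapes near zero (ensemble starts at the intercept, a
  standard choice for additive networks) removes the shock; pruning then
  unfolds gradually across training, which is the intended operating
  regime.
* **Gradient routing of R₁.** ReLU networks are positively homogeneous, so
  the gate's backward-pass scale σ(φ) can be absorbed into θ⁽¹⁾: at the
  shape-weight optimum the loss is locally flat in φ, and the useful
  selection signal is the *transient* "does scaling this feature up reduce
  error" gradient. If R₁'s gradient is also routed into φ (as naive
  end-to-end autograd would), its gate component grows with the fitted
  effect size and at equilibrium cancels the error-reduction pull on
  precisely the informative features; empirically this collapses top-5
  recovery to chance-like levels. We therefore apply R₁'s gradient to the
  shape weights only. The gate logit integrates the prediction-error
  signal plus the R₂ pruning pressure; R₁ still shrinks magnitudes through
  the weights. Dead features pass no gradient to their own weights (their
  activations are identically zero), so dying freezes a shape network.

A note on the pruning horizon: R₂'s per-step pull on each logit is
`lr·λ₂·σ'(φ) ≈ 1.25e-5`, so crossing the 0.05 init requires ~4000 steps
from R₂ alone. At study scale (n = 1000, M ≈ 100) the early transient
plus the sustained error-path drift close the gap within the 40-epoch
default; on small cohorts (few features, few hundred rows) gates survive
40 epochs and pruning only appears on a longer horizon (e.g. 100 epochs).
This is a property of the operating regime, not a malfunction — the alive
count trajectory in the training history makes it visible.

## Feature selection protocol

Features are ranked by gate logit φ descending (ties: lower index first);
alive features necessarily precede dead ones. "Top-k" selection restricts
the data to the k best-ranked features and retrains from scratch with the
k gates frozen alive (φ excluded from optimization, λ₂ = 0). The
comparator ranking fits an L1-penalized linear model by coordinate
descent (soft-threshold updates on standardized columns) and ranks by
|coefficient|; when a target k is given, the penalty is bisected so at
least k coefficients are nonzero. The comparison heads (hinge-loss linear
"SVM", logistic regression, 3-layer MLP with biases and 2-way softmax)
train with the same SGD protocol, sampler and weight decay, differing
only in architecture and loss.

## Data handling

Features are z-scored with population (denominator N) statistics fitted
on the training split only; zero-variance columns get sd replaced by 1
and are flagged. Bias-free shape networks make centering material: the
shapes can only bend around 0, so the input scale/location convention is
part of the model contract. Stratified k-fold plans come from
scikit-learn's `StratifiedKFold` (shuffled, seeded) and serialize to
JSON; the cross-validation harness refits the standardizer inside every
fold. Missing cells are a hard error by default (`impute="median"`
opt-in). Any two-valued target column is accepted; the user names the
positive value.

## Synthetic cohort generator

The generator emulates the statistical shape of a mid-sized biomarker
cohort: default n = 1000 subjects, 5 informative + 94 noise columns,
22.6% positive class, right-skewed features. Columns are drawn i.i.d.
standard normal and passed through an exponential tilt
`x = (exp(a z) − e^{a²/2}) / sd` (default a = 0.5), keeping zero mean and
unit variance while skewing right. The outcome is `+1` iff
`intercept + Σ f*_j(x_j) + ε > 0`, with ε ~ N(0, 0.5²) and the intercept
bisected on the empirical latent scores to hit the target positive rate
(to the 1/n granularity; a ±1-percentage-point gate guards
unreachability). Five shape families are supported — linear, saturating,
bump, step-like, quadratic — each rescaled so its contribution has unit
empirical sd times a strength ~ U(0.8, 1.25) with random sign. The
rescaling matters: raw catalogue draws give localized kinds (bump) an
order of magnitude less latent variance than global ones, making recovery
a shape lottery rather than a test of the method. Default noise sd 0.5
against a ~√5 latent sd puts the Bayes error low but not zero.

What the generator does **not** emulate: correlated biomarkers, missing
data, measurement batch effects, label noise beyond the latent ε, and the
far weaker total signal of real depression cohorts. Passing recovery
tests therefore show the machinery works under clean additive conditions,
not that real cohorts would yield stable selections.

## Benchmarks and problem sizes

The reference experiments (`deepgam.benchmark`, used by the test suite
and `scripts/acceptance.py`) run ten replicate seeds each of: (1) the
full pipeline at study scale — train on 99 features, rank by gate,
retrain the top-5 and a random-5 control, evaluate on a held-out
stratified fold (~1 min/replicate); (2) the 2×2 (R₁, tanh) ablation and
(3) monotone shape recovery, both on a 10-feature cohort so a multi-seed
sweep stays in the minutes range. Shape recovery compares the learned
curve with the true shape by Pearson correlation after sign alignment
over the central 90% of the data mass; the sign ambiguity is inherent
(only the sum Σf_j + β₀ is identified up to per-feature offsets that
cancel, and curve polarity can trade against other features near the
decision threshold).

## Numerical choices

* AUC: trapezoid over the tie-grouped threshold sweep — equal to the
  Mann–Whitney statistic with half-credit ties to 1e−12 (tested against a
  brute-force pair count and scikit-learn).
* Zero-denominator metrics report 0 with an explicit degeneracy flag
  rather than NaN, keeping cross-fold averages well defined.
* Mean CV report is the unweighted mean over folds.
* Model archives are `.npz` (named arrays + JSON metadata with a format
  version); loads verify the version and fail cleanly on truncation.
* All randomness flows from integer seeds into `numpy.random.default_rng`;
  every pipeline is bit-reproducible for a fixed seed on a fixed machine.

## Known limitations

* Selection reads the transient SGD signal; with strongly correlated
  informative features the gate ranking can split credit arbitrarily.
* The tanh bound caps each feature's contribution at ±1 on the ±1 label
  scale; outcomes needing larger per-feature swings (regression targets
  especially) are structurally underfit.
* The hinge-loss head is a linear-kernel SVM trained by SGD, not a QP
  solver; margins are approximate.
* Single-CPU numpy implementation; training cost scales linearly in M
  with batched C×C matmuls (M = 99, C = 128, 40 epochs ≈ 1 minute).
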