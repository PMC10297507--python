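# Methods

This note documents the models, the numerical choices, and the design
decisions behind `heartrisk`, in the order data flows through the
pipeline. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Record schema and I/O

The unit of data is a 13-attribute clinical record (plus an optional
0–4 disease stage). The schema constrains six numeric attributes to
closed intervals (age 29–77, resting blood pressure 94–200 mm Hg,
cholesterol 126–564 mg/dL, maximum heart rate 71–202 bpm, ST
depression 0.0–62.0, vessel count 0–3) and seven categoricals to
enumerated levels. Two notes on fidelity to the source tables this
schema transcribes:

* The ST-depression upper bound of 62.0 is far above the conventional
  ~6.2 for this attribute; the schema follows the printed bound, and
  the generator draws uniformly across it. Values in the conventional
  range remain valid.
* Published *samples* of this data routinely violate the documented
  levels (thal codes 0/1/2, chest-pain 0, slope 0, vessel count 4).
  The packaged ten-row sample file reproduces such a sample verbatim.
  This is why validation has two modes: **lenient** (default) keeps
  out-of-range values and flags warnings; **strict** raises. The
  binary risk label is stage ≥ 1.

Files use the UCI comma-separated dialect (optional header, `?` for a
missing value); the processed Cleveland/Hungarian files are accepted
verbatim (13 or 14 columns, headerless). Reading never imputes —
missing values stay explicit until encoding, keeping I/O pure.

## Synthetic cohorts

The generator emulates scaling a few-hundred-row clinical table up to
an arbitrary cohort size with a mock-data tool, with one deliberate
difference: mock-data tools give no usable feature–label dependence,
so recovery experiments against them are unfalsifiable. Here labels
come from a latent-variable logistic model on the canonical flat
encoding (scaled numerics + one-hot categoricals, 25 features):

    y = 1  iff  w·x + b + s·ε > 0,    ε ~ standard logistic

so `noise_scale` s = 1 gives exactly P(y=1) = σ(w·x + b) and s = 0
makes the label a deterministic threshold rule — the ground truth for
the signal-recovery experiments. When a target class balance is set,
the intercept is calibrated to the empirical quantile of the latent
scores (discrete attributes leave the achieved balance a few records
off the target; the calibrated intercept is reported back).

Attribute marginals are uniform within the schema ranges/levels — the
neutral choice when the true distributions are unknown. Consequences
worth keeping in mind: synthetic cohorts have no attribute
correlations, no realistic marginal shapes, and a label mechanism of
our choosing. Passing recovery tests therefore demonstrates that the
*pipeline* can learn a known signal end to end — not that any accuracy
figure transfers to real patients.

Two signal presets exist: `default_signal()` (clinically-plausible
directions — risk up with age, blood pressure, cholesterol, ST
depression, vessel count, asymptomatic chest pain, exertional angina,
defect thal codes; down with achieved heart rate — at noise giving a
moderately hard problem) and `separable_signal()` (one strong weight
on maximum heart rate, no noise). Defect injection (exact duplicates,
`?` cells, out-of-range outliers) draws binomial counts from the
seeded RNG and returns a manifest, so cleaning can be cross-checked
defect by defect; damage is applied before duplication so duplicates
stay exact copies, and labels are never touched. Every generator is a
pure function of its configuration.

## Kalman smoothing

Vital streams are smoothed with the minimal scalar filter: random-walk
state, identity observation. Predict x̂⁻ = x̂, P⁻ = P + Q; update
K = P⁻/(P⁻+R), x̂ ← x̂⁻ + K(z − x̂⁻), P ← (1−K)P⁻. Defaults: Q = 1e-3
(slow drift), R = the series' sample variance (cheap plug-in when the
sensor noise is unknown), initial estimate = first observation,
initial variance 1. For Q = 0 the posterior variance is positive and
non-increasing; as R → 0 the gain → 1 and the filter follows the data.
No richer state model is attempted — the streams this stage sees are
univariate level signals, not waveforms.

## Encoding

Numerics are min-max scaled against the *schema* ranges (stable across
folds; fitted bounds only widen to data extremes so lenient
out-of-range values still land near [0, 1]). Categoricals are one-hot
with a trailing "other" slot for unknown levels (strict mode raises
instead). Imputation values (median/mode) are computed from whatever
records are passed to `fit_encoder` — pass the training fold only and
no test statistic can leak.

A recurrent model needs a sequence; a clinical record is not one. The
encoder feeds one attribute per time step in schema order (13 steps,
each a fixed-width vector — scalars in slot 0, one-hots padded to the
widest width), so the recurrence genuinely integrates information
across steps. A `single_step` mode presents all 25 features at once
for comparison. The per-attribute design makes the learning problem
genuinely positional — the network must discover *which step* carries
a signal — which is the harder and more honest exercise of the cell.

## Fuzzy triage

Trapezoidal low/normal/high membership functions for blood pressure
(low 94/94/100/110, normal 100/110/140/150, high 140/150/200/200) and
maximum heart rate (low 71/71/90/110, normal 100/120/160/180, high
160/180/202/202), anchored to the schema ranges and conventional
clinical bands (hypertension ≳ 140–150 mm Hg; a low maximal heart rate
is a poor chronotropic response, so *high* achieved rate maps to the
high-risk band of this rule base's source convention). The 3-level
resting ECG code is ordinal and maps crisply: 0 → low, 1 → normal,
2 → high. All breakpoints are configuration, not constants.

The rule base is intentionally shallow, mirroring a triage decision
rather than a full Mamdani controller: state = high iff the maximum
high-membership across the three variables reaches the threshold
(default 0.5); otherwise normal iff the best normal-membership is at
least the best low-membership; ties resolve high > normal > low. A
full rule-matrix mode is a possible extension point, but nothing in
the triage contract (partition + notification) needs defuzzification.
Notification is a structured log event with a deterministic sequence
number — no wall-clock timestamps in the core, so identical inputs
yield byte-identical logs.

Triage routes only high-risk records onward, yet the evaluation
protocol scores the classifier on whole cohorts; the two views are not
reconcilable from the source material, so `cross_validate` exposes
both (`with_triage` restricts to routed records; `full_cohort`, the
default, bypasses triage).

## The GRU cells

Both cells share the skeleton given in the README. Decisions where
the printed equations underdetermine the implementation:

* **Weight naming.** The update/reset equations reuse one symbol for
  the input and hidden weights, which is dimensionally impossible in
  general; each gate gets an input matrix (hidden×input) and a hidden
  matrix (hidden×hidden). No biases in the cells, matching the
  bare-matrix equations.
* **Additive candidate.** The candidate is printed as an *additive*
  function of the reset gate (W_cx x + W_cr r + W_ch h), not the
  conventional r ⊙ (U h). The default follows the printed form;
  `candidate_form="cho"` restores the conventional coupling. Both
  variants pass the same gradient check.
* **Unbounded gates.** swish is not confined to [0, 1], so (1 − z) can
  be negative and the hidden state can grow without bound. The cell is
  implemented literally; an opt-in `gate_clamp` and global
  gradient-norm clipping (5.0) are the stability guards. swish's β is
  unstated and defaults to 1 (SiLU).
* **Zero-weight identity.** swish(0) = 0 makes the all-zero modified
  cell exactly the identity on its hidden state — a useful exactness
  test, asserted in the suite.

## Network, training, and the collapse problem

Architecture: "four layers, two hidden" is read as recurrent ×2
(hidden) → dense(5, ReLU) → output(1, sigmoid). Dropout (rate 0.16)
is applied to the dense activations in train mode (inverted dropout).
Loss is binary cross-entropy (the natural choice for a sigmoid output;
unstated in the source). Adam uses β₁ = 0.9, β₂ = 0.999, ε = 1e-8
with bias correction; the learning rate is 0.018 × 0.94^epoch
(granularity of the decay is unstated; per-epoch is assumed). Batch
size 128, mini-batches reshuffled per epoch from the run seed. The
`lag = 1039` hyperparameter is carried in the config for completeness
but has no interpretation for fixed 13-step sequences and is unused.

**Initialisation.** The stated weight range is 0.1–0.2. Read as
all-positive weights, every hidden unit starts nearly identical (narrow
positive band ⇒ strongly correlated activations), and in our
experiments the recurrent stack then cannot break symmetry on the
per-attribute sequence task at any learning rate tried — training sits
at chance indefinitely. The package therefore reads the range as a
*magnitude*: |w| uniform in [0.1, 0.2] with a random sign
(`init_mode="magnitude"`, the default). The literal `positive` mode
and a `symmetric` (±0.2 uniform) diagnostic mode remain available.
Biases are not part of the stated range: the dense bias starts at +0.1
so no ReLU unit is born dead, and the output bias at 0 (an untrained
network then scores exactly 0.5).

**Collapse detection and restarts.** At learning rate 0.018, Adam
moves every parameter ≈ 0.018 per step — more than the whole init
range within one epoch. Early training can therefore close every gate
and kill every ReLU (cell candidates or the dense layer), after which
the output is constant and all upstream gradients are exactly zero:
an absorbing state. `train()` treats three symptoms as a failed
attempt — non-finite loss, output collapsed to a constant (batch std
below 1e-8), and no epoch in the trailing window of 10 beating a mean
BCE of 0.67 (≈ the ln 2 constant-predictor level) once 12 epochs have
run — and restarts from a fresh draw of the ongoing seeded RNG, at
most `max_restarts` (30) times, so a run remains a deterministic
function of (data, config, seed). If the budget is exhausted, a
non-finite loss raises; a merely-stalled run finishes its epochs and
is flagged. The sigmoid/tanh baseline collapses more often than the
swish/ReLU cell at this operating point (roughly four attempts in five
versus one in ten on the recovery task), which is why the budget is
generous; failed attempts are detected within ~a dozen epochs, so they
are cheap.

**Hidden size** is not stated by the source configuration; the default
(16) was chosen by a robustness sweep on the synthetic recovery task
(hidden sizes 8–20 all learn; 16 gave the best accuracy/stability
balance with restarts enabled).

## Evaluation

Stratified 70/30 split: train share = round(0.7 n) exactly, per-class
counts by largest remainder (each class preserved to ±1 record).
Stratified k-fold: per class, shuffled members are dealt a base share
per fold and the remainder tops up the currently smallest folds (ties
to the earliest index), so fold sizes differ by at most one and are
exactly equal when k divides n. Stratification itself is a disclosed
choice (the source protocol says only "shuffled"); it stabilises
small-fold class balance.

Metrics from the confusion table (positive class = risk): accuracy,
precision, recall, specificity, F1, and the error rate — computed as
(FP+FN)/total, identically 1 − accuracy; the identity is
property-tested. Zero-denominator ratios are reported as 0 and listed
in an `undefined` field rather than silently dropped. ROC-AUC is a
descending threshold sweep with trapezoidal area, which equals the
Mann–Whitney pairwise-ordering statistic with ties counted ½; the
brute-force pair count is kept in the tests as the independent oracle,
and scikit-learn serves as a second reference (1e-9 agreement).
Average precision is the mean of precision at each positive's rank
(stable sort; ties keep original order). "Mean average precision" for
this single-positive-class task is that class's AP, taken at face
value. Cross-validation fits the encoder and the model per fold on the
training portion only; fold models get distinct seeds (base + fold
index); aggregates are unweighted mean ± sd across folds.

## Problem sizes in the tests and acceptance script

The recovery experiments run at 2,000 records × 50 epochs (training
accuracy, and 10-fold CV), the schema/fold arithmetic at 100,000
records, gradient checks on hidden-size-3 networks with 2 records, and
Kalman checks on 2,000-step streams — sizes at which every check is
exact or statistically stable while the whole suite stays in the
minutes range. Gradient checks are run at an all-positive operating
point: central differences are only valid away from the ReLU/clamp
kinks, where the loss is differentiable.

## Known limitations

* Synthetic cohorts are uniform and uncorrelated; no claim about real
  patient data follows from the recovery results.
* The literal swish-gated cell is not numerically safe at the default
  learning rate without the restart mechanism; with gates outside
  [0, 1] the hidden state is unbounded by design.
* The per-epoch decay makes epochs beyond ~100 inert
  (0.94^100 ≈ 2e-3 of the initial rate), so the 765-epoch default
  schedule is effectively front-loaded; tests use explicit small epoch
  counts.
* The fuzzy rule base is a shallow max-of-high triage, not a full
  inference matrix; its breakpoints are defaults to be overridden per
  deployment, not clinically validated cut-offs.
* The optional loader test for the real Cleveland + Hungarian tables
  requires network access and skips without it.
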