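# Methods

## Problem setting

`weaksup` creates training data programmatically.  A user writes *labeling
functions* (LFs): heuristics λ_j that map a candidate x_i (for example, a
tagged chemical–disease mention pair in a biomedical sentence) to a vote in
{−1, +1} or abstain (∅, encoded 0 in memory and as an absent entry on
disk).  Applying n LFs to m candidates yields the sparse label matrix
Λ ∈ {−1, ∅, +1}^{m×n}.  The package's job is to synthesize Λ — noisy,
overlapping, conflicting — into probabilistic labels ỹ_i = p(y_i = +1 | Λ_i)
without any ground truth, and to train a downstream classifier on them.

## The generative label model

The joint model over a vote row λ and the latent class y ∈ {−1, +1} is a
log-linear factor model with three indicator families:

    φ_lab_j  = 1{λ_j ≠ ∅}          (propensity)
    φ_acc_j  = 1{λ_j = y}          (accuracy)
    φ_corr_jk = 1{λ_j = λ_k}       (pairwise correlation, (j,k) ∈ C)

with weights w ∈ R^{2n+|C|} and p_w(λ, y) = Z_w^{-1} exp(w·φ(λ, y)).
Weights are estimated by minimizing the negative log *marginal* likelihood
of the observed rows, Σ_y having been summed out.  The implied accuracy of
LF j is α_j = logistic(w_acc_j) (the increasing orientation: positive
weights mean better than chance).  The class posterior is closed-form,
p(y=+1|λ) = logistic(Σ_j w_acc_j λ_j), because the propensity and
correlation factors do not involve y; all-abstain rows get exactly 0.5.

The correlation indicator is taken literally, so joint abstention counts
as agreement.  There is no class-prior factor; class balance enters only
through the data.

### Two fitting routes

* **Exact enumeration** (n ≤ 10): the 2·3^n configuration table is built
  once, giving the partition function, marginal likelihood, and its exact
  gradient; L-BFGS minimizes the per-row NLL plus an L2 ridge (default
  1e-4).  This route is the oracle the stochastic route is tested against.
* **Persistent contrastive divergence** (any n): the data-side expectation
  is computed exactly (only y is latent per row, with a closed-form
  conditional); the model-side expectation is tracked by persistent Gibbs
  chains over (λ, y) (one chain per 100 rows, floor of 50; 10 burn-in
  sweeps; 2 sweeps per step).  Steps of size 1.0 are held flat for the
  first 60% of 800 epochs and then decay as 1/√t, and the returned weights
  average the final quarter of iterates to damp chain noise.  The flat
  warm-up matters: the landscape is ill-conditioned (propensity directions
  are much flatter than accuracy directions) and a decaying-from-the-start
  schedule stalls far from the optimum.

### Multimodality and canonicalization

The marginal likelihood has an exact relabeling symmetry: (w_lab, w_acc) →
(w_lab + w_acc, −w_acc) swaps the meaning of the two latent classes and
leaves the likelihood unchanged.  Fitted parameters are canonicalized to
the non-adversarial orientation (mean accuracy weight ≥ 0).  Beyond the
symmetry, the likelihood can be genuinely multimodal — most vividly when a
perfectly correlated block of chance-level LFs can be explained either as
a block of perfect voters defining the class (the global optimum of the
independence model) or at its true accuracy.  `fit_exact` therefore runs a
deterministic base start (all accuracies initialized at logit 0.7, the
better-than-chance prior) plus seeded jittered restarts and keeps the best
objective.

### The correlated-block pathology

With 10 always-voting LFs — five perfectly correlated with true accuracy
50%, five independent with accuracy 99% — the independence-assuming MLE
assigns the block ~100% and the independents ~50%: five always-agreeing
voters look like the label itself, and the genuinely excellent LFs look
like coin flips relative to it.  This is reproduced by
`simulate.correlated_block_preset` + `fit_exact` (the two quantities
`scripts/acceptance.py` reports) and is the motivating case for structure
selection.  The preset defaults to m = 10,000, large enough that the
saturation is stable to within a point or two; the configuration describes
an asymptotic claim, so any large m behaves the same.

## Correlation structure selection

Which pairs belong in C is decided from Λ alone.  The estimator maximizes
a *joint marginal pseudolikelihood*: the sum over j of the conditional
log-likelihood of LF j's votes given all other votes, under a model with
one propensity and one accuracy weight per LF and one agreement
coefficient per unordered pair, all shared across the n conditionals, with
the latent class summed out.  The objective and gradient are exact (a 3×2
table per row; no sampling).  L1 (default 0.01) penalizes only the
agreement coefficients; the pair score s_jk is the coefficient magnitude.

Design rationale:

* **A latent class channel is required.**  Conditionally independent LFs
  are strongly correlated *marginally* (they all track the truth); naive
  regressions of one LF's votes on another's would flag every accurate
  pair.  Summing out a shared class absorbs exactly the truth-mediated
  component, so agreement coefficients capture only dependence beyond the
  class.  On the reference independence regime (n=8, accuracy 0.75, 50%
  voting, m=5000) all pair scores fall below 0.1, while a duplicated
  column scores ~50× higher than any other pair.
* **The class channel must be capacity-bounded.**  Accuracy weights are
  box-constrained to |w| ≤ 5 (implied accuracy ≤ ~99.3%), encoding the
  non-degeneracy assumption that no real source is arbitrarily close to
  perfect.  Without the bound, a perfectly correlated block can
  impersonate the class and explain its own agreement exactly, zeroing
  the very coefficients the selector exists to find; with it, agreement
  of exactly 1 always leaves a residual only the correlation channel can
  absorb, and the truth-aligned parameterization becomes the global
  optimum.
* **Multi-start.**  The hijacked-class basin still attracts the default
  initialization, so the fit runs seeded jittered restarts (default 6)
  and keeps the best objective.  Everything is deterministic given the
  seed.

Thresholding the scores at ε gives a pair set C(ε), nested as ε
decreases.  Sweeping a descending grid (default: 25 log-spaced values
spanning the observed score range) records the selected-pair count per ε;
the operating point is the *elbow* — the interior grid point with the
greatest absolute count difference from its two neighbors, ties broken
toward the larger ε (the cheaper model).  ε thresholds raw coefficient
magnitudes; standardized scores would be an alternative but the raw scale
is what the L1 geometry already normalizes.

## Majority vote vs. generative model

Let f_1(λ) = Σ_j λ_j and f_w(λ) = Σ_j w_j λ_j.  The modeling advantage

    A_w = (1/m) Σ_i [1{y_i f_w > 0 ∧ y_i f_1 ≤ 0} − 1{y_i f_w ≤ 0 ∧ y_i f_1 > 0}]

is the net rate at which the weighted vote correctly overrides the
majority vote (ties count as wrong for both, so A_w equals the
sign-accuracy difference between f_w and f_1 exactly).  Two closed-form
bounds delimit the density regimes: with expected density d̄ = n·p_l and
mean accuracy ᾱ, the expected optimal advantage is at most
d̄²·ᾱ·(1−ᾱ) in the sparse regime and exp(−2·p_l·(ᾱ−½)²·d̄) in the dense
regime (both assume non-adversarial sources, ᾱ > ½; inputs at or below ½
are rejected).

The observable surrogate assumes true weights lie in [w_min, w_max] with
mean w̄ (defaults: logit of 0.55 / 0.95 / 0.75) and computes

    Ã* = (1/m) Σ_i Σ_{y=±1} 1{y f_1 ≤ 0} · Φ(λ_i, y) · σ(2 f_w̄(λ_i) y),
    Φ(λ_i, y) = 1{c_y w_max > c_{−y} w_min},

with c_y the count of class-y votes: the sigmoid-weighted share of rows a
best-case weighted vote could flip.  The strategy optimizer compares Ã*
with the advantage tolerance γ (default 0.01, one accuracy point): below
γ it emits majority-vote labels (ỹ ∈ {0, ½, 1}; ties stay at ½ rather
than silently picking a class); otherwise it runs structure selection,
fits the generative model with the selected C (exact route when n allows,
CD otherwise), and emits its marginals.  The generative branch always
includes structure selection.  Advantage quantities are fractions
internally and percentages in serialized reports.

## Synthetic data

The simulator works at the label-matrix level: y ~ class balance; LF j
votes with probability p_l_j; a cast vote equals y with probability α_j.
Blocks of perfectly correlated LFs copy the lead member's propensity and
correctness draws, so within-block agreement is exactly 1 (abstention
patterns included); with no blocks the correlated path reproduces the
independent draw bit-for-bit at the same seed.  A single seeded generator
drives each simulation and is echoed in the output for provenance.  Two
presets encode the reference regimes: the density sweep (m=1000, balanced,
all accuracies 0.75, 10% voting — dispersion around the mean accuracy is
not modeled) and the correlated-block pathology above.  Gaussian features
with a calibrated Bayes accuracy (class means ±μ, ‖μ‖ = Φ⁻¹(target))
support the discriminative-generalization checks.

What the simulations do not emulate: real LF error structure is neither
conditionally independent nor perfectly correlated, abstention is usually
correlated with difficulty, and class balance is rarely exact.  Passing
tests demonstrate the estimators' correctness under the stated generative
regimes, not end-task performance on real corpora.

## Noise-aware discriminative training

The expected logistic loss under soft targets, Σ_i [ỹ_i·l(s_i,+1) +
(1−ỹ_i)·l(s_i,−1)], is computed exactly by the two-term expansion (never
by sampling) and reduces to the supervised loss bit-for-bit on hard
targets.  The reference model is an L2-regularized linear classifier
(default 1e-4, intercept unpenalized) fit by full-batch L-BFGS with an
analytic gradient — deterministic without any seed.  A linear model is the
reference implementation deliberately: the contract under test is the
loss, not the architecture.  Generalization beyond the LFs is measured as
accuracy restricted to rows where every LF abstained.

## Numerical choices and degenerate inputs

* Abstain = 0 in memory, absent on disk (MatrixMarket + id sidecars, or
  long-form TSV); stored zeros are eliminated on construction.
* Offsets are 0-based half-open; candidate ids derive from sentence id and
  span offsets, so extraction is rerun-stable.
* LF application is pure; the lenient error policy converts LF exceptions
  to logged abstentions, strict mode aborts with the candidate id.
* Exact-mode limit n ≤ 10 (≈1.2e5 configurations); larger models must use
  the CD route, and the error says so.
* Empty matrices are validation errors everywhere; all-abstain rows
  produce ỹ = 0.5; ties under majority vote produce ỹ = 0.5.
* Model files are versioned JSON; float round-trips are bit-exact.

## Problem sizes

The test suite runs the full pipelines at m between 1,500 and 10,000 and
n between 2 and 100 (density sweep), 20 seeds for the frequency-style
claims — sizes at which every stochastic tolerance above was calibrated
against the exact oracle rather than tuned to outcomes.

## Known limitations

* Binary classes only; no multi-class latent variable, no continuous LF
  outputs.
* Pairwise correlation factors only — no triplet or higher-order
  structure, no "fixing/reinforcing" factor types.
* The structure estimator's capacity bound is an assumption, not a fitted
  quantity; sources genuinely more accurate than ~99.3% would leak small
  spurious pair scores.
* The pseudolikelihood selector is a reconstruction faithful to the
  published usage (scores thresholded at ε, elbow rule) rather than a
  re-derivation of the original estimator's theory.
* No distributed execution; LF application is a simple in-process loop.
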