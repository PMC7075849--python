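# weaksup

Training-data creation from programmatic weak supervision, for teams that
can write heuristics but cannot afford hand labels — biomedical text
mining being the motivating case (e.g. labeling candidate chemical–disease
relation mentions with pattern rules, distant-supervision dictionaries, or
crowd votes).

Users write *labeling functions* (LFs): black-box heuristics
λ_j : candidate → {−1, +1, ∅} where ∅ means abstain.  Applied to m
unlabeled candidates, n LFs yield a sparse label matrix Λ.  `weaksup`
then:

1. **models the LFs' unknown accuracies and correlations without ground
   truth**, via a log-linear generative model over (Λ, y) with a latent
   binary class and indicator factors for labeling propensity
   1{λ_j ≠ ∅}, accuracy 1{λ_j = y}, and pairwise correlation
   1{λ_j = λ_k} for a selected pair set C.  Fitting minimizes the
   negative log marginal likelihood, either by exact enumeration (n ≤ 10)
   or by SGD with persistent Gibbs chains; the implied accuracy of LF j
   is logistic(w_acc_j);
2. **selects C automatically** with an L1-penalized marginal
   pseudolikelihood (latent class summed out), sweeping the selection
   threshold ε and picking the elbow of the selected-pair count curve;
3. **decides whether modeling is worth it**: the modeling advantage
   A_w — the net rate at which an accuracy-weighted vote correctly
   overrides the unweighted majority vote — is bounded above by the
   observable surrogate Ã*(Λ); when Ã* falls below a tolerance γ the
   optimizer skips fitting and emits majority-vote labels;
4. **emits probabilistic labels** ỹ_i = p(y_i = +1 | Λ_i) and trains a
   **noise-aware** linear classifier on them by the exact expected
   logistic loss, which generalizes to candidates every LF abstained on.

The estimators follow scikit-learn conventions (`LabelModel`,
`CorrelationSelector`, `StrategyOptimizer`,
`NoiseAwareLogisticRegression`: `fit` / `predict_proba` / `get_params`),
with plain functions (`fit_exact`, `fit_cd`, `predicted_advantage`, …)
underneath, plus a `weaksup` CLI.

## Worked example: when correlated sources fool the model

Ten always-voting LFs on a balanced binary task: LFs 0–4 are perfectly
correlated copies of one chance-level vote (true accuracy 50%), LFs 5–9
are independent and excellent (99%).  The independence-assuming fit gets
this exactly backwards — five always-agreeing voters look like the label
itself:

```
$ weaksup simulate --preset correlated-block --m 10000 --seed 1 \
    --out block.mtx --truth block_truth.tsv
wrote 10000x10 simulated matrix to block.mtx

$ weaksup fit --matrix block.mtx --mode exact --seed 1 --out naive.json
fit (exact) done; estimated accuracies: [0.999, 0.999, 0.999, 0.999, 0.999,
                                         0.495, 0.493, 0.493, 0.493, 0.494]
```

The correlated block is estimated at ~100%, the 99%-accurate independents
at ~50%.  Structure selection finds exactly the ten within-block pairs
from the votes alone:

```
$ weaksup structure --matrix block.mtx --seed 1 --out structure.json
selected 10 pairs at epsilon=1.011
```

and refitting with those pairs in the model repairs the estimates:

```python
from weaksup import LabelMatrix, DependencySet, FitConfig, fit_exact
import json

L = LabelMatrix.from_mtx("block.mtx")
pairs = json.loads(open("structure.json").read())["pairs"]
params = fit_exact(L, deps=DependencySet(tuple(map(tuple, pairs))),
                   config=FitConfig(seed=1))
print(", ".join(f"{a:.3f}" for a in params.accuracies()))
# 0.499, 0.499, 0.499, 0.499, 0.499, 0.991, 0.990, 0.990, 0.991, 0.989
```

The strategy optimizer (`weaksup analyze` / `weaksup auto-label`) reports
label density 10.0 and a predicted advantage of 48.4% for this matrix —
far above the default γ = 1% — so it chooses the generative model (`GM`)
rather than majority vote.

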