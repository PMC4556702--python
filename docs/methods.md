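# Methods

## Model and procedure

`banditsel` treats feature selection as the approximate solution of a
zero-sum matrix game.  The pure strategies of the "selector" player are
candidate feature subsets; the environment plays data splits.  A mixed
strategy — a probability vector over the K subsets — is learned online by
EXP3 (exponential-weights exploration/exploitation): each round draws a
subset from the current mixture, scores it by the test accuracy of a
classifier fitted on that subset under a fresh stratified train/test split,
and applies the importance-weighted exponential update to the drawn arm only.
Because the reward estimate r/x is unbiased for every arm, the log-weights
concentrate around t·(mean reward), and arms whose mean reward trails the
best by Δ are suppressed by a factor ≈ exp((γ/K)·t·Δ).

Sparsity is imposed afterwards by the elimination rule x_i' = 0 for
x_i ≤ t^α/t with α ∈ (0, 1), survivors renormalised.  The threshold decays
with the round count, so any strategy whose probability stays bounded away
from zero eventually survives while transient exploration mass is pruned.
On explicit payoff matrices the same rule is applied to both players of an
EXP3 self-play loop, and an LP solver (scipy's HiGHS) provides exact
equilibria as the reference; exploitability — the larger of the two players'
best-response gains — certifies approximation quality and is zero exactly at
a Nash equilibrium.

## Equilibrium estimate: averaged vs final iterate

For *self-play* the package returns the time-average of the played
distributions by default.  The last iterate of exponential-weights dynamics
does not converge at interior equilibria — it cycles, and measurably so: on
matching pennies at 20 000 iterations the final-round pair has exploitability
0.3–1.0 depending on the seed, while the averaged pair reaches 0.006–0.023,
in line with the classical guarantee that average no-regret play approaches
the equilibrium.  `average=False` restores the final-round estimate.  For
*single-learner ranking* the rewards are stationary, the final distribution
converges, and the final round is the default (averaging is available).

Tie handling at the threshold: entries exactly equal to t^α/t are zeroed by
default; `keep_equal=True` keeps them (the two conventions differ only on
exact ties).  If every entry falls below the threshold, the single largest
entry is kept with probability one — a purification-style fallback, since a
player must always retain a playable strategy; ties resolve to the lowest
index.

## Stability statistics

For ω selected sets with total size Ω over a universe of m features, CW =
(Σ_f F_f² − Ω)/(Ω(ω−1)) is monotone in Σ F_f² under Σ F_f = Ω, 0 ≤ F_f ≤ ω,
and any count vector satisfying those constraints is realisable as an actual
collection.  The extremes therefore have closed forms — counts spread as
evenly as possible over the universe (minimum) or concentrated on ⌊Ω/ω⌋
features at full count ω plus a remainder (maximum) — and CW_rel =
(CW − CWmin)/(CWmax − CWmin).  The closed forms are gate-checked against an
exhaustive enumeration of all collections for small universes in the test
suite.  Conventions: a pair of empty sets counts as fully similar in
I-overlap and one empty set as fully dissimilar; CW is undefined (error) for
all-empty collections; when CWmax = CWmin the relative statistic carries no
information and NaN is returned with a warning.

Functional stability maps each selected set to the set of *distinct*
categories its features hit before computing the statistics.  Deduplication
is deliberate: functional redundancy is the premise, and hitting a category
twice is not more stable.  Note that CW_rel's normalisation discounts
forced overlap, so with very few categories the functional CW_rel can be
*lower* than the feature-level one (or undefined when every run covers all
categories) even when selections are functionally identical; the
functional-redundancy phenomenon is therefore best read from I-overlap or
raw CW at the category level, and the tests check it that way.

## Synthetic designs

**Small-n-large-p.**  n = 10 observations, p = 100 features; class ±1 drawn
from N(±μ^0.9, I).  The base mean vector μ is not part of the published
design; the default draws it once as Uniform(0, 1) with a seed stored in the
configuration, so all replicates share one data-generating distribution and
every feature carries weak, heterogeneous signal (a sparse-signal preset
with k informative features is also provided).  The stability study keeps
the 50 candidate subsets fixed across the 200 Monte-Carlo replicates: the
candidates are part of the study design, and resampling them per replicate
caps every subset-based method's cross-replicate stability near the
random-selection level (an oracle that always picks the truly best subset
then scores CW_rel ≈ 0.06).  `resample_subsets_per_rep=True` switches to
per-replicate menus.

**Functional categories.**  Three categories × three features; each category
has a latent standard-normal covariate and its features are copies with
N(0, 0.01²) perturbations; labels are Bernoulli with logit θ*ᵀx over one
representative feature per category, so a logistic regression on one
representative per category is exactly well-specified.  Unstated design
quantities were fixed once to realise the regime this design is meant to
exhibit — clean separation between category-covering and category-missing
subsets: θ* = (2.0, −2.4, 2.8), n = 200 samples, T = 5000 bandit rounds,
α = 0.75.  At materially weaker signal or smaller n the accuracy gap between
optimal and near-optimal subsets (≈ 0.10) falls below what the concentration
factor (γ/K)·T·Δ can resolve, and maximum-likelihood noise blurs the
coefficient-error separation.  Subsets 4–15 split evenly between
single-category (two categories missing) and two-category (one missing)
draws, with within-subset repeats allowed.

What these generators do *not* emulate: real omics marginals (counts,
intensities, heavy tails), correlated feature blocks beyond the exact
redundancy structure, batch effects, or label noise beyond the logistic
model.  Passing tests show the machinery behaves as designed under its own
assumptions, not that selections on real cohorts will be stable.

## Tunable parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| γ schedule | exploration rate | 1/log(t+1), capped at 1 | constant γ ∈ (0,1] also supported |
| α | threshold exponent | 0.75 | support-recovery value; 0.27 is the CLI default for real-data ranking with T = 3000 (threshold ≈ 0.0029) |
| split_fraction | train share per reward draw | 0.5 | stratified; symmetric split maximises test signal at n = 10 |
| ridge | L2 penalty of the reward classifier | 1.0 | keeps p ≥ n fits well-posed |
| t-test variant | Welch (unequal variances) | — | pooled option available |

## Numerical choices

EXP3 weights are stored as logarithms and rebased only when the leading
log-weight exceeds 500, so long runs cannot overflow while short traces keep
exact weight values.  Probabilities are computed softmax-style from centred
log-weights.  The reward classifier is an in-package ridge-penalised
logistic regression fitted by IRLS (unpenalised intercept, 30 Newton
iterations, step tolerance 1e-8, Hessian jitter 1e-12); it matches
scikit-learn's LogisticRegression to 2e-4 on the same penalty and costs
~0.1–0.3 ms per fit, which is what makes million-evaluation studies
feasible; any sklearn-style estimator can be substituted.  LP equilibria
clean entries below 1e-9 and renormalise.  Rewards outside [0, 1] raise —
they are never clipped silently.

## Problem sizes

The bundled studies run at the sizes used throughout the documentation: the
stability study at 200 replicates (acceptance script; 50-replicate scaled
version in the test suite with a correspondingly wider comparison band), the
functional study at 50 test replicates, game solving at 20 000 self-play
iterations.  All are deterministic given their seed; Monte-Carlo replicates
derive per-replicate seeds from the master seed by counter, independent of
execution order.

## Known limitations

* EXP3 concentration at K = 50 arms and T = 2000 rounds resolves only large
  reward gaps; rankings on weak-signal data (n = 10) are reproducible but
  remain noisy, and the final distribution stays close to uniform — the
  reported stability of the unthresholded ranking reflects that.
* CW_rel is undefined for fully constrained collections (CWmin = CWmax) and
  is returned as flagged NaN.
* Only binary labels are supported; multi-class outcomes, survival
  endpoints, and sparse-SVM comparators are out of scope.
* The planted-support game constructor covers support sizes 1–3.
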