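# banditsel

Stable functional feature selection via thresholding bandits and sparse
zero-sum games.

## The problem

In omics biomarker studies the number of features *p* (genes, metagenomic
counts, clinical variables) dwarfs the number of samples *n*, and features are
organised in hidden functional categories of near-interchangeable members.
Re-running a feature selector on a new cohort then returns a different gene
list — yet often the *same biology*: low feature-level stability can coexist
with high functional stability.  `banditsel` implements a selection framework
that embraces this structure, plus the statistics to measure stability at both
levels.

## The method

Feature selection is cast as a two-player zero-sum matrix game.  Candidate
feature *subsets* are the pure strategies; a mixed strategy is a probability
distribution *x* over them.  The distribution is learned by the **EXP3**
adversarial bandit: at round *t* the arm (subset) *i* is played with

    x_i(t) = (1 - γ) w_i / Σ_j w_j + γ/K,

the drawn subset is scored by the test accuracy of a classifier fitted on its
columns under a fresh train/test split, and the importance-weighted reward
r̂ = r / x_i updates only the drawn arm: w_i ← w_i · exp(γ r̂ / K).  Sparsity is
then induced by the **thresholding rule**

    x_i' = 0  whenever  x_i ≤ t^α / t,     α ∈ (0, 1),

followed by renormalisation.  For games with a unique Nash equilibrium of
support k′ and α = 3/4, thresholded no-regret play recovers exactly the
equilibrium support for *t* large; the same machinery solves explicit payoff
matrices via EXP3 self-play, with an LP solver as the exact reference.

Stability of repeated selections S_1..S_ω over a universe 𝓕 is quantified by

* **I-overlap** — mean pairwise |S_i ∩ S_j| / |S_i ∪ S_j|;
* **CW** — Σ_f (F_f/Ω)·(F_f−1)/(ω−1), with F_f the selection count of
  feature f and Ω = Σ|S_i|;
* **CW_rel** — CW rescaled by its exact minimum/maximum over collections with
  the same (Ω, ω, |𝓕|), removing subset-size bias;

each computable at the feature level or, through a feature→category map
(e.g. GO terms), at the functional level.

## Worked example

`examples/functional_study.py` runs ten Monte-Carlo replicates of the
functional-category design: 9 features in 3 categories of redundant copies,
labels from a well-specified logistic model, and 15 candidate 3-feature
subsets of which only the first three cover every category:

```
mean probability per subset (first 3 are the optimal ones):
[0.191 0.248 0.326 0.008 0.016 0.011 0.009 0.009 0.008 0.017 0.014 0.019
 0.043 0.062 0.019]
mean coefficient error ||theta* - theta_hat|| per subset:
[ 1.04  1.03  1.03  7.6  11.23 11.77  9.66  9.68 11.9  12.72  8.98  7.76
 10.39  9.63  8.59]
{
  "median_optimal_mass_raw": 0.783,
  "median_optimal_mass_thresholded": 1.0,
  "error_separation_rate": 0.8
}
```

The bandit piles its probability mass on the three category-covering subsets
(~0.77 of raw mass; after thresholding the surviving distribution lives on
them entirely in the median replicate), and logistic fits on those subsets
recover the true coefficients (error ≈ 1) while subsets missing a category
cannot (errors ≥ 7).

Other entry points: `examples/solve_game.py` (LP vs. EXP3 game solving,
planted-support recovery), `examples/rank_subsets.py` (ranking random subsets
on small-n-large-p data), `examples/stability_measures.py` (feature vs.
functional stability), `examples/smallnp_study.py` (scaled stability study),
and a CLI:

```sh
banditsel solve-game --matrix M.csv --iterations 20000 --alpha 0.75 --seed 1
banditsel rank --table data.csv --label-col class --n-subsets 100 \
    --subset-size 30 --iterations 3000 --alpha 0.27 --seed 7
banditsel stability runs/*.json --categories go_map.tsv
banditsel experiment smallnp --reps 200 --seed 1
```

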