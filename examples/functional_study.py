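"""Scaled-down run of the functional-category ranking study.

Ten Monte-Carlo replicates of the redundant-category design: 9 features in 3
categories of interchangeable copies, labels from a well-specified logistic
model, 15 candidate 3-feature subsets of which only the first three cover all
categories.  The bandit should concentrate its probability mass on those
three, and logistic fits on them should recover the true coefficients while
the others cannot.
"""

import json

import numpy as np

from banditsel import FunctionalConfig, run_functional_experiment

result = run_functional_experiment(FunctionalConfig(reps=10), seed=1)

print("mean probability per subset (first 3 are the optimal ones):")
print(np.round(result.probs.mean(axis=0), 3))
print("mean coefficient error ||theta* - theta_hat|| per subset:")
print(np.round(result.errors.mean(axis=0), 2))
print(json.dumps({k: round(v, 3) for k, v in result.summary().items()
                  if isinstance(v, float)}, indent=2))
print("(median_optimal_mass_thresholded near 1 means the pruned distribution")
print(" lives on the category-covering subsets; their errors stay small while")
print(" category-missing subsets keep errors bounded away from zero)")
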