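"""Evaluate DEG rankings against prior gene sets with pooled scaled ranks.

Simulates 6 'experiments' whose rankings place their prior genes early
(a method that works) and 6 whose rankings are random (a method that does
not), then prints the deviation-from-uniform summary for each.
"""

import numpy as np

from chardir import ExperimentRanking, evaluate_rankings

rng = np.random.default_rng(3)
p, n_prior = 500, 40


def make(informative):
    rankings, priors = [], {}
    for j in range(6):
        prior = rng.choice(p, n_prior, replace=False)
        if informative:  # prior genes drawn towards the top of the list
            score = rng.uniform(size=p)
            score[prior] += 0.5
            order = np.argsort(-score)
        else:
            order = rng.permutation(p)
        rankings.append(ExperimentRanking(f"e{j}", [f"g{i}" for i in order]))
        priors[f"e{j}"] = {f"g{i}" for i in prior}
    return rankings, priors


for label, informative in [("informative method", True),
                           ("uninformative method", False)]:
    curve = evaluate_rankings(*make(informative))
    print(f"{label}: pooled n={len(curve.pooled)}, phi={curve.phi:.4f}, "
          f"sup(D(r)-r)={curve.sup_deviation:+.3f} "
          f"({curve.sup_deviation / curve.phi:+.1f} phi), "
          f"mean AUC={np.mean(list(curve.aucs.values())):.3f}")
# Deviations many times phi indicate genuine prioritization of the prior
# genes; an uninformative ranking stays within ~1 phi of uniform and its
# per-experiment AUCs hover around 0.5.
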