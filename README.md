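# chardir

Multivariate differential gene expression via the **characteristic
direction**: the unit normal to the separating hyperplane of a regularized
linear discriminant analysis between two classes of expression profiles
(control vs. perturbed).  Genes do not vary independently, and a
perturbation that is invisible gene-by-gene can still separate the classes
cleanly along a single direction in expression space.  `chardir` estimates
that direction, turns it into a gene ranking and a thresholded DEG set,
extends it to gene-set enrichment through principal angles, and provides
the rank-pooling statistics needed to compare any DEG-calling methods
against prior-knowledge gene sets.

It is a library first (the functions below), with a thin `chardir` command
for shell use and short narrative scripts under `examples/`.

## The statistic

For expression profiles with p genes and two classes with means μ₁, μ₂ and
pooled within-class covariance Σ̂, the direction is

    b ∝ Σ̂γ⁻¹ (μ₂ − μ₁),      Σ̂γ = γ Σ̂ + (1 − γ) σ² I,   γ ∈ [0, 1],

normalized so that Σᵢ b̂ᵢ² = 1.  Each squared component b̂ᵢ² is that gene's
share of the total differential expression; the sign of b̂ᵢ is the sign of
the gene's contribution (positive = up in the perturbed class).  Because
p ≫ N, the inverse is taken exactly inside the ≤ N−1-dimensional subspace
spanned by the centered samples and the mean difference — no p×p matrix is
ever formed.  At γ = 0 the statistic reduces to the normalized mean
difference; at γ = 1 (the default) the unshrunk covariance is inverted by
pseudo-inverse.

Significance thresholds come from a simulated null: class means are
redrawn from a multivariate t distribution (N−1 degrees of freedom, scale
Σ̂γ/N), pushed through the same inverse, and the mean sorted squared null
components ⟨b²_null⟩ over 100 repetitions form a reference curve.  Genes
are accepted either where sorted b̂²/⟨b²_null⟩ > 1 (conservative) or up to
the peak of the perpendicular distance s between the cumulative ratio
share and the diagonal (s-peak); the peak height flags whether there is
any differential expression at all.

A gene set S defines a coordinate subspace; its first principal angle θ
with the direction satisfies cos²θ = Σ_{i∈S} b̂ᵢ², which under an isotropic
null follows Beta(k/2, (p−k)/2) — an analytic enrichment p-value,
Benjamini–Hochberg-adjusted across a GMT library.

## Worked example

```python
from chardir import (SyntheticSpec, generate_two_class, as_two_class,
                     characteristic_direction, null_component_curve, call_degs)

spec = SyntheticSpec(p=300, n_d=60, D=5, N=10, delta=0.3, seed=7)
X, design = as_two_class(generate_two_class(spec))
direction = characteristic_direction(X, design)          # gamma = 1
null = null_component_curve(X, design, reps=100, seed=7)
result = call_degs(direction, null, mode="s_peak")
```

Running `python examples/01_direction_and_deg_calling.py` (the same
computation) prints:

```
subspace dimension used: 5
top 5 genes by squared component: ['gene239', 'gene138', 'gene206', 'gene80', 'gene31']
s-peak height: 0.468  (significant: True)
s-peak cutoff position: 49  (true DEG count: 60)
called DEGs: 49, of which truly differential: 49
conservative (ratio > 1) set size: 29
```

The s-peak height (0.468, a sizable fraction of unity) says the dataset
carries real differential expression; the peak position (49) estimates the
number of genes carrying it, close to the 60 planted DEGs, and all 49
called genes are true positives here.  `examples/02_synthetic_benchmark.py`
repeats the ranking comparison at 2,000 genes / 400 DEGs / 10 samples per
class and prints mean ROC AUCs of 0.929 for the characteristic direction
against 0.667 (Welch t) and 0.653 (absolute mean difference).

The other examples demonstrate principal-angle enrichment with the Beta
null (`03`) and the pooled-rank evaluation statistics with the φ = 1/√n
fluctuation scale (`04`).

## Command line

```sh
chardir simulate --p 2000 --n-d 400 --n 10 --delta 0.3 --seed 1 --out-prefix sim
chardir call --input sim_expression.tsv --design sim_design.tsv --seed 1 --out degs.csv
chardir enrich --input sim_expression.tsv --design sim_design.tsv --gmt sets.gmt --out enrich.csv
chardir evaluate --ranking exp1.tsv --ranking exp2.tsv --gmt priors.gmt --out-prefix eval
```

Inputs are tab-delimited genes × samples matrices (or GCT 1.2), GMT
gene-set libraries, and two-column ranked lists; every output starts with
a `#` header block recording the version, seed, γ and input checksums so
the run can be reproduced from the file alone.

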