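# omiclust

Multi-omic cancer subtype discovery by multiple-kernel similarity
learning.

Tumors of one cancer type differ widely in outcome, and no single
molecular readout captures why: copy-number changes matter mostly when
they move expression, point mutations are invisible to expression
panels, and methylation changes can mimic either. `omiclust` integrates
four patient × gene matrices — somatic point mutations (binary),
copy-number alterations (log2 tumor/normal ratios), promoter methylation
(beta-values) and expression (z-scores) — into a single patient-by-patient
similarity matrix, clusters patients on it, and tests whether the
resulting subtypes separate survival and which gene-level alterations
define each subtype. It is aimed at computational biologists working
with TCGA-style cohort exports.

## The model

Each data type *d* contributes a bank of 55 Gaussian kernels with
locally scaled bandwidths,

```
K(x_i, x_j) = exp(-||x_i - x_j||² / (2 ε_ij²)) / (ε_ij √(2π)),
ε_ij = σ (μ_i + μ_j) / 2,
```

where `μ_i` is the mean distance from patient *i* to its *k* nearest
neighbors and the 11 × 5 grid over *k* ∈ {10, 12, …, 30} and σ ∈
{1.0, 1.25, 1.5, 1.75, 2.0} spans complementary views of the data. The
similarity `S` (rows on the probability simplex), kernel weights `w`
(on the simplex) and a low-rank factor `L` (orthonormal, N × C) are
learned jointly by minimizing

```
- Σ_{ijl} w_l K_l(x_i, x_j) S_ij + β ||S||²_F
+ γ tr(Lᵀ(I_N - S)L) + ρ Σ_l w_l log w_l
```

by coordinate descent: exact simplex projection for the rows of `S`,
eigenvectors of the Laplacian `I - S` for `L` (Ky Fan), and a softmax of
kernel–similarity alignments for `w`. A kNN-graph diffusion step between
updates sharpens the C-block structure. The number of clusters is chosen
by scanning candidate counts `C` and minimizing, over Givens rotations
`R`, the separation cost

```
J(R) = Σ_ij Z_ij² / max_j Z_ij²,   Z = X R,
```

with `X` the top Laplacian eigenvectors; `J ≥ N`, with equality when
every patient loads on a single rotated eigenvector, and the largest
drop in `J` across candidates selects `C`. Subtypes are assigned by
k-means on the spectral embedding, and evaluated by silhouette,
k-means stability (NMI), Kaplan–Meier/log-rank survival separation, and
per-cluster hypergeometric enrichment of discretized alterations
(gain/loss at ±1, over/under-expression at z ±1, hyper/hypo-methylation
at beta 0.75/0.25) with BH correction and a 2/3-in vs <1/3-out
representativeness filter.

## Worked example

Simulate a 60-patient cohort with three planted subtypes and run the
full pipeline with automatic cluster-number selection:

```
$ python -c "
from omiclust.simulate import SyntheticSpec, generate, write_cohort
spec = SyntheticSpec(n_samples=60, c_true=3, proportions=(0.4, 0.35, 0.25),
                     genes_per_type={'mutation': 60, 'cna': 60,
                                     'methylation': 60, 'expression': 60},
                     seed=0)
write_cohort(generate(spec), 'demo')"

$ omiclust run --mutation demo/mutations.maf --cna demo/cna.tsv \
    --methylation demo/methylation.tsv --expression demo/expression.tsv \
    --clinical demo/clinical.tsv --clusters auto --seed 0 --out demo/results
clusters: 3
silhouette_mean: 0.8798
stability_nmi: 1.0000
logrank_p: 5.726e-06
```

The scan selected the planted three subtypes (`scan.json` records the
separation-cost curve), the clusters are compact and perfectly stable
(silhouette 0.88, stability 1.0), and the planted cluster-dependent
hazards produce a strongly significant log-rank separation (p ≈ 6e-6).
`demo/results/` also holds the learned similarity matrix, per-kernel
weights, per-patient labels, Kaplan–Meier step tables and the
enrichment table, with a checksum MANIFEST for reproducibility; the
same analyses are available programmatically via
`omiclust.subtype_pipeline`.

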