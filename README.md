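# ancestryx

Gene–ancestry interaction testing for multi-cohort GWAS.

When case-control GWAS data come from two or more closely related
populations, a variant's effect may differ between genetic backgrounds —
and a conventional pooled analysis will average such an effect away,
while a per-cohort analysis confounds it with collection artefacts
(ascertainment, genotyping batch, geography). `ancestryx` implements a
test that separates the two: individuals are re-grouped into empirical
**ancestry groups** by clustering on the leading principal components of
the genotype matrix, and each marker is tested for *heterogeneous*
association across those groups, with the same test repeated on the
original **collection groups** as a foil. It is aimed at analysts who
already hold multi-cohort GWAS genotypes and want to screen them for
ancestry-specific effects.

## The statistics

For a marker with dosage $x_i \in \{0,1,2\}$ and a hard clustering
$z_{ic}$ of samples into $K$ groups, two nested GLMs are compared
(logit link for case-control, identity for quantitative traits):

- heterogeneous: $g(\mathbb{E}[y_i]) = \sum_c z_{ic}\,\alpha_c + \sum_c z_{ic}\,\beta_c x_i + w_i^\top\gamma$
- null: $g(\mathbb{E}[y_i]) = \sum_c z_{ic}\,\alpha_c + \beta x_i + w_i^\top\gamma$

The null keeps cluster-specific intercepts (different background disease
rates) but a single shared genetic effect. Evidence of heterogeneity is
the BIC difference

$$T = \mathrm{BIC}_{\text{null}} - \mathrm{BIC}_{\text{het}},$$

and computing $T$ under the ancestry clustering ($T_{anc}$) and the
collection clustering ($T_{coll}$) gives the difference statistic

$$D = T_{anc} - T_{coll}.$$

Positive $D$ means ancestry explains the heterogeneity better than
collection; negative $D$ flags a collection artefact. $D$ has no
closed-form null distribution, so significance thresholds are calibrated
by retrospective simulation: the observed phenotype, covariates, and
clusterings are held fixed while null genotypes are drawn in
Hardy–Weinberg proportions over a MAF grid (0.05–0.50), and the
threshold is the 99th centile of the pooled null $D$ sample. Candidates
pass the $D$ filter, are ranked by $T_{anc}$, and (with two discovery
phases) must show consistent effect directions. Replication cohorts
without genome-wide data use the collection label as a noisy ancestry
proxy; the accompanying switch-rate power analysis quantifies the power
lost to that label noise.

A bundled generator (`ancestryx.synthgen`) simulates the whole design —
Balding–Nichols-differentiated populations, ascertained case-control
sampling, ancestry-specific odds ratios, and collection labels that
disagree with true ancestry at a configured rate — so every stage is
testable with known truth.

## Worked example

```python
import numpy as np
import ancestryx as ax

# two overlapping populations, one marker with an ancestry-specific effect
cfg = ax.SimConfig(
    n_per_population=(2000, 2000), n_markers=3000, fst=0.01,
    causal=(ax.CausalMarker(42, (0.7, 1.0), maf=0.3),),
    label_switch_rate=0.2, seed=11,
)
ds, truth = ax.simulate_dataset(cfg)

kept = ax.prune_markers(ds)                       # LD pruning (r2 < 0.2)
basis, scores = ax.fit_pca(ds, kept, n_components=2)
anc = ax.cluster_ancestry(scores, k_min=2, k_max=6, seed=0)
coll = ax.collection_clustering(ds)
print(f"selected K = {anc.K}; ancestry vs collection switch rate = "
      f"{ax.switch_rate(anc, coll):.3f}")

res = ax.snp_test(ds, "m00042", anc, coll, W=ds.W)
print(f"T_anc = {res.t_anc:.2f}, T_coll = {res.t_coll:.2f}, D = {res.d:.2f}")
print("per-ancestry-cluster OR:", np.round(res.or_anc, 3))
```

Output:

```
selected K = 2; ancestry vs collection switch rate = 0.194
T_anc = 4.62, T_coll = -0.80, D = 5.43
per-ancestry-cluster OR: [1.072 0.747]
```

BIC selects two ancestry clusters, and the clustering disagrees with the
collection labels for 19.4% of samples — recovering the 20% label noise
injected by the generator. At the causal marker the heterogeneity signal
is clearly stronger under the ancestry grouping ($D = 5.4 > 0$), and the
per-cluster odds ratios (1.07 and 0.75) recover the simulated pattern of
an effect confined to one population (true ORs 1.0 and 0.7; cluster
label order is arbitrary).

The same pipeline is available from the shell:

```bash
ancestryx simulate --n-per-pop 300 --n-markers 800 --fst 0.02 --seed 5 --out-prefix demo
ancestryx pca --genotypes demo.raw --samples demo.samples.tsv --out scores.tsv
ancestryx cluster --scores scores.tsv --out clusters.tsv
ancestryx test --genotypes demo.raw --samples demo.samples.tsv \
    --clusters-a clusters.tsv --covars sex --out tests.tsv
ancestryx calibrate --genotypes demo.raw --samples demo.samples.tsv \
    --clusters-a clusters.tsv --sims 2000 --seed 3 --out thresholds.json
ancestryx power --or-group1 0.9 --maf 0.3 --n-cases 500 --n-controls 500 --out power.tsv
```

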