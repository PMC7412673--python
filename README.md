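# hippo-sc

Zero-inflation-guided preprocessing for single-cell UMI count data.

Droplet-based scRNA-seq with unique molecular identifiers produces count
matrices in which, for a **homogeneous** cell population, most genes are well
described by a simple Poisson: gene *g* with mean UMI count λ_g has expected
zero proportion e^{−λ_g}. Excess zeros ("drop-outs") beyond that expectation
are, for the most part, not technical noise but **cell-type mixing**: a finite
Poisson mixture has zero probability Σ_k π_k e^{−λ_k} ≥ e^{−Σ_k π_k λ_k}
(Jensen's inequality). This package turns that observation into a workflow:

1. **Zero-inflation test** — per gene, compare the observed zero proportion
   p̂_g to e^{−X̄_g} with the statistic
   z_g = (p̂_g − e^{−X̄_g}) / √(p̂_g(1−p̂_g)/C), one-sided against
   p_g > e^{−λ_g}. Genes with z > 2 are flagged as heterogeneity carriers.
   A Poisson deviance score d_g is available as an alternative for
   high-count data.
2. **Iterative clustering** — repeatedly: select zero-inflated genes within
   the most variable cluster, log(1+X)-transform and standardize them, split
   the cluster in two with PCA + K-means, and score every cluster's
   intra-cluster variation (sum of sample variances of the leading
   uncentered, unscaled PCA embeddings). Stop at K clusters or when fewer
   than G·o genes remain inflated.
3. **Differential expression** — per gene between two clusters: a plug-in
   t statistic (m₁−m₂)/√(m₁/n₁+m₂/n₂) against the standard normal, and a
   Poisson likelihood-ratio deviance against χ²₁, with Bonferroni control.
4. **Model diagnostics** — per-gene Poisson / negative binomial / zero-inflated
   negative binomial maximum-likelihood fits (variance λ²/r + λ;
   ZINB = π₀δ₀ + (1−π₀)NB(λ, r)) with nested likelihood-ratio tests for
   overdispersion and zero inflation.

A simulator generates Poisson-mixture, NB and ZINB count matrices with known
ground truth, so every claim above is testable without external data.

## Worked example

```python
import numpy as np
from hippo import (default_mixture_spec, simulate_poisson_mixture,
                   gene_zero_stats, HippoConfig, hippo)
from sklearn.metrics import adjusted_rand_score

spec = default_mixture_spec(seed=0)          # 3 cell types x 300 cells, 2000 genes
m, truth = simulate_poisson_mixture(spec)

stats = gene_zero_stats(m)
z = np.array([s.z for s in stats])
print(f"{(z > 2).sum()} of {m.n_genes} genes zero-inflated at z > 2")

res = hippo(m, HippoConfig(K=3, seed=0))
ari = adjusted_rand_score(truth.labels, res.final_labels.labels)
print(f"stopped: {res.stop_reason}; ARI vs truth = {ari:.3f}")
```

prints

```
84 of 2000 genes zero-inflated at z > 2
stopped: reached_K; ARI vs truth = 1.000
```

84 of the 100 truly heterogeneous genes exceed the z = 2 cutoff, and two
rounds of feature selection + binary splitting recover the three simulated
cell types exactly (adjusted Rand index 1.0).

The same pipeline is scriptable from the shell:

```bash
hippo simulate --out-dir fix --seed 0
hippo select  --matrix fix/matrix.mtx --genes fix/genes.tsv --barcodes fix/barcodes.tsv --out stats.tsv
hippo cluster --matrix fix/matrix.mtx --genes fix/genes.tsv --barcodes fix/barcodes.tsv -k 3 --out-dir run
hippo de      --matrix fix/matrix.mtx --genes fix/genes.tsv --barcodes fix/barcodes.tsv \
              --labels run/labels.tsv --group1 0 --group2 1 --out de.tsv
hippo diagnose --matrix fix/matrix.mtx --genes fix/genes.tsv --barcodes fix/barcodes.tsv --out diag.tsv
```

Each command writes a JSON manifest (configuration, input digests, seed,
summary) alongside its output.

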