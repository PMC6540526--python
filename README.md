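# repclonity

Tumor-infiltrating B cells leave a readable trace in bulk RNA-seq: assembled
B-cell-receptor (BCR) variable-region sequences, each a *clone* with a read
count. `repclonity` turns per-sample clone tables into the repertoire
statistics used to ask whether the B-cell response carries prognostic or
predictive information in cancer cohorts — in melanoma, a clonally
restricted IGHG repertoire (low species evenness) is a favorable prognostic
factor, and absence of any assembled IGHG associates with lack of response
to CTLA-4 blockade.

The package is aimed at computational immunologists working downstream of a
BCR assembler (AIRR Rearrangement TSV or a minimal assembler-output
dialect). It provides:

* **Diversity / clonality metrics** per (sample, chain): total clone reads
  per million library reads (CPM), species richness S, Shannon entropy
  H = −Σ pᵢ ln pᵢ, Simpson concentration λ = Σ pᵢ² and Gini–Simpson 1 − λ,
  species evenness (H/S, with Pielou's H/ln S as an option), top and
  second clone proportions, and mean V-region identity against a germline
  V FASTA (a somatic-hypermutation surrogate), plus rank-abundance
  structures and the chain-presence matrix.
* **Expression classifiers**: a silhouette-filtered nearest-centroid
  subtype predictor with per-class gene selection and stratified
  cross-validated error, and a regularized linear multiclass classifier
  (call = highest softmax probability) for B-cell phenotype panels.
* **Survival and association inference**: Cox proportional-hazards models
  (Efron ties, hazard ratios per SD of the measurement), nested
  likelihood-ratio tests, Kaplan–Meier curves, Mann–Whitney / Fisher /
  chi-square / ANOVA+Benjamini–Hochberg screens, Spearman correlation
  matrices, and the heatmap-style two-way clustering with fixed
  missing-value rules (missing metric → 0, evenness → 1, V-identity →
  median).
* **A synthetic-data generator** (Dirichlet-multinomial clone frequencies,
  substitution-only hypermutation, evenness-linked exponential survival,
  response-linked BCR presence, class-structured expression) so the whole
  pipeline runs and is tested without any external download.

## Worked example

```python
import numpy as np
from repclonity import diversity, simulate

cfg = simulate.SimConfig(seed=1)
rep, truth = simulate.simulate_repertoire(cfg, np.random.default_rng(1))
prof = diversity.diversity_profile(rep, ref=simulate.bundled_germline())
print(f"S={prof.richness}  H={prof.shannon:.3f}  "
      f"gini_simpson={prof.gini_simpson:.3f}  evenness={prof.evenness:.4f}  "
      f"top={prof.top_clone_prop:.3f}  v_identity={prof.mean_v_identity:.2f}")
```

prints

```
S=34  H=2.657  gini_simpson=0.891  evenness=0.0782  top=0.253  v_identity=96.09
```

i.e. a repertoire of 34 clones whose entropy (2.66 nats) is well below the
uniform maximum ln 34 ≈ 3.53, a 25% top clone, and clones averaging 96.1%
nucleotide identity to their germline V gene (≈ 3.9% hypermutation).

The `analysis/` scripts run the full study on a synthetic 473-tumor cohort
(`python analysis/01_simulate_cohort.py` … `05_cluster_heatmap.py`, outputs
under `results/`). The survival screen from `04_survival_association.py`,
hazard ratios per SD with likelihood-ratio p-values, looks like:

```
                  hr_univariable  p_univariable_lrt  hr_multivariable  p_multivariable_lrt
evenness                  1.3361             0.0011            1.3207               0.0023
mean_v_identity           0.8286             0.0391            0.8400               0.0614
richness                  0.8594             0.1018            0.8866               0.2126
...
```

Evenness tops the screen: higher evenness (less clonal restriction) means
higher hazard, consistent with the planted per-SD hazard ratio of 1.38.

The same pipeline is scriptable from the shell:

```
repclonity run-all --out-dir out --seed 7
repclonity diversity --clones clones.tsv --dialect airr \
    --germline v.fasta --library-sizes libs.tsv -o profiles.tsv
```

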