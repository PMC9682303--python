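# phylomorph

Phylogenetic geometric morphometrics in Python: Procrustes shape analysis
and the comparative statistics needed to ask whether a body plan evolves as
one integrated unit or as semi-independent modules.

The package was built around the study design used for suckermouth armoured
catfishes (Loricariidae) — landmark configurations digitised from museum
specimens, species means placed on published phylogenies, and a battery of
modular hypotheses ranging from fully integrated (one module) to seven body
regions (mouth, neurocranium, opercula, pectoral/dorsal fins, pelvic fins,
anal area, caudal peduncle) — but every component is generic: any landmark
dataset (TPS or wide CSV, 2-D or 3-D), any rooted Newick tree with branch
lengths, and any landmark→module partition.

## What it computes

* **GPA** — generalized least-squares Procrustes superimposition (translation,
  scale and orientation removed; reflections disallowed), species mean
  shapes, Procrustes distances.
* **Ordination** — PCA of species means, broken-stick axis selection
  (retain axis *i* while its variance share exceeds
  b_i = (1/p)·Σ_{j≥i} 1/j), shape backtransforms, and phylomorphospace
  projection with Brownian-motion (BM) ancestral estimates.
* **Phylogenetic signal** — K_mult, the multivariate generalisation of
  Blomberg's K: the ratio of ordinary to phylogenetically corrected mean
  squared deviation from the phylogenetic mean, scaled so E[K] = 1 under
  single-rate BM; permutation p-values.
* **Modularity** — the covariance ratio
  CR = √( tr(S₁₂S₂₁) / √( tr(S₁₁°S₁₁°)·tr(S₂₂°S₂₂°) ) )
  (within-module diagonals zeroed; mean of pairwise CRs for >2 modules),
  with landmark-permutation nulls, effect sizes on a common null for model
  comparison, and EMMLi-style maximum-likelihood model selection over
  pooled landmark-pair correlations with AICc weights.
* **Integration** — phylogenetically corrected two-block PLS: rPLS is the
  correlation of the first pair of singular variates of the between-block
  covariance (0 = independent, 1 = fully integrated).
* **Evolutionary rates** — per-module multivariate BM rates with a max/min
  ratio test against single-rate simulation, and penalized-likelihood
  multirate BM in which log σ² itself evolves by BM with smoothing λ.
* **Macroevolution** — convergence metrics C1–C4 (how much of the maximum
  past distance between lineages the focal tips have closed), ellipse
  crossing counts in a 2-D morphospace, and disparity-through-time at 31
  slices with burst detection (increase > 10 between slices).
* **Synthetic data** — ultrametric pure-birth trees and landmark datasets
  evolving by multivariate BM with block-structured trait covariance
  (known within/between-module correlations and per-module rates), so
  every stage is testable without downloads.

Phylogenetic correction everywhere means pre-multiplying mean-centered
species data by the inverse square root of the BM tree covariance
C (C_ij = depth of the most recent common ancestor of tips i and j).

## A worked example

`examples/03_modularity_and_integration.py` simulates 71 species with the
default 7-region modular covariance (within-module correlation 0.7,
between 0.1) and tests the ten-model battery:

```
model comparison by CR effect size (common null):
                        model  n_modules       cr         z
                    7_regions          7 0.203320 -6.477929
             6_opercula_split          6 0.228431 -6.213348
5_mouth_head_fins_anal_caudal          5 0.234347 -6.151012

7-region modularity: CR = 0.20, p = 0.0010 (CR < 1 -> modular)
integration: mean rPLS = 0.24, p = 0.0249 (0 = none, 1 = full)
EMMLi best model: 7_regions (weight 1.00)
```

Both model-selection routes recover the generating 7-module structure; the
CR far below 1 says the body is strongly modular at these settings, and the
modest rPLS reflects the weak (0.1) between-module correlation used to
generate the data.  The other scripts in `examples/` walk through shape
analysis, phylogenetic signal, rates, convergence and disparity the same
way, each printing the numbers it computes and what they mean.

A thin CLI wraps the same pipeline for file-based runs:

```sh
phylomorph simulate --n-species 40 --seed 1 --out demo/
phylomorph all config.yaml      # GPA -> PCA -> signal -> modularity -> rates -> DTT
```

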