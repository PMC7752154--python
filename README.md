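# immunosig

Discovery of immunomodulatory expression signatures from single-cell RNA-seq
and their association with immune-checkpoint-blockade (ICB) response and
survival.

`immunosig` is a tested, reusable implementation of a common study design in
ICB biomarker research: learn latent expression signatures from a large
single-cell compendium with an autoencoder, identify the signatures enriched
for immunomodulator genes, project bulk expression from clinical trial
cohorts through the same model, and test whether the selected signature
predicts clinical improvement and overall survival after adjusting for the
established covariates (TMB, CTL infiltration, *PD-1*/*PD-L1*/*CTLA-4*
expression; sex, subtype/stage).

## The model

An autoencoder `x → h = f(W_e x + b_e) → x̂ = W_d h + b_d` is trained on a
library-size-normalized, log1p-transformed cells × genes matrix. Each of the
K latent units is an **expression signature**: row k of the decoder `W_d`
(L2-normalized) gives its per-gene loadings, and the encoder output `h_k`
gives its per-observation activation score. In the default linear,
unregularized configuration the decoder rows span the top-K principal
subspace of the data, so the model is anchored against classical PCA while
remaining a trainable, extensible architecture (a ReLU bottleneck is one
config switch away).

Downstream of the representation:

- **Ranking** — each signature's loadings are tested for enrichment of an
  immunomodulator gene set (two-sided Wilcoxon rank-sum of member vs
  non-member |loading|), BH-adjusted across the K signatures; subcategory
  profiles (co-stimulator, co-inhibitor, ligand, receptor, cell adhesion,
  antigen presentation, other) characterize the top signatures.
- **Clinical association** — per-patient scores come from encoding the bulk
  cohort matrix; patients are split at the median score, and the battery
  reports the Wilcoxon score comparison between responders and
  non-responders, the Fisher's exact odds ratio (conditional MLE, exact
  two-sided p and CI), the confounder-adjusted logistic OR per unit score,
  Kaplan–Meier curves with the log-rank test, and the multivariate Cox HR
  (Efron ties). All intervals are 95%.
- **Enrichment** — preranked GSEA (weighted KS running sum, gene-label
  permutation null) of the high-vs-low differential expression ranking.

A synthetic-data module generates negative-binomial single-cell counts
carrying planted latent gene programs — one concentrated on a designated
immunomodulator set — plus clinical cohorts in which response odds and death
hazard depend on the planted program with known effect sizes, so every claim
the pipeline makes is checkable against ground truth.

## Worked example

```python
from immunosig import (SimulationConfig, TrainingConfig, make_immuno_collection,
                       preprocess, train_signature_model, rank_all_signatures,
                       simulate_single_cells, simulate_cohort, encode,
                       orient_signatures, attach_scores, dichotomize,
                       fisher_or, logistic_adjusted)

cfg = SimulationConfig(seed=1)               # 500 genes, 3000 cells, 298 patients
cells, truth = simulate_single_cells(cfg)    # planted immunomodulatory program
model = train_signature_model(preprocess(cells), 8, TrainingConfig(epochs=300, seed=1))
model = orient_signatures(model, truth.immuno_genes)   # fix latent sign ambiguity

ranking = rank_all_signatures(model, make_immuno_collection(truth.immuno_genes))
print(ranking.top_k, ranking.fraction_significant)

bulk, cohort = simulate_cohort(cfg, truth)
scores = encode(bulk, model)
strat = dichotomize(attach_scores(cohort, scores, ranking.top_k[0]))
f, l = fisher_or(strat), logistic_adjusted(strat.table)
print(round(f.effect, 3), round(f.p, 4))
print(round(l.extras["or_per_sd"], 3), round(l.p, 4))
```

Output (seed 1):

```
['s1', 's2', 's8', 's3', 's6'] 87.5
1.481 0.1817
1.274 0.0809
```

`top_k` lists the signatures most enriched for the planted immunomodulator
set and `87.5` is the percentage of the 8 signatures significantly
associated with immunomodulation at BH-adjusted p < 0.05 (the planted
program loads broadly, so several latent factors pick up parts of it). On
the 298-patient cohort, the Fisher OR of `1.48` compares response odds
between high- and low-score patients, and `1.274` is the per-standard-
deviation odds ratio of the score after controlling for TMB, CTL and
checkpoint-gene expression — near the planted per-unit OR of 1.3, attenuated
by the imperfect correlation between the learned score and the true program
activity, and, at a realistic trial size, not yet significant (p = 0.08).
The acceptance script shows the same estimate converging to the planted
value at n = 5000.

The same flow is available from the shell:

```bash
immunosig simulate --seed 1 --outdir data/
immunosig train --matrix data/cells --k 8 --seed 1 --out model.h5
immunosig score --matrix data/bulk.tsv --model model.h5 --out scores.tsv
immunosig rank --model model.h5 --gmt data/immuno.gmt --out-prefix rank
immunosig stratify --cohort data/cohort.tsv --scores scores.tsv --signature s2 --out strat.tsv
immunosig associate --strat strat.tsv --out assoc.tsv
```

or as a single run: `immunosig run --config run.yaml` (writes a manifest with
content hashes of every stage output).

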