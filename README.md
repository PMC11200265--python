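# assaymatch

Zero-shot bioactivity prediction by **assay–molecule matching**: predict
whether a molecule is active in a bioassay for which *no labelled
measurements exist*, using only the assay's textual description.

Classical QSAR models are trained per assay and cannot say anything about a
new endpoint until measurements accumulate. `assaymatch` reframes the problem
as matching: a model is trained once on a large pooled table of
(molecule, assay, active?) triples, consuming the molecule's structure *and*
the assay's text, and is then applied unchanged to assays it has never seen —
e.g. to prioritize a screening library for a brand-new HTS campaign from the
protocol text alone.

## The method

Three components are chained:

1. **Featurization.** Molecules become extended-connectivity fingerprints
   (ECFP, 1024 bits, radius 2); assay documents become dense vectors through
   a pluggable embedding provider (a TF-IDF + truncated-SVD LSA encoder is
   included; any deterministic text-embedding model can be slotted in).

2. **Barlow Twins fusion.** A molecule encoder f and a text encoder g (MLPs
   with a shared projector h) are trained so that for a batch of matched
   pairs the cross-correlation matrix of the two projections,

   C_ij = ⟨ ĥ(f(x))_i , ĥ(g(t))_j ⟩ / N   (ẑ = batch-standardized z),

   approaches the identity, by minimizing

   L(C) = Σ_i (1 − C_ii)² + λ Σ_{i≠j} C_ij² .

   The diagonal term aligns each embedding coordinate across the two
   modalities; the off-diagonal term decorrelates distinct coordinates and
   prevents collapse. The network (forward pass, backpropagation through the
   batch standardization and the correlation loss, AdamW) is implemented in
   NumPy, making training bitwise-reproducible from (seed, config, data).

3. **Gradient-boosted matching + conformal reliability.** A LightGBM
   classifier on the concatenated encoder bottlenecks [f(x); g(t)] outputs
   P(match). Mondrian (class-conditional) inductive conformal prediction
   wraps these probabilities: each prediction becomes a subset of
   {active, inactive} with per-class validity at confidence level ε = 0.80;
   singleton sets are flagged *confident*.

Evaluation follows zero-shot screening conventions: PR AUC and ΔPR AUC
(minus the active prevalence, so 0 = random), ROC AUC, BEDROC (α = 20) for
early recognition, recall curves, Tanimoto/Murcko-scaffold diversity of the
top of a ranking, plus Wilcoxon / Welch / Mann–Whitney tests with
Benjamini–Hochberg correction and the mean-of-means replicate protocol.

Because real pooled bioassay corpora are large downloads, the package ships a
**synthetic world generator**: assays carry latent concept vectors, molecule
activity depends on the concept–molecule inner product, and the observed
fingerprints/text embeddings are noisy views of the latents. Zero-shot
transfer, modality ablations and conformal coverage are all measurable
against a known ground truth (see `docs/methods.md`).

## Worked example

```bash
# 1. simulate a world: 30 assays x 120 molecules, 10 assays held out
assaymatch simulate --out world --seed 5 --n-assays 30 --mols-per-assay 120

# 2. train on the training assays only (zero-shot = assay-disjoint)
python - <<'EOF'
import json, pandas as pd
held = set(json.load(open("world/split.json"))["heldout_assays"])
pairs = pd.read_csv("world/pairs.tsv", sep="\t", dtype=str)
pairs[~pairs.assay_id.isin(held)].to_csv("train_pairs.tsv", sep="\t", index=False)
pairs[pairs.assay_id.isin(held)].to_csv("heldout_pairs.tsv", sep="\t", index=False)
EOF
assaymatch train --pairs train_pairs.tsv --embeddings world/embeddings.tsv \
                 --out model --seed 9

# 3. zero-shot predictions for the 10 never-seen assays
assaymatch predict --archive model --pairs heldout_pairs.tsv \
                   --embeddings world/embeddings.tsv --out preds.tsv --ranked
assaymatch evaluate --predictions preds.tsv --labels world/pairs.tsv --out report
```

The evaluation report aggregates per-assay metrics over the 10 held-out
assays (mean ± sd across assays):

```
pr_auc        0.483 ± 0.096
delta_pr_auc  0.183 ± 0.096
roc_auc       0.682 ± 0.089
```

ΔPR AUC of 0.183 means the ranking concentrates actives well above the
random-guess baseline (the ~0.30 active prevalence) in assays the model has
never observed — the signal travels purely through the assay text. The top
of the ranked prediction file:

```
     id assay_id  probability  p_value_active  p_value_inactive  confident
M001166    A0009     0.974721        0.956140          0.008065          1
M000226    A0001     0.954544        0.947368          0.008065          1
M002046    A0017     0.941380        0.947368          0.008065          1
```

`confident = 1` marks singleton conformal prediction sets: at ε = 0.80 the
active call for M001166 is backed by a conformal p-value of 0.96 for
"active" against 0.008 for "inactive".

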