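# Methods

## Problem setting

Given a pooled table of (molecule, assay, label) triples, the pipeline learns
to score the *match* between a molecule's structure and an assay's textual
description, so that it can rank molecules for an assay that contributed no
labels to training. Training and evaluation are always assay-disjoint: a
task (assay) lives in exactly one split, which is what makes the evaluation
zero-shot rather than few-shot.

## Model

**Featurization.** Molecules: binary extended-connectivity fingerprints,
default 1024 bits at radius 2, hashed by RDKit's Morgan generator.
Stereochemistry is excluded from the hashing by default and can be switched
on per call (`include_chirality`). Invalid SMILES raise immediately; the
batch API collects per-row errors instead of dropping rows, so filtering is
always explicit. Assay text: any deterministic fixed-dimension embedding
provider. The included LSA provider uses TF-IDF (natural term frequency,
smoothed IDF log((1+N)/(1+df)) + 1, L2 document normalization, lowercase word
tokens — scikit-learn's defaults) followed by truncated SVD; component signs
are fixed by making each component's largest-magnitude loading positive.
The LSA dimensionality is a free parameter (default 256) since nothing in
the method pins it.

**Fusion network.** A molecule encoder and a text encoder (MLPs, ReLU,
linear output) feed a *shared* projector. For a batch of N matched pairs the
two projector outputs are batch-standardized per dimension (population
variance, epsilon 1e-8 so constant dimensions map to zero) and combined into
the cross-correlation matrix C = Ẑaᵀ Ẑb / N. The loss

    L(C) = Σ_i (1 − C_ii)² + λ Σ_{i≠j} C_ij²

is minimized with AdamW (decoupled weight decay applied to weight matrices,
not biases; lr 1e-3, weight decay 1e-2, β = (0.9, 0.999)). Training runs 25
epochs, or stops early when a validation loss fails to improve for
`patience` (default 5) epochs, restoring the best-epoch weights. The default
off-diagonal weight is the canonical λ = 0.005. Which pairs enter the
alignment objective is configurable: `all` labelled pairs or
`positives_only`; the downstream matcher always trains on all pairs. All
computation is float64 NumPy with explicitly derived gradients, so a (seed,
config, data) triple reproduces training bit for bit on any machine.

**Matcher.** LightGBM binary classifier on the concatenation of the two
encoder bottleneck outputs (the information-bottleneck features; projector
outputs are available as an alternative source). Fixed defaults (300 trees,
learning rate 0.05, 31 leaves); hyperparameter search campaigns are
deliberately out of scope. LightGBM runs single-threaded in deterministic
mode so refits reproduce predictions exactly.

**Conformal reliability.** Mondrian (class-conditional) inductive conformal
prediction on the matcher probabilities. A calibration item of true class c
scores nonconformity 1 − p̂(c); a test item receives, per class, the
conservative p-value (1 + #{calibration scores ≥ test score}) / (n_c + 1)
(ties count toward inclusion, no smoothing), and the class enters the
prediction set iff its p-value exceeds 1 − ε. Default ε = 0.80. The
conservative variant guarantees expected per-class coverage ≥ ε under
exchangeability of calibration and test points, with a discreteness bonus of
order 1/n_c. "Confident" means a singleton set; an empty set (possible when
ε > n_c/(n_c+1)) is reported as non-confident with both p-values attached.
Calibration points are always held out of matcher training (a 15% slice of
the training pairs by default), as inductive conformal prediction requires.

## Evaluation conventions

* **PR AUC** is average precision — the mean of precision-at-rank over the
  ranks of the actives — with descending-score ordering and ties broken by
  stable input order. No trapezoidal interpolation.
* **ΔPR AUC** subtracts the active prevalence of the evaluated set (the
  expected score of a random ranking, up to a +O(log N / N) finite-sample
  bias of average precision).
* **ROC AUC** uses the Mann–Whitney identity, ties counted 1/2.
* **BEDROC** (default α = 20) uses the exponentially weighted rank sum with
  the closed-form robust-initial-enhancement normalization, which maps a
  perfect ranking to exactly 1.
* **Recall curve**: step curve of (fraction screened, fraction of actives
  found) from (0,0) to (1,1).
* **Significance tests**: two-sided Wilcoxon signed-rank (zeros dropped),
  Mann–Whitney U, Welch t, Pearson. The nonparametric tests use exact null
  enumeration up to n = 12 (Mann–Whitney: only for tie-free pooled samples)
  and the (tie-corrected) normal approximation above. Benjamini–Hochberg
  step-up adjustment for multiplicity.
* **Aggregation**: metrics are averaged over replicates within a task first,
  then mean and population SD are taken across tasks ("mean of means");
  ragged replicate counts are a protocol error. Replicates re-run the whole
  training pipeline from a derived seed — they measure training
  stochasticity, not data resampling.

## The synthetic world

Real pooled bioassay corpora are multi-gigabyte downloads; the generator
produces worlds with the same *shape* and a known ground truth.

Per world: each assay k has a unit concept vector a_k ∈ R^d (latent_dim
d = 8). Concepts are drawn in anti-correlated pairs (a, −a) — two assays
probing one axis in opposite directions, like an agonist and an antagonist
screen. Molecules are fresh draws m ~ N(0, I_d) per assay. Activity is
Bernoulli with P(active) = σ(⟨a_k, m⟩ / T + b_k), temperature T = 0.25; the
per-assay bias b_k is found by bisection against the realized uniform draws
so each assay's empirical prevalence hits the target (0.30) exactly up to
rounding, with both classes always present. Observed modalities are noisy
views: text embedding = a_k + N(0, 0.1² I); fingerprint = sign pattern of a
fixed random projection of (m + N(0, 0.1² I)) into 512 bits. A third of the
assays (80 of 240 by default) is held out, sharing no assay, molecule or
text with training.

Why these defaults: for an active pair the best achievable per-dimension
correlation between the two modalities is roughly E[⟨a, m⟩ | active] / √d ≈
0.35 — the alignment signal a fusion network can extract is intrinsically
bounded. Measuring the held-out cross-correlation is itself noisy because
held-out positives cluster by assay (one text vector per assay), so the
off-diagonal noise floor scales with the number of held-out assays, not
pairs; 80 held-out assays put that floor near 0.05, well below the
attainable diagonal. The anti-correlated concept pairs make the molecular
modality alone uninformative across the pooled table, so any cross-assay
generalization must flow through text — this is what the modality-ablation
comparison (fused vs fingerprint-only matcher) exercises.

The desk-scale fusion configuration (`BENCH_BT_CONFIG`) departs from the
full-scale defaults for reasons that are properties of this regime:

* encoders 512→256→32 (molecule) and a single linear layer 8→32 (text):
  with only ~160 distinct training-assay embeddings, a hidden-layer text
  encoder memorizes the corpus and games per-batch correlations instead of
  learning the concept map — a linear map closes most of that
  generalization gap;
* projector 32→64→8: the world has 8 latent axes, so only 8 projector
  dimensions can carry independent aligned signal; wider outputs dilute the
  diagonal and manufacture redundant (correlated) dimensions;
* λ = 1.0 instead of 0.005: with the diagonal capped near 0.35, the
  (1 − C_ii)² term dominates the objective and the canonical λ never
  removes real off-diagonal correlation; weighting redundancy on an equal
  footing does;
* alignment trains on active pairs only (`positives_only`): activity is
  the only mechanism linking a molecule to its assay's concept, so aligning
  inactive pairs would align statistically independent views.

What passing tests on this world do and do not show: they demonstrate that
the implementation recovers plantable latent structure end to end —
alignment, zero-shot transfer, ordering of ablations, conformal validity.
They do not demonstrate chemistry: synthetic fingerprints are random sign
projections, not circular substructures; text embeddings are noisy concepts,
not language; assay heterogeneity, batch effects and frequent-hitter
artifacts of real HTS data are absent. Real-fingerprint behaviour is tested
separately on small SMILES sets through the featurization module.

## Numerical choices and degenerate inputs

* Batch standardization epsilon 1e-8; batches need N ≥ 2; the last training
  mini-batch is kept when it has ≥ 2 rows.
* Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  objects). Pairwise-diversity SD is the population SD over distinct pairs.
* The top slice of a ranked list holds floor(fraction · N) molecules, at
  least one.
* Non-finite training loss raises immediately with the epoch number;
  single-class label vectors, empty calibration classes, all-tied ranking
  degeneracies each raise their own exception type rather than returning
  NaN.
* All component seeds derive from one root seed via NumPy `SeedSequence`
  spawning (kept below 2^31 for LightGBM).
* Problem sizes in the shipped tests and acceptance script (240-assay
  worlds, 3–20 replicates, 500/1000-point calibration/test draws) were
  chosen so every stochastic assertion has a several-sigma margin under the
  generator's known sampling variability.

## Limitations

* The transformer-based text encoder used in full-scale deployments is
  abstracted behind the provider interface and not shipped; the LSA and
  fixture providers are the tested paths.
* The NumPy trainer is CPU-only and single-threaded by design
  (reproducibility first); it is not intended for corpus-scale pretraining.
* Conformal validity is marginal (per class, in expectation over
  calibration/test exchangeability); per-assay conditional coverage is not
  guaranteed.
* Matcher hyperparameters are fixed sane defaults; no tuning campaign.
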