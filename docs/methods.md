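# Methods

This note records the modeling assumptions, default parameters, and
design decisions behind `clpbench`, in the spirit of a package reference
manual: what the pipeline computes, why the defaults are what they are,
and what the synthetic benchmark does and does not demonstrate.

## Synthetic structure–activity data

The generator produces molecules from a curated fragment grammar and
plants an exactly recoverable activity signal, so that every downstream
stage (tokenization, splitting, training, metrics) can be validated
against an independent oracle.

**Fragment grammar.** Twelve scaffolds (benzene, pyridine, pyrimidine,
thiophene, furan, pyrrole, imidazole, naphthalene, quinoline, indole,
piperidine, cyclohexane), forty plain substituents (alkyl, alkoxy, amino,
halogen, carbonyl, small rings, aryl), and four pharmacophore fragments:
trifluoromethyl `C(F)(F)F`, sulfonamide `S(N)(=O)=O`, nitro
`[N+](=O)[O-]`, and nitrile `C#N`. Substituents attach through their
first atom to a random C–H carbon; attachments that fail RDKit valence
sanitization are resampled. The fragment list deliberately exercises
multi-character tokens (`Cl`, `Br`) and bracket atoms (`[nH]`, `[N+]`,
`[O-]`) so tokenizers are tested on the full grammar. The pharmacophores
were chosen so that no plain substituent contains any of them as a
substructure; substructure matching (SMARTS queries — a SMILES-parsed
query can silently fail on the charged nitro group because of valence
bookkeeping) is therefore an exact label oracle.

**Classification ("hit discovery") sets.** Default 5500 molecules with
10% actives, the scale of the emulated screening datasets. Actives are
constructed by placing 1–2 pharmacophores and verified by matching;
inactives are verified to match none; duplicates are rejected. The active
count is exact by construction: `round(n_molecules * active_fraction)`.
An optional `label_noise` flips each label independently after
construction. Molecules carry 1–4 substituents and, with probability
0.35, a second ring system; this diversity is what makes a
dissimilarity-filtered test set constructible (see Splits) and gives the
diverse similarity profile typical of screening collections (modal
maximum train-similarity below 0.4).

**Regression ("lead optimization") sets.** Analog series: each series
builds one parent (a larger scaffold — naphthalene, quinoline, indole,
indane, biphenyl — plus three core substituents and a series-level
pharmacophore complement, each fragment included with probability 0.25),
and analogs add exactly one small variable group. Series size defaults
to 5. The pKi value is

    value = intercept + Σ_k effect_k · indicator_k + N(0, noise_sd),

with defaults intercept 6.0, effects (1.5, 1.0, −0.8, 0.5) in log units,
and noise_sd 0.3 — a typical inter-assay reproducibility scale for
ChEMBL-like potency data. With `noise_sd = 0` the values are exactly
linear in the indicator vector (OLS residuals are zero); at the default
noise, OLS recovers each effect within standard sampling error. Making
the pharmacophore complement a series-level property keeps within-series
similarity high (analog series behave like real lead-optimization data,
with modal test-to-train maximum similarity above 0.5 after the grouped
split) while leaving enough indicator variance across series for the
signal to be identifiable.

**Randomness.** A single integer seed expands through
`numpy.random.SeedSequence` into per-stage streams (molecule assembly,
noise, shuffling). Identical configs produce byte-identical record lists.

**What the generator does not emulate.** Physically realistic binding,
activity cliffs, assay heterogeneity, stereochemistry, tautomerism, and
the long-tailed scaffold frequency distribution of real screening decks.
Passing tests demonstrate that the pipeline is correct and that the
architectures can learn substructure-driven signal under controlled
conditions — not that any architecture will reach a particular accuracy
on real assay data.

## String processing

* Canonicalization: RDKit parse → `RemoveStereochemistry` → canonical
  SMILES; idempotent; unparseable strings are dropped and logged.
* SMILES token grammar: bracket atoms `[...]` as single tokens;
  two-character elements (`Cl`, `Br`) matched greedily; `%NN` ring
  closures as one token; digits, bond symbols, and parentheses as single
  tokens. Concatenating tokens always reproduces the input.
* Length filter: molecules with more than 75 SMILES tokens are removed;
  the boundary is strict (75 kept, 76 removed). The filter is applied to
  SMILES token counts only; SELFIES sequences of retained molecules may
  be longer.
* SELFIES: the package ships its own codec for the self-referencing
  grammar (`clpbench._selfies`). Atoms keep their SMILES spelling in
  brackets; non-single bonds become symbol prefixes; branches become
  `[BranchK]` symbols annotating the branch length in symbols; ring
  closures become `[RingK]` symbols referencing how many symbols back the
  ring-opening atom lies; lengths and references are written in base-16
  index symbols `[0]`…`[15]`. Encoding is a two-pass layout over the
  parsed SMILES tree (index widths and positions are iterated to a fixed
  point), which keeps ring references correct even when a ring closure
  sits inside a branch, as in fused-ring canonical SMILES. The contract —
  enforced on 100% of generated molecules — is that decoding
  re-canonicalizes to the original SMILES. The codec covers
  stereochemistry-free single-fragment organic molecules; it does not
  implement valence repair of arbitrary symbol strings, which the
  benchmark never needs (all SELFIES it consumes are its own encodings).
* Vocabulary: built on the full dataset (train+validation+test) before
  splitting, with the pad token reserved at index 0. Fitting before the
  split avoids unknown-token failures at evaluation; only the token
  inventory is shared, which is a negligible leak. The default pipeline
  uses a closed vocabulary; an optional `<unk>` token is available for
  external data. Padding is right-sided to the corpus maximum length.

## Token encodings

One-hot uses the V×V identity structure (pad row zeroed); rows are
mutually orthogonal unit vectors. Random and learnable encodings
initialize i.i.d. Normal(0, 1/dim) from an explicit seed — variance 1/dim
keeps dot products O(1) regardless of dimension. Random tables are
excluded from the optimizer and verified bit-identical after training;
learnable tables receive gradients, except the pad row, which is zeroed
after every backward pass. Embedding-dimension candidates are
{16, 32, 64, 128}, mirroring the RNN hidden-dimension ladder; combined
with the CNN grid this enumerates 432 CNN configurations. One-hot vectors
feed the first layer directly (no projection), so their effective
dimension is the vocabulary size.

## Architectures

All three sequence encoders terminate in the same three-layer perceptron
(128 → 64 → 1, ReLU, dropout 0.25 between layers); dropout 0.25 is also
applied inside each encoder. The classification output is a logit
(sigmoid applied at prediction time); regression output is unbounded.
The optimizer is Adam at the grid learning rate, batch size 32. The
models run on a small reverse-mode autodiff engine (`clpbench.nn`) whose
gradients are verified against finite differences in the test suite.

* **CNN** — stacked length-preserving 1-D convolutions (stride 1, zero
  padding) with ReLU; pad positions are re-zeroed between layers so that
  stacked convolutions see the same zeros as their boundary padding;
  masked global max pooling over valid positions.
* **RNN** — stacked bidirectional GRUs. Pad handling is by gating: where
  the mask is 0 the hidden state carries through unchanged, so the final
  state equals the state at each sequence's true length. The pooled
  representation concatenates the final forward and backward states
  (width 2·hidden).
* **Transformer** — token vectors plus learnable positional embeddings
  (table size `max_len` = 128, covering the 75-token limit), post-norm
  blocks with multi-head self-attention (pad keys masked at −1e9 before
  the softmax) and a feed-forward of the configured width; masked mean
  pooling. The model width equals the token embedding dimension, so the
  head count must divide it.

Pooling choices (max for CNN, final-state concat for RNN, mean for
Transformer) are the field's defaults; all are masked so predictions are
invariant to extra padding columns, which the tests assert exactly.

The **XGBoost baseline** trains gradient-boosted trees on the same
Morgan fingerprints the splitter uses, capped at 2000 trees with
early stopping counted in trees.

## Splits

* Levenshtein distance is computed character-wise on canonical SMILES
  (via edlib, checked against a brute-force dynamic program).
* Fingerprints: Morgan radius 2, 1024 bits — recorded in `SplitCriteria`
  so alternatives are a one-line config change.
* Classification: training molecules are drawn at random per class;
  validation molecules must be distant from training, and test molecules
  from both, under two strict criteria — edit distance > 10 *and*
  Tanimoto < 0.60 to every reference molecule. Each `DataSplit` carries
  an audit (per molecule: exact nearest-train edit distance and maximum
  Tanimoto) that tests recompute from scratch. The benchmark uses scaled
  per-class fractions 35% / 8% / 8%: the unselected remainder is the
  slack the dissimilarity filter needs, since a random training draw
  leaves some pool molecules too similar to qualify. Requesting sizes
  that exhaust the pool raises an error reporting per-class eligible
  counts.
* Regression: single-linkage clusters at Tanimoto ≥ 0.6 define analog
  groups ("substructure similarity" grouping); whole groups are
  allocated greedily, largest first, to the partition with the largest
  remaining deficit, meeting 70/15/15 within one group's size. A single
  group covering more than 70% of the data raises an error suggesting a
  lower threshold.
* Monte Carlo validation: k = 5 independent 80/20 resamples of the
  training pool (overlapping validation sets, unlike disjoint k-fold);
  per-fold seeds derive from the master seed.

## Training

Classification loss is binary cross-entropy with per-molecule weights
equal to the inverse class frequency normalized so the majority class has
weight 1 (10:1 imbalance ⇒ active weight 10); regression loss is mean
squared error. Early stopping: an epoch improves only if it lowers the
best validation loss by strictly more than 1e-5; after 5 consecutive
non-improving epochs training halts and the best epoch's weights are
restored. `max_epochs` defaults to 100 (early stopping dominates in
practice). A run whose loss turns non-finite (e.g. at the highest
learning rates) is marked failed, excluded from selection, and warned
about rather than aborting the grid search. Grid search trains every
configuration on every fold and selects by minimal mean validation loss;
the budget-subsampling analysis draws k configurations uniformly without
replacement, ranks them by validation loss, and reports the mean test
metric of the top 10 (all, when k < 10), with mean ± sd over repeats.
Single runs are fully deterministic given (seed, config, data) on a fixed
platform; across BLAS builds, float summation order may perturb results
in the last few ulps.

## Evaluation and statistics

Classification decisions threshold predicted probability at 0.5.
Undefined precision (no predicted positives) is reported as 0 with a
flag. Concordance ties: prediction ties credit 1/2; pairs tied in the
true values are excluded (an error if *all* pairs are tied). The
comparison procedure runs a Friedman omnibus test across models (identical
columns short-circuit to statistic 0, p = 1, where the rank-based statistic
is undefined), then all pairwise Wilcoxon signed-rank tests — two-sided
by default (a one-sided alternative is exposed), exact null for n ≤ 12
without ties, normal approximation with continuity correction otherwise,
zero differences dropped — with Holm–Bonferroni step-down adjustment.
The top-k hyperparameter inspection ranks configurations by mean
validation loss by default; ranking by test metric is available
(descending) but not the default, since selecting on test data biases
the inspection.

## Problem sizes used by the test suite

The suite validates at reduced scale, chosen to keep a full run in a few
minutes on one CPU while preserving the study's structure: generator
contracts at 300–2000 molecules; split audits at 1000 molecules with
per-class sizes (35+350 / 8+75 / 8+75); OLS recovery at n = 2000;
re-weighting direction over 5 seeds at n = 1100; and an end-to-end
factorial benchmark (one 1100-molecule dataset, reduced grids of 8
configurations for the sequence models and 4 for the baseline, 2 Monte
Carlo folds, 15-epoch cap) asserted to finish within its budget. The
full-scale grids (432 CNN configurations, 5 folds, 100-epoch cap) are
enabled by `grid_scale="full"`.

## Known limitations

* The autodiff engine is single-threaded NumPy; full-scale grid searches
  are CPU-days, not CPU-minutes. The reduced grids exist for exactly
  this reason.
* The SELFIES codec covers the encoder's own output grammar, not
  arbitrary external SELFIES strings.
* The dissimilarity split requires slack in the pool: the study's exact
  partition sizes (3850/825/825 of 5500) assume selection from a larger
  source collection; on a self-contained pool the same criteria are
  applied at scaled sizes.
* One-hot encoding couples model width to vocabulary size for the
  Transformer (head count must divide V), so some head-count settings
  are unsatisfiable under one-hot — a documented consequence of feeding
  one-hot vectors directly into the first layer.
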