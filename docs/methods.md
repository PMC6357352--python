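# Methods

## Model

The predictor maps a sample's mutation vector m ∈ {0,1}^{G_m} and expression
vector e ∈ R_{≥0}^{G_e} (log2(TPM+1)) to a vector of log10 IC50 values over D
drugs. It is a composition of three dense feed-forward networks:

* a mutation encoder M_enc and an expression encoder E_enc, each the encoder
  half of a symmetric autoencoder pre-trained to reconstruct its omics matrix
  on a large unlabelled corpus;
* a prediction head P on the concatenated bottleneck activations, with one
  merging layer, three hidden layers and a D-unit linear output.

Every unit computes y = F(Σ w_i x_i + b) with F = ReLU except P's output
layer, which is linear so the network can fit the roughly symmetric
log-IC50 distribution. Weights are initialized from He's uniform
distribution U[−L, L], L = √(6/fan_in) (suited to ReLU), biases at zero.
All training minimizes mean squared error with mini-batch Adam
(defaults lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8); batch order is reshuffled
every epoch from the run seed, so runs are bit-reproducible given
(seed, batch size).

### Pre-training and architecture search

Autoencoder architecture (layer-1 width, layer-2 width, bottleneck width)
and batch size are selected by exhaustive enumeration of a grid — production
default {4096, 2048, 1024} × {512, 256, 128} × {64, 32, 16} × {128, 64},
54 candidates. Each candidate trains for a 20-epoch screen; the candidate
with the lowest reconstruction MSE on a held-out 10% corpus slice wins (ties
break toward fewer parameters, then lexicographically smaller widths), and
is re-trained for the long refit (default 100 epochs at production scale).
Because deep reconstruction networks on uncentered non-negative inputs
occasionally settle into poor basins, the refit can be repeated from several
fresh inits (`refit_restarts`), keeping the lowest evaluated loss; the
desk-scale default is 4 restarts. Whether screening scores the training
slice or the held-out slice is configurable; held-out is the default.

### Supervised phase

Samples are split 80/10/10 into train/validation/test (validation and test
sizes are round(fraction·n), remainder to training). The two encoders carry
their pre-trained parameters and remain trainable; P is freshly initialized.
Training is end-to-end; the validation slice is used only for early
stopping: after the best epoch, `patience` consecutive non-improving epochs
plus the detecting epoch end training (patience 3 ⇒ a loss that stops
improving after epoch 1 halts training at epoch 5). Improvement is strict
(any decrease resets the counter). The parameters at the stop are kept —
there is no rollback to the best epoch — matching the convention of early
Keras versions; `restore_best` is available as a flag. Test samples never
influence parameters; shuffling their labels leaves trained weights
bit-identical.

### Missing-response imputation

GDSC-style response matrices have missing (drug, sample) entries. They are
filled drug-wise: the distance between two drug rows is the root mean
squared difference over their pairwise-complete samples (Euclidean corrected
for the shared-sample count, so differing missingness patterns stay
comparable; +∞ when no sample is shared), and a missing cell takes the
weighted mean of the k = 5 nearest drugs observed at that sample, weights
1/(d + ε) with ε = 1e-9 (a `uniform` scheme is available). Imputed values
are convex combinations of neighbour values. The published pipeline
delegated this step to an external package whose metric is not documented;
the rule above is this package's explicit, configurable choice, and it is
verified against a brute-force reimplementation rather than claimed
bit-compatible with the original.

## Benchmark protocol

`run_benchmark` repeats, over `n_iter` fresh random splits: the pre-trained
model; a randomly initialized twin (identical architecture, He-uniform
encoders); a variant whose encoders are replaced by 64-component PCA
projections (loadings fitted on the training split only, to avoid leakage)
feeding the same head; expression-only and mutation-only variants (head
merging layer narrowed to one bottleneck); multivariate linear regression on
the merged mutation+expression principal components; and one RBF
support-vector regressor per drug on the same components (C = 1, ε = 0.1 —
the published comparison says only "regularized SVM"; hyperparameters are
exposed). Reported per model: median test MSE and median epochs consumed
(completed epochs at the early stop).

## Association analyses

The mutation–drug scan Welch-t-tests predicted IC50 between mutation
carriers and wildtype samples for every admissible (stratum, gene, drug)
triple. Admissibility: within-stratum mutation rate strictly above 10%, and
(in stratified mode) at least 10 carriers. ΔIC50 = mean(carriers) −
mean(wildtype); positive values mark resistance-associated mutations.
Welch's unequal-variance t-test is the default because carrier groups are
small and heteroscedastic; the pooled test is a flag. The Bonferroni family
is all tests performed in one scan invocation — the per-stratum scan adjusts
jointly across strata — and significance is adjusted P < 1e-5. A
(stratum, gene) whose carrier or wildtype group has fewer than 2 samples is
skipped with a warning. The family-size choice (global rather than
per-stratum) is this package's explicit reading of a single threshold
applied across all combinations.

Extreme-responder analysis takes, for one drug, the bottom and top
⌈fraction·n⌉ samples of predicted IC50 (default 1%; ties broken by stable
sample order), and reports: percent stratum composition per group; per-gene
mutation-rate differences (sensitive − resistant) ranked by absolute
difference; Welch t-tests on expression per gene ranked by raw P with ties
by |t| (the published analysis does not state its ranking score; raw P is
this package's choice), with a top-300 gene list and per-gene direction; and
the mean mutation burden within a gene subset. Expression z-scoring is
applied only for display, never for testing. Functional enrichment of the
ranked list is deliberately out of scope (external services).

## Synthetic data

The generator emulates the statistical skeleton of paired tumor/cell-line
pharmacogenomic cohorts without reproducing any real cohort's marginals:

* a k-dimensional latent state z per sample (k = 8), with small per-stratum
  mean shifts (3 strata) so cancer-type structure exists;
* expression e_g = max(0, a_g·z + μ_g + ε), loadings a_g ~ N(0, I/k)
  (so per-gene latent variance ≈ 1), noise sd 0.5, and offsets
  μ_g = 2·sd_g + U(0,2) chosen so ≥95% of pre-rectification values are
  positive — a log2(TPM+1)-like non-negative support without simulating
  read counts;
* mutations: independent Bernoulli, rate 0.05 for passengers and 0.30 for
  driver genes (4 drivers by default);
* response ic_d = β_d + u_d·z + Σ γ_{d,j} m_j + ε, with unit-scale latent
  loadings, additive driver effects γ = 1 log-IC50 unit on planted
  (gene, drug) pairs, noise sd 0.5, and 10% of entries masked at random;
* a 2000-sample corpus and a 300-sample cohort drawn from the same loadings
  and effects — the transferability the pre-training stage exploits. The
  null generator zeroes u and γ for type-I-error calibration.

What this does not emulate: mutation co-occurrence structure (mutational
burden, cancer-type-specific spectra), heavy-tailed expression marginals,
batch effects, and drug–drug correlation beyond the shared latent space.
Consequently the mutation autoencoder has nothing sample-specific to learn
from synthetic mutations (its reconstruction optimum is the per-gene rate),
which weakens the two-omics pre-trained model relative to what real
mutation data supports; passing transfer tests therefore demonstrate the
machinery and the expression-side benefit, not the full real-data effect.

## Desk-scale configuration

Default sizes (G_e = 300, G_m = 200, D = 30, corpus 2000, cohort 300) keep
every experiment at minutes on one CPU. The desk-scale encoder architecture
is 512/64/16 with batch 64: the first layer is kept at roughly twice the
supervised training-sample count, preserving the production setup's
over-parameterized regime, which is where pre-training materially helps;
the head uses 64/64/64 hidden widths on the 16+16 merged bottlenecks.
Pre-training uses lr 3e-3 (uncentered non-negative inputs traverse slowly at
1e-3 on a small corpus), a 20-epoch screen and a 200-epoch refit with 4
restarts for expression and 2 for mutations (the sparse binary matrix has a
flat reconstruction landscape). The supervised phase uses lr 1e-3, batch 64, max 100 epochs,
patience 3.

## Numerical choices and degenerate inputs

* Distances/weights: zero drug-row distances are guarded by ε rather than
  special-cased; cells with fewer than k valid neighbours use all available
  with a logged warning.
* Correlations of zero-variance vectors are reported as NaN with a warning
  rather than raising.
* The PCA encoder refuses n_components above the data rank.
* Non-finite inputs are rejected before training; a non-finite loss aborts
  with the epoch index.
* All randomness flows from explicit seeds through numpy Generators; grid
  search, splits, inits and batch orders derive sub-seeds from one stream.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; production-scale
  inputs (15k+ genes, thousands of samples) are out of its intended range.
* Only dense ReLU/linear layers are provided — no dropout, normalization or
  convolutional variants.
* Bonferroni is the only multiplicity correction, by design.
* The transfer benefit on synthetic cohorts is a few hundredths to ~0.15
  MSE at desk scale — real cohorts, with richer mutation structure and far
  higher dimension-to-sample ratios, are the regime where the gap widens.
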