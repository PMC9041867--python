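# Methods

This note documents the models, the training protocols, the synthetic study
worlds, and the numerical and design choices behind `peabrain`.

## The two-stage model of tissue transcription

The package treats the transcriptional machinery of a tissue as two nested
prediction problems.

**Stage 1 — mean abundance from the core promoter.**  For each gene, the
±2 kb window around the annotated TSS (the "core promoter", 4 kb total) is
encoded as a position × channel matrix: four one-hot DNA channels (fixed
order A, C, G, T; an N base is an all-zero column) plus one binary channel
per annotation track (epigenetic marks, regulatory elements).  Negative-
strand promoters are reverse-complemented so transcription always runs
left→right in the matrix, and annotation channels are flipped with the
sequence.  A 1D CNN maps this matrix to the gene's normalized mean
abundance in one tissue:

    [conv(11 filters × width 5, leaky-rectify slope 0.01) → max-pool] × 3
    → dropout(p = 0.5)
    → dense(1001, linear)      ← the gene-embedding layer
    → dense(1, linear)

With linear top layers the prediction is exactly a linear combination of
the 1001 embedding activations, which is what makes the penultimate layer
usable as a dense gene representation.  The leaky rectifier is
f(x) = x for x > 0 and 0.01·x otherwise.

**Stage 2 — individual differences from sequence differences.**  For one
gene, each individual's two haplotype sequences over a TSS-centred window
are reconstructed from a VCF by substituting alternate alleles into the
reference, one-hot encoded and *summed* (so the diploid DNA channels sum to
2 per column and phase is irrelevant).  The model input for a pair (A, B)
is the element-wise difference of the two diploid encodings and the target
is the difference of their normalized expression values; both directions
(A−B) and (B−A) are used during training, making the target function odd.
The network is conjoined from three subnetworks — upstream flank, core
promoter, downstream flank — each a conv/pool stack ending in a linear
dense layer; their outputs are concatenated, passed through one penultimate
dense layer (1001 units) and a single output neuron.  The core subnetwork
reuses the Stage-1 conv stack; the flank subnetworks use larger pool sizes.

## Training protocol

Both stages minimize mean squared error with Adam (learning rate 0.001,
β₁ = 0.9, β₂ = 0.999, ε = 1e-8), train for a minimum of 100 epochs, then
exit early once a held-out validation split (10% of training examples, or
10% of training *individuals* for Stage 2) has not improved for a patience
of 20 epochs (Stage 1) / 10 epochs (Stage 2), and restore the
best-validation checkpoint.  All randomness — weight initialization
(Glorot-uniform), example shuffling, dropout masks, splits — is drawn from
a generator seeded in the config, so runs are bit-reproducible.

Stage-1 performance is assessed by 10-fold cross-validation over genes;
Stage-2 and the elastic-net baseline use repeated (default 5, minimum 3)
95/5 individual-level splits: train on all directed pair differences among
training individuals, score cv-r² on all directed pair differences among
the held-out individuals.  cv-r² ≡ 1 − Σ(yᵢ−fᵢ)²/Σ(yᵢ−ȳ_test)², computed
against the *test-set* mean, so it is negative when the model has no
predictive ability.  A gene is "captured" when mean ± 1.96·SE over the
repeat cv-r² values lies entirely above zero.

The number of directed training pairs grows quadratically with cohort
size, so each Stage-2 epoch draws a fresh random subset of directed pairs
(`max_pairs_per_epoch`, default 128) from the training pool — plain SGD
over the pair universe; every pair is visited over the course of training
in expectation.  The validation and test pair sets are always exhaustive.

## Impact scores and variant effects

The **impact** of a promoter position is the absolute change in predicted
mean abundance when that position's entire input column (DNA *and*
annotation channels) is zeroed; no renormalization of neighbouring columns
is applied.  Positions inside several genes' promoters take the maximum
impact across genes; the **non-specific score** is the position-wise
arithmetic mean across tissue models, averaging over whichever tissues
score a position.  Impact is computed with a single designated trained
model (the best-validation checkpoint), not an ensemble.

A single variant is scored with a trained Stage-2 model by building
homozygous-reference and homozygous-alternate diploid encodings that
differ only at the variant and evaluating the (alt − ref) difference
sequence d.  The reported effect is the odd part of the network output,
(f(d) − f(−d))/2.  Direction-augmented training drives f towards an odd
function, for which this equals f(d); symmetrizing makes two contracts
exact rather than approximate: a ref/ref "variant" scores exactly 0 and
swapping ref and alt exactly negates the effect.

## Coordinate and indel conventions

Coordinates are 0-based half-open internally; VCF (1-based) and gene-model
TSS (1-based) are converted at the boundary; BED is native 0-based.  After
indel substitution each haplotype string is re-anchored at the TSS: the
upstream and downstream flanks are independently truncated or N-padded at
their *outer* edges back to the nominal flank length.  This preserves the
TSS-aligned difference semantics — a downstream indel cannot shift
upstream content, and positions keep their distance-to-TSS meaning.
Unphased heterozygotes place the alternate allele on haplotype 1
deterministically; the diploid sum is invariant to that choice.  Variants
spanning the TSS anchor, overlapping records, and alleles inconsistent
with the reference are hard errors.

## Normalization

Expression values are rank-transformed to normality as
Φ⁻¹((rank − 0.5)/n) with tie-averaged ranks.  Residualization fits
ordinary least squares per gene on an intercept, the supplied covariates,
and the leading expression PCs; PCs are computed on the
covariate-residualized matrix (the order is not fixed by convention; this
package residualizes first) and the smallest number of components whose
cumulative explained variance reaches the target (default 55%) is used.  A
target of 0 disables the PC block.  Residuals are rank-transformed per
gene afterwards.  Collinear design columns are dropped with a warning.

## Statistical harness

Enrichment of a per-variant or per-position score in a binary annotation
is tested by maximum-likelihood logistic regression of the label on the
score (optionally rank-normalized first, making the coefficient invariant
to monotone transforms) plus covariates, reporting the coefficient, a 95%
profile-likelihood interval (the points where the profile deviance crosses
χ²₁(0.95); Wald fallback with a warning if profiling fails) and the
two-tailed Wald p-value.  Perfect separation is flagged with an
infinite-CI sentinel.  The locus regression rank-normalizes both the mean
per-locus impact and the local SNP-heritability table before OLS, with
Bonferroni adjustment across tissues.  Variant tables are joined on the
canonical `chromosome_position_ref_alt_build` key.

## Synthetic study worlds

The generator writes standard formats (FASTA, TSV, BED, VCF) plus a
ground-truth table, and is byte-deterministic given its seed.

*Stage-1 world* (default 500 genes × 4 kb promoters): each promoter gets
0–4 planted copies of the motif `TGACGTCA` (reverse-complemented into the
genome for negative-strand genes) and, with probability 0.5, a 200 bp
"enhancer" interval recorded only as an annotation; mean expression is
1.0·(motif count) + 1.0·(enhancer state) + N(0, σ), σ = 0.25 by default
and 0 in the recovery suites.  Truth counts are re-scanned from the
emitted genome, so chance background occurrences are included.  Because
the enhancer state is invisible in the DNA letters, DNA-only (class-A)
models face a hard ceiling that DNA+annotation (class-B) models do not —
the basis of the annotation-ordering test.

*Stage-2 world* (default 60 unrelated individuals × 10 kb window × 50
biallelic SNPs): minor-allele frequencies uniform on [0.05, 0.5],
Hardy-Weinberg genotypes from independent allele draws, a causal subset
(20 in the effect-ranking suite) with βⱼ ~ N(0, 0.5), expression
Σβⱼ·dosage + N(0, 0.1), rank-normalized before modelling.

What these worlds deliberately lack: linkage disequilibrium, population
and relatedness structure, realistic motif grammars, indel-rich variation
(a simple indel path exists but is not simulated by default), and any
mapping/measurement noise.  Passing the recovery suites therefore shows
the machinery is correct and sensitive at desk scale; it does not certify
performance on real cohorts, where LD, confounding and weak effects
dominate.

## Desk-scale problem sizes

The reference-scale Stage-2 window is 1 Mb (0.48 Mb flanks, 4 kb core,
flank pool sizes 100/50/10).  The package defaults train on a 10 kb window
(3 kb flanks); flank pool sizes are scaled by the cube root of the
flank-length ratio — three pooling stages multiply, so this keeps the
final feature length comparable — and the actual values are recorded in
the model manifest (18/9/2 at 3 kb).  The Stage-1 conv stack uses three
blocks with pool sizes (10, 10, 5) for 4 kb input (a 4 kb window reduces
to 7 positions before the dense layers); for shorter demo windows the
examples pass proportionally smaller pools.  The acceptance script and the
heavy tests use: Stage 1, 500 genes with a 450/50 split; Stage 2, 60
individuals with three repeated splits; impact enrichment pooled over 12
motif-bearing promoters; elastic net, 100 individuals × 30 variants.

## Numerical choices

Float32 weights and activations; valid (unpadded) convolutions; pool
remainders truncated; inference always runs with dropout disabled and is
deterministic.  Max pooling ties break toward the first maximum
(`argmax`).  The training engine's backpropagation is verified against
float64 central finite differences in the test suite.  Empty elastic-net
models (all-zero weights) are legal and reported; constant dosage columns
are dropped with a warning.  The elastic-net mixing parameter is fixed at
0.5 with the regularization path chosen by 3-fold cross-validation on the
training pairs.

## Known limitations

Training is single-process NumPy on CPU: adequate for the 10 kb desk
scale, far from the compute needed for 1 Mb windows over hundreds of
genes.  The Stage-2 cv-r² at a 5% test fraction rests on very few test
individuals (3 of 60), so single-repeat values are noisy — hence repeated
splits and the captured-gene CI.  Saturation scans of all 3L substitutions
are possible through `variant_effect_stage2` in a loop but are not
productized.  GCTA/HESS-style heritability estimation, relatedness
filtering and upstream VCF quality control are consumed as inputs, never
recomputed.
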