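# icbscreen

Biomarker analysis for immune checkpoint blockade in non-small cell lung
cancer (NSCLC): Bayesian-NMF expression subtyping, SBS96 mutational-signature
extraction, per-sample genomic feature engineering, and an
association/survival screening harness — exercised end to end on synthetic
cohorts that reproduce the statistical structure the analysis assumes.

## Who this is for

Computational oncologists and statisticians who want a tested, reusable
implementation of a checkpoint-blockade biomarker workflow: deriving
microenvironmental (M) and tumor-intrinsic (TI) expression subtypes,
decomposing mutation catalogs into signatures, computing the standard
exome-derived response features (TMB, clonal/subclonal burden, neoantigen
binders, receptor burden, metagene scores), and screening everything
against best overall response (BOR) and progression-free survival (PFS).
The original patient data are controlled-access; the package ships a
synthetic-cohort generator so every stage runs, and is tested, without any
data download.

## The core methods

**ARD-NMF.** A nonnegative matrix `V` (genes × samples, or SBS96 channels ×
samples) is approximated by `W·H` under automatic relevance determination:
each component `k` has a relevance scale `λ_k` (inverse-gamma hyperprior)
shared by `w_k` and `h_k` through an exponential or half-normal prior.
Multiplicative updates minimize

    D(V | WH)/φ + Σ_k [ (f(w_k) + f(h_k) + b)/λ_k + c·log λ_k ],

with `D` Frobenius (expression, consensus matrices) or generalized KL
(mutation counts).  Components whose relevance collapses are pruned; the
surviving count `K_eff` is the effective rank.  Rank selection uses the
ARD phase; reported factors are maximum-likelihood refits at that rank.

**Subtyping.**  Filter genes (differential expression `p < 0.05`,
`|log2FC| > 0.5` for the M variant; top high-variance genes for TI), drop
sparse/low genes, median-center, then consensus-cluster resampled subsets
on 1 − Spearman distance for K = 2..10 (500 iterations each).  The summed,
normalized consensus matrix is factorized with a half-normal-prior B-NMF;
its effective rank is the cluster number K.  The expression matrix is then
factorized at that K, samples are assigned by argmax of normalized H,
marker genes are read off the W matrix (top 50% of normalized weights,
positive in-minus-out expression difference), and held-out samples are
classified by NNLS projection onto the marker weights.

**Screening.**  Univariate logistic regression of each feature on binary
response (CR/PR vs SD/PD), Wald CIs, Benjamini–Hochberg FDR with tiers
q < 0.1 (significant) and q < 0.25 (near-significant), a ≥5% prevalence
filter for binary features, log-transformed burdens; KM/log-rank for
binned features; hypergeometric over-representation and Mann–Whitney
set-significance comparisons; cross-correlation feature blocks.

See `docs/methods.md` for every default and design decision.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py 1      # seed 1
python analysis/02_expression_subtypes.py 1
python analysis/03_mutational_signatures.py 1
python analysis/04_genomic_features.py 1
python analysis/05_response_screen.py 1
python analysis/06_survival_and_integration.py 1
```

With seed 1 the simulation prints

```
simulated 120 samples, 800 genes; response rate 0.36; median TMB 4.1/MB
```

— a cohort of 120 tumors with three latent expression programs, in which
membership in the first program and higher TMB raise the odds of response
(overall response rate 36%).  Signature extraction reports

```
extracted K_eff = 7 signatures from 200 samples
```

and labels all seven against the packaged synthetic reference set at
cosine similarity ≥ 0.997 (including the aging-like, smoking-like and
APOBEC-like spectra).  The response screen then recovers the generative
structure:

```
             odds_ratio  ci_low  ci_high       p       q         tier
subtype_M-1      6.1185  2.6957  13.8871  0.0000  0.0001  significant
subtype_M-2      0.1217  0.0433   0.3423  0.0001  0.0003  significant
```

Membership in the response-favorable subtype multiplies the odds of
response by ~6; the resistant subtype divides them by ~8; both survive BH
adjustment at q < 0.1.  The survival screen flags the same subtype split
(log-rank q = 0.03) and median-binned TMB (q = 0.06), and the integrative
step groups the four mutation-burden features into one correlation block.

The same stages are available as a CLI (`icbscreen simulate|factorize|
subtype|signatures|features|associate|survive|integrate|run`) and as
library functions under `icbscreen.*`.

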