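# Methods

This note documents the models and procedures implemented in `icbscreen`,
the choices made where the underlying methodology leaves them open, and
what the synthetic cohorts do and do not establish.

## The analysis in one paragraph

The package reimplements a biomarker-discovery workflow for immune
checkpoint blockade in non-small cell lung cancer: bulk expression cohorts
are organized into microenvironmental (M) and tumor-intrinsic (TI) subtypes
by consensus clustering plus Bayesian NMF; somatic mutation catalogs are
decomposed into SBS96 signatures with automatic relevance determination;
per-sample genomic features (mutational burden, clonality, neoantigen
binders, receptor burden, metagene scores) are derived with fixed published
rules; and each feature is screened against best-overall-response and
progression-free survival with multiplicity control.  The original cohort
is controlled-access, so a synthetic-cohort generator reproduces the
statistical structure each stage assumes and every result in this
repository is computed on simulated data.

## ARD-NMF engine

`V ≈ W H` with `W (F×K_max) ≥ 0`, `H (K_max×N) ≥ 0`.  Component `k`
carries a relevance scale `λ_k` with an inverse-gamma(a, b) hyperprior;
columns of `W` and rows of `H` share that scale through an exponential
(L1) or half-normal (L2) prior.  The MAP objective is

    C(W,H,λ) = D(V|WH)/φ + Σ_k [(f(w_k)+f(h_k)+b)/λ_k + c·log λ_k]

with `f(x)=Σx, c=F+N+a+1` (exponential) or `f(x)=½‖x‖², c=(F+N)/2+a+1`
(half-normal).  `D` is the Frobenius divergence (Gaussian noise; used for
expression and consensus matrices) or generalized Kullback–Leibler
(Poisson noise; used for mutation counts).  Optimization alternates
multiplicative majorization–minimization updates of `W` and `H` with the
exact minimizer of `λ`, so the recorded objective trace is non-increasing.

Choices that the methodology leaves open, fixed here:

- **Hyperparameters.** `a = 10`; `b` is data-driven so the hyperprior mode
  of `λ` matches the per-component scale implied by `mean(V)/K_max`.
- **Dispersion φ.** `φ = 1` for Poisson counts.  For the Gaussian case
  `φ = 0.2·max(var(V), mean(V)²)`; this fraction was calibrated on
  structured low-rank matrices and block consensus matrices so that
  components whose energy is far above the resampling-noise floor survive
  while noise-level components are pruned.  φ is exposed as a parameter.
- **Pruning.** A component is inactive when its mass `‖w_k‖₁·‖h_k‖₁`
  falls below 1% of the largest.  Pruning is applied during optimization
  (a near-dead component is zeroed only when doing so lowers the penalized
  objective, preserving monotonicity) and K_eff is the count of surviving
  components.
- **Debiasing refit.** The ARD prior shrinks `W` and `H`; after rank
  selection the surviving components are refit by plain multiplicative
  updates with the prior off (maximum-likelihood at the selected rank).
  Rank selection and the reported posterior come from the ARD phase; the
  reported factors come from the refit.  In multi-restart runs only the
  selected run is refit.
- **Restart selection.** Among converged restarts, the modal `K_eff` is
  found first; among runs at that rank the one with maximal posterior is
  returned.  Ties between equally frequent ranks go to the rank whose best
  run has the higher posterior.
- **Tolerances.** Relative objective change `< 1e-7` declares convergence;
  `max_iter = 1e5`; division floors at `1e-10`.
- **Scale identifiability.** Reported `W` columns are normalized to sum 1
  with the scale moved into `H`.

## Expression subtyping

The M pipeline: keep genes with differential-expression `p < 0.05` and
`|log2 FC| > 0.5` (both strict); drop genes with more than 10% NA-or-zero
values or mean expression in the bottom decile; subtract each gene's
median (fold changes); compute the sample–sample Spearman correlation;
hierarchically cluster 500 resampled subsets for each K in 2..10,
recording co-clustering frequencies; sum the consensus counts over K and
divide by the total iteration count; determine K as the ARD effective rank
of that summed matrix under the half-normal prior with multi-restart modal
selection; factorize the filtered expression matrix at that K; keep, per
cluster, genes in the top 50% of normalized W weights owned by that
cluster with a positive within-minus-outside mean difference, ranked by
that difference (50 per cluster by default); classify held-out samples by
nonnegative least squares against the marker weight matrix with argmax
assignment (ties to the lowest cluster index).  The TI variant replaces
the DE seed list with the top 2,000 high-variance genes of a reference
collection (capped at the gene count when the matrix is smaller) and
requires at least 100 reference samples.

Open details fixed here: each consensus iteration subsamples 80% of
samples without replacement; linkage is average; "normalized weights"
means W columns scaled to sum 1; cohort-2 classification is NNLS
projection; clusters are named M-1../TI-1.. in decreasing training-size
order.  The summed consensus matrix is consumed directly by the B-NMF.

**Membership factorization at fixed K.**  The ARD posterior on a raw
log2(TPM+1) matrix prefers solutions in which one component carries the
expression baseline shared by all samples, which can merge two genuine
programs at K equal to the program count.  Because K is already fixed by
the consensus step, the membership factorization selects among restarts by
reconstruction fit at that rank, and adds one warm-started candidate whose
H is initialized from the hierarchical co-clustering labels and whose W
columns start at cluster centroids.  On noiseless synthetic cohorts this
recovers the generating partition exactly; it is a package design choice,
documented here because the source procedure does not specify the
initialization.

## Mutational signatures

Extraction runs ARD-NMF (Poisson divergence, exponential prior, `K_max =
15`) on the channels × samples catalog from 20 random initializations and
keeps the modal-rank, maximum-posterior run.  Extracted signatures are
labeled with the reference signature of maximal cosine similarity when it
reaches 0.8, else "unassigned".  Per-sample attributable burden is the
sample's H column normalized to proportions times its total mutation
count, so attribution conserves totals exactly; a zero-mutation sample
receives zeros.  "Relative projection strength" is read as normalized H;
re-fitting NNLS per sample against the final W is a noted alternative that
is not the default.  Cohort pooling is plain catalog concatenation.

## Genomic features

- TMB: `ln(events/MB + 1)` over nonsynonymous SNVs, DNVs and indels; the
  raw rate per MB is kept for binning (e.g. the >10 mut/MB high bin).
  The exome territory defaults to 33 MB — the size of a conventional
  exome capture, exposed as configuration since captures differ.
- Clonality: a variant is clonal iff its CCF cluster exceeds 0.85
  (strict); subclone count is the number of distinct CCF clusters.
- Neoantigen binders: peptides whose best percentile rank across the
  patient's class-I alleles is ≤ 2, deduplicated per peptide; a
  per-variant collapse is available behind a flag.
- Receptor burden: `(rearranged reads + 1)/(aligned reads/1e6)`, natural
  log for testing.
- Metagene scores: per-sample mean of log2 TPM over the set's present
  genes, z-scored across samples with `ddof = 1`.
- The immunoproteasome set is fixed: PSMB8, PSMB9, PSMB10 (inducible
  catalytic subunits) plus PSME1, PSME2 (PA28 α/β activator).

## Statistical harness

Differential expression is a gene-wise Welch unequal-variance t-test on
log2 values with BH adjustment — an intentional stand-in for a moderated
linear model, whose internals are out of scope; the expression filter
(coding genes at log2TPM ≥ 0.5 in ≥ 30% of samples) precedes it.  The
response screen fits one logistic model per feature (intercept + feature),
reporting `OR = exp(β)`, Wald 95% CI and two-sided Wald p, BH q across the
screened family, and tiers q < 0.1 / q < 0.25; burden features enter
log-transformed; binary features below 5% prevalence are excluded;
perfectly separated features are flagged with infinite-CI sentinels and
excluded from the BH family.  Gene-set over-representation is the
upper-tail hypergeometric probability.  Gene-set significance comparison
is a two-sided Mann–Whitney U on per-gene `−log10 p` scores (signing by
fold-change direction is optional), exact for small sets.  The bivariate
cytokine model is OLS `y ~ 1 + x1 + x2` with univariate comparators.
Survival features are binned (z-scores at 0, burdens at the cohort median
with ties to low, cluster membership vs rest, alterations by presence) and
compared by two-group log-rank with KM medians and BH across the screen.
Integrative clustering is average-linkage on 1 − Spearman cross-correlation
with constant features dropped.

## Synthetic cohorts

`m_default`: 120 samples × 800 genes, three equiprobable latent programs,
60 markers each, +2.0 log2 marker effect, gene-level Gaussian baseline
(mean 3.0, sd 1.0), noise sd 0.6, 5% dropout.  `ti_default`: 220 samples ×
1,000 genes, four programs emulating lineage blocks, same effect sizes.
`sig_default`: 200 samples, 500–2,000 mutations each, sparse Dirichlet
exposures over at most 4 of 7 synthetic reference signatures; three
references imitate the geometry of aging-like (C>T at CpG), smoking-like
(C>A-heavy) and APOBEC-like (C>T/C>G at TpC) processes so labeling is
exercised — they are synthetic stand-ins, not COSMIC signatures.  Variant
tables draw per-sample mutation rates log-normally (sd 0.8 on the log
scale) around 150 events because real tumor mutational burden spans orders
of magnitude; clinical outcomes use a logistic link on named truth
features, CR/PR vs SD/PD splits consistent with the binary response,
exponential PFS (median 12 months for responders, 3 for nonresponders) and
independent exponential censoring.  Program effects are additive on the
log2 scale; PFS is exponential because only rank-based tests consume it.

What the generator does not emulate: gene–gene correlation beyond program
blocks, compositional/library-size artifacts, batch effects, overlapping
program membership, signature-count correlation with clinical features,
and real marginal distributions of the controlled-access cohort.  Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own assumptions, not that it would recover the published
cohort's biology.

## Problem sizes and determinism

Recovery experiments run 10 independent cohort draws per scenario with 100
consensus iterations per K and 10 B-NMF restarts (20 for signature
extraction), sizes chosen so a complete run finishes in a few minutes on
one CPU while keeping the Monte-Carlo error of the recovery fractions
small.  All randomness flows from a single master seed through
SHA-256-keyed `numpy.random.SeedSequence` splits, so every stage is
bit-reproducible given the seed.

## Known limitations

- The Welch-test DE stand-in is less powerful than a moderated model at
  small n; its role here is gene ranking, not inference.
- ARD rank determination depends on the dispersion φ; the default is
  calibrated for consensus matrices and count catalogs, and sharply
  different data scales may need an explicit φ.
- Response-focused DE filtering can split a response-neutral expression
  program on noise genes (seen in the demo cohort, where the determined K
  exceeds the generating program count while the response-relevant
  programs are still recovered cleanly); the packaged recovery experiments
  filter genes only on quality, where the cluster number is recovered
  reliably.
- Wald inference for the logistic screen; profile-likelihood CIs are a
  noted extension.
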