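# Methods

This note documents the models implemented in `mirqtl`, the defaults and why
they were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Synthetic cohort generator

**Genotypes.** Each LD block draws two haplotypes per sample from a latent
AR(1) Gaussian process with parameter ρ ∈ (−1, 1); a haplotype carries the
effect allele where the latent value falls below the allele-frequency
quantile, and the dosage is the sum of the two haplotypes (hard 0/1/2 counts;
imputation uncertainty is not modelled). This gives monotonically decaying
LD r² within a block, exact independence across blocks, and an analytic
handle for tests. Effect-allele frequencies are drawn uniformly from the
block's MAF range (default 0.05–0.5). Allele pairs are non-palindromic by
default so harmonisation is exercised separately and deliberately. A cohort
simulated from an existing variant table shares ids, alleles, frequencies and
LD layout — that is how independent replication/biobank cohorts are made.

**Expression.** miRNA levels (log2-CPM scale) are Σβ·dosage + covariate
terms + N(0, σ²). The covariate set mirrors the discovery design: age
(N(65, 8²) years), sex, two sub-cohort indicators, five PCs (standard
normal, drawn independently of genotypes — the generator does not model
population structure, so PCs act as pure nuisance covariates). The residual
SD defaults to 1.0; the residual variance structure of plasma miRNA levels
is not something the source data pin down, so it is an explicit parameter
rather than a constant.

**Phenome.** Case status per phecode is Bernoulli with
logit = logit(prevalence) + effect·z(score). With a nonzero effect the
realised marginal prevalence deviates slightly from the nominal value (the
intercept is set at score = 0); at the effect sizes used this is negligible.

**Two-trait regional tracks.** `export_two_sample_stats` simulates two
*individual-level* cohorts on one variant grid and scans each marginally, so
SEs, LD-induced signal spread and sampling noise are genuine rather than
drawn from an assumed covariance. Scenarios: `shared` (one causal variant in
both traits), `distinct` (two causal variants with LD r² < 0.05; an error is
raised if the region cannot host them), `null`.

**Mediation panels.** The generator emits an exposure-instrument panel whose
per-instrument effects follow the path algebra (mediator track bx·θ_EM,
outcome track bx·(θ_direct + θ_EM·θ_MO), plus noise at the stated SEs) and an
independent mediator-instrument panel (outcome track gm·θ_MO). The second
panel exists because θ_MO is not identified from exposure instruments alone:
their outcome/mediator ratio estimates (θ_direct + θ_EM·θ_MO)/θ_EM. Defaults
(θ_EM = θ_MO = 0.7, θ_direct = 0.51, J = 10 per panel, |bx| ∈ [0.1, 0.3],
SEs 0.01/0.02) encode a well-powered cis-instrument setting in which the
mediator carries 49% of the total effect — the benchmark structure for the
mediation analysis.

**What the generator does not emulate.** Sequencing-count noise in CPM,
LLOQ-driven missingness, recombination maps, population structure and
relatedness beyond GRM sampling noise, imputation dosage uncertainty.
Passing tests therefore demonstrate correctness of the estimators under the
generative model they assume, not robustness to assay artefacts.

## eQTL scan

Per (miRNA, variant): OLS of expression on dosage + covariates + intercept.
Implementation residualises phenotypes and dosages on the covariate block
once and runs per-variant simple regressions on the residuals
(Frisch–Waugh), which reproduces the full-model dosage coefficient, SE and
t exactly; a test asserts equality with statsmodels OLS to 1e-10. p-values
are two-sided from t with df = n − (covariates + 2); no normal
approximation. Monomorphic variants (sample MAF < 1e-4) are skipped and
counted, never emitted as NaN rows. The cis window is ±500 kb around the
mature-miRNA start, boundary inclusive (the convention here; the window is
a parameter). Variance explained is t²/(t² + df), the squared partial
correlation. The matrix-decomposition speed-ups used by high-dimensional
GWAS frameworks are deliberately not reproduced — plain per-variant OLS has
the identical estimand at desk scale.

## Harmonisation and replication

Tracks are joined on variant id; swapped alleles flip β sign and EAF;
palindromic (A/T, C/G) variants are dropped by default because strand cannot
be resolved, with an optional EAF-based rescue (keep when both |EAF − 0.5| >
0.08 — the margin where frequency orientation is reliable). Harmonisation is
involutive (tested). Replication: p < 0.05/m_tested in the independent
cohort **and** concordant β sign.

## Conditional/joint stepwise selection

Marginal per-dosage effects move to the standardised-genotype scale via
var(g) = 2·eaf·(1 − eaf); the standardised marginal effect is
b̃ = z/√(n + z²). With X'X = nR (LD correlation R from the reference panel),
the joint model over a set S is b_S = R_S⁻¹ b̃_S with residual variance
updated from 1 − b_S'b̃_S at each step. Selection starts from the smallest
marginal p and repeatedly adds the candidate with the smallest conditional p
(its Wald χ²(1) p in the joint model including the candidate) while that p
is below the threshold (default 2.4×10⁻¹¹); candidates with LD r² > 0.9 to
any selected variant are never eligible. Per-variant sample-size differences
within a region are ignored (single-cohort use; the median n is used).
Non-PSD LD inputs are projected to the nearest PSD correlation with a
warning. The assessment window is a parameter (default 1 Mb around lead
signals — the conventional choice where sources conflict). A from-scratch
oracle implementation (naive linear algebra per step) agrees on 200 random
instances of up to 10 variants.

## Genomic risk loci

Greedy p-ordered clumping (ties: smaller p, then smaller position) at
r² < 0.6 yields independent significant variants; re-clumping at r² < 0.1
yields leads. Each independent significant variant spans an LD block (the
extent of significant variants at r² ≥ 0.6 with it); blocks on a chromosome
merge when separated by ≤ 250 kb. Locus lead = smallest-p member; the locus
set is invariant to input order and loci are disjoint (both tested).

## Heritability

GRM: A_jk = (1/M)·Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1 − p_i)) over
variants passing MAF ≥ 0.1 (and INFO ≥ 0.5 when an INFO vector is supplied);
allele frequencies are taken from the sample. Relatedness filtering removes,
greedily, the sample participating in the most above-cutoff pairs until none
remain (default cutoff 0.025 — appropriate for genome-scale M; at small
simulated M, off-diagonal noise ~1/√M makes a proportionally larger cutoff
necessary, as the demo script notes). h² is the Haseman–Elston regression
slope of standardised-residual cross-products on off-diagonal GRM entries,
clipped to [0, 1] for reporting with the raw value retained. This moment
estimator targets the same estimand as score-based fast heritability
methods — narrow-sense SNP h² — and carries the same permutation-p
semantics: p = (1 + #{permuted ≥ observed})/(n_perm + 1) under
phenotype-label shuffling (default 1,000 permutations; covariates are
residualised out before everything else, so the choice of including PCs is
a flag on the caller's covariate table).

## Colocalisation

Wakefield log-ABF per variant: with V = se² and z = β/se,
lABF = ½[ln(V/(V+W)) + z²·W/(V+W)] — the exact log marginal-likelihood ratio
of b ~ N(0, W) against b = 0 (verified against quadrature to 1e-6).
Hypothesis sums run in log space (log-sum-exp), so |z| up to 50 cannot
overflow; the H3 term uses Σᵢ L1ᵢ·Σⱼ L2ⱼ − Σᵢ L1ᵢL2ᵢ computed via log1p.
Priors default to the field convention p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (only the
PP.H4 > 0.7 decision rule is externally fixed; the priors are assumptions
and are parameters). Effect-prior variances default to (0.15·sd)² for
quantitative traits and 0.2² on the log-odds scale for binary traits.
Variants missing from either track are intersected away and counted.

## PheWAS

Phecode case = at least one mapped ICD occurrence (no multiple-occurrence
threshold; none is externally specified). Optional per-phecode exclusion
ranges turn would-be controls with a related diagnosis into excluded
samples. Instruments: BH within the cis window, survivors at q < 0.1
clumped by ascending p at r² < 0.1, weights = discovery β. GRS =
Σ weight·dosage with allele alignment (swapped coding contributes
2 − dosage; a GRS is therefore identical up to a constant shift, which the
standardisation before regression removes). Logistic regression per phecode
with ≥ 200 cases; scores standardised so effects are log-odds per SD,
matching MR scaling. Perfect separation is flagged and reported as missing —
no penalised fallback is silently applied. BH FDR within each score's
result set.

## Mendelian randomisation

Ratio form throughout: r_j = by_j/bx_j, w_j = (bx_j/se_by_j)² (equivalent to
weighted regression through the origin; equivalence is tested). IVW-MRE
(the main model) inflates the FE SE by max(1, √(Q/(J−1))). Egger orients
bx ≥ 0 first and scales both SEs by max(1, √(RSS_w/(J−2))) with t(J−2)
tests. Weighted median: interpolated weighted order statistic; SE by seeded
parametric bootstrap (default 5,000 draws). Correlated-instrument IVW: GLS
with Ω = D ρ D; a singular Ω receives a 1e-8 ridge with a warning.
MR-PRESSO: observed weighted RSS around leave-one-out estimates versus a
parametric null rebuilt inside each of ≥1,000 simulations; outlier p-values
Bonferroni-corrected; the distortion test is not implemented (outlier
detection plus re-run is the supported workflow). MVMR: WLS without
intercept; condition number > 1e8 errors naming the most collinear exposure
pair. MR-BMA: exhaustive enumeration over exposure subsets (capped at
K = 12), conjugate Gaussian effect prior (default variance 0.25) and
independent inclusion prior (default 0.1); marginal likelihoods evaluated in
precision space and verified against a multivariate-normal oracle.
Bidirectional MR warns when instrument sets overlap. MR requires J ≥ 3
(robust estimators need the degrees of freedom); with one instrument the
Wald ratio is the designated tool. Steiger-style directionality filtering is
not applied.

**Mediation.** θ_indirect = θ_EM·θ_MO, proportion = θ_indirect/θ_total.
CI by delta method by default — the gradient-based variance is accurate when
θ_total is well separated from zero — with a seeded parametric bootstrap as
the alternative; both are reported by the analysis driver since the right
choice depends on how noisy the total effect is.

## Pipeline and determinism

Stages communicate through TSV; every stage derives its RNG seed from the
global seed; the manifest records parameters, per-stage counts (variants
skipped, records dropped, phecodes excluded, routing decisions) and SHA-256
hashes of all artifacts. Re-running a config with the same seed is
byte-identical (tested). The decision tree routes each miRNA by instrument
count: 1 → single-variant PheWAS, ≥2 → GRS PheWAS, ≥3 → MR; skips are
recorded with reasons.

## Problem sizes used in the test and acceptance suites

Chosen to make every check sharp yet quick on one CPU: IVW calibration
1,000 replicates (J = 10, θ = 0.3); Q null 2,000 replicates; contamination
comparison 500 replicates; COJO oracle 200 instances (≤10 variants);
colocalisation 100 replicates per scenario at n = 8,000 and causal-variant
z ≈ 8; heritability recovery n = 2,000, M = 5,000, 20 phenotype replicates
per h² level on one genotype panel (genotypes fixed, phenotypes redrawn —
valid under the generative model and much cheaper than re-simulating
genotypes); permutation-p uniformity n = 300, M = 1,000, 100 replicates of
99 permutations; MR-PRESSO 100–200 replicates of 1,000 simulations; FDR
checks 300 replicates (instrument selection) and 30 replicates (logistic
PheWAS) with 10 planted true signals so the realised false-discovery
proportion has usable variance.

## Known limitations

- The HE heritability estimator is less efficient than REML; its permutation
  p is exact under exchangeability but the point estimate can leave [0, 1]
  in small samples (hence the reported raw value).
- Single-causal-variant colocalisation: regions with allelic heterogeneity
  dilute PP.H4; no SuSiE-style decomposition.
- The COJO reconstruction assumes the LD reference matches the association
  cohort and ignores per-variant n differences.
- Logistic PheWAS has no small-sample correction; separation is reported,
  not repaired.
- The generator's PCs are pure noise covariates; confounding by population
  structure is not simulated, so the scan's robustness to stratification is
  untested here.
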