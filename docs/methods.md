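# Methods

This note documents the statistical models implemented in `autozyg`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Pedigree inbreeding and kinship

Pedigrees are validated directed acyclic parent maps; parsing accepts
whitespace-separated `id sire dam [cohort]` with `0`/`NA` for unknown parents,
auto-adds referenced-but-unlisted parents as founders, and reports a named
individual when a cycle is present. Kinship is computed by the classical
recursion φ(a,a) = (1 + φ(s_a, d_a))/2 and φ(a,b) = (φ(s_a,b) + φ(d_a,b))/2
(recursing through the individual later in topological order), memoized; the
full matrix is built by the equivalent tabular pass in O(n²). F_ped of an
individual is the kinship of its parents. An unknown parent contributes zero
kinship — i.e. it is assumed unrelated and non-inbred, so individuals with
incomplete ancestry have downward-biased F_ped. This is deliberate: the bias
is exactly the phenomenon the estimator comparison quantifies. Ancestry
completeness is classified into nested tiers (no parents, one parent, both
parents, both parents plus ≥1 maternal grandparent, all four grandparents);
analyses filter on a minimum tier.

## Genotype QC and LD pruning

Dosages are stored per individual × marker as 0/1/2 with −1 for missing
calls; reference-allele frequencies use non-missing calls only. QC removes
individuals with call rate ≤ 0.95 first, then markers with MAF < 0.01, call
rate < 0.99, or exact Hardy–Weinberg P < 1e-5, all evaluated on the retained
individuals. The HWE test conditions on allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one (no mid-p); probabilities are computed in log space with a gammaln
expression, stable at extreme thresholds, and the test matches a brute-force
enumeration oracle exactly in the test suite.

LD pruning slides a window (default 50 SNPs, step 5) along each chromosome
after dropping MAF < 0.05 markers, and iteratively removes the marker with
the largest variance inflation factor (diagonal of the inverse window
correlation matrix; missing calls mean-imputed for this purpose only) until
all VIF ≤ 10, dropping the later marker on ties, which makes the result
deterministic in marker order. Singular windows (duplicated columns) are
handled by a least-squares fallback that assigns them infinite VIF.

## Genomic inbreeding estimators

* **F_hom**: homozygous non-missing calls / non-missing calls.
* **F_GRM**: mean over non-missing polymorphic markers of
  (x² − (1+2p)x + 2p²) / (2p(1−p)). Its expectation is 0 in a
  Hardy–Weinberg population; monomorphic markers are a hard error (QC first).
* **ROH / F_ROH**: scanning-window caller. Windows of 5 consecutive SNPs
  (capped at 200 Mb span) are homozygous iff they contain 0 heterozygous and
  ≤ 2 missing calls; a SNP is a hit iff ≥ 5% of the windows overlapping it
  are homozygous; maximal hit runs are split at inter-SNP gaps > 1 Mb and
  kept iff ≥ 15 SNPs, ≥ 5 Mb, and ≤ 275 kb per SNP on average. The hit
  proportion (not part of the published parameter list) uses the conventional
  default 0.05 and is configurable. Windows near chromosome ends simply
  overlap fewer windows; the hit fraction is taken over existing windows.
  F_ROH divides summed segment length by the assayed genome length, a map
  attribute that defaults to the 2,434,125 kb autosomal span of the emulated
  SNP chip (the source constant is interpreted as kilobases — a ~2.4 Mb sheep
  autosome set is not physical — and is configurable). The expected length of
  a segment descending from a common ancestor g generations back is
  exponential with mean 1/(2g) Morgans, i.e. 100/(2g) Mb at 1 cM ≈ 1 Mb;
  `expected_roh_length_mb` exposes this, and the ROH caller's output from
  gene-dropped full-sib matings reproduces the Exp(25 Mb) tail for g = 2
  (KS check in the acceptance suite, restricted to segments away from
  chromosome ends, which are censored).

## Identity disequilibrium g2

g2 measures the excess probability of joint heterozygosity at two loci
relative to independence — positive when inbreeding varies among
individuals. With h_il the heterozygosity indicator (0 at missing calls),
over ordered pairs of distinct loci (l, k):

    m_within  = mean over pairs of (1/n)      Σ_i   h_il h_ik
    m_between = mean over pairs of (1/(n(n−1))) Σ_{i≠j} h_il h_jk
    g2 = m_within / m_between − 1

Both pair sums collapse exactly to row/column-sum identities (Σ_i r_i², Σ_l
s_l², total T), so the estimator, the bootstrap over individuals (SE), and
the permutation test (each locus column permuted independently across
individuals; upper-tail p with the +1 correction) all run in O(nL) per
replicate. A `pairwise_complete=True` variant excludes individuals missing at
either locus of a pair (O(nL²)); the two agree exactly on complete data and
differ negligibly at the default 0.1% missingness. Loci with no observed
heterozygotes carry no information and are dropped with a warning; a
non-finite ratio (e.g. duplicated individuals at n = 2) is flagged as
degenerate. Heterozygosity–heterozygosity correlations split the panel into
random halves and correlate per-individual F_hom/F_GRM between halves,
summarising marker-panel sufficiency.

## Mixed models

**Animal models (continuous traits).** y = Xβ + Σ Z_k u_k + e with
u_k ~ N(0, σ²_k K_k): year of birth (K = I), additive genetic (K = A, the
numerator relationship matrix = 2 × kinship over the phenotyped ids),
maternal genetic (dam-indexed, K = A over dams) and maternal environment
(dam-indexed, K = I). β includes an intercept, individual F, maternal F and
covariates (sex by default); aliased columns are dropped by a rank-revealing
QR. Variance components are estimated by REML with average-information
updates, step-halved to preserve the likelihood and non-negativity, with a
multiplicative EM-style fallback (σ² ← σ²·(y'PG Py)/tr(PG)) whose fixed point
is the score equation; components are clamped to zero at the boundary. Start
values split the phenotypic variance equally over all components. Convergence
is declared at a relative REML-likelihood change < 1e-8 (max 200 iterations);
non-convergence sets a flag rather than raising. Fixed effects get Wald
z-statistics and 95% intervals from (X'V⁻¹X)⁻¹. Dense n×n algebra is used
throughout — appropriate for the few-thousand-record scale this package
targets.

**Fitness GLMMs.** First-year survival and annual survival are
binomial-logit; annual breeding success is Poisson-log; models are fitted
separately per sex, with year (and an individual effect for repeated annual
records) as random intercepts. Fitting is penalized quasi-likelihood: IRLS
working responses and weights passed to the REML engine with the residual
variance fixed at 1, warm-starting variance components between outer passes.
Wald 95% intervals are reported. This is a deliberate frequentist replacement
for MCMC fitting of the same fixed/random structure: parameter recovery and
calibration on synthetic data, not posterior reproduction, are the
validation targets. PQL's known attenuation for binary data is small at the
simulated random-effect variances (≤ a few percent of the slope) and is
absorbed by the coverage checks. Complete separation is detected via extreme
linear predictors and flagged.

**Effect conversions.** Percent trait change per ΔF:
100·|β|·ΔF/mean. Odds-scale survival reduction per ΔF:
100·(1 − exp(ΔF·β)). Birthweights are age-corrected by regressing capture
weight on a cubic in capture age over records taken within 10 days of birth
(later captures excluded; ≥ 8 records required) and keeping the residuals.

## Synthetic-data generator

The generator's defaults are the study conditions used in all tests:

* **Population**: 10 birth cohorts on top of 60 + 30 founders, 140 offspring
  per cohort (~1,500 individuals), both sexes reproductive from age 1 to 6.
  Sires are drawn with geometric weights calibrated so the top 20% of
  available males father 80% of offspring (strong polygyny); with probability
  0.05 a dam instead mates a relative with kinship ≥ 0.125 when one is
  available, producing occasional close inbreeding over a background of drift
  relatedness. Roughly a third of individuals end up with nonzero F_ped,
  comparable to a complete multigeneration pedigree of a small closed
  population.
* **Genome/markers**: 26 autosomes × 10 cM at 1 cM ≈ 1 Mb, 3,000 SNPs on a
  near-regular grid with ±30% spacing jitter (≈87 kb spacing). The genome is
  deliberately ~10× shorter than a real ungulate autosome set so a desk-scale
  marker count preserves SNP-chip marker density — the regime the ROH
  caller's density filter presumes (pruned-panel spacing ≈190 kb). The map in
  Morgans shrinks with it, so realized autozygosity varies more per
  individual than in the real system; tests rely on ranking and calibration
  properties, not on absolute variances.
* **LD / founder haplotypes**: each chromosome is cut into blocks (mean
  0.25 cM); each block has `founder_pool_size` (default 3) variant
  sequences, and every founder haplotype picks one variant per block at
  random. Within-block r² is ≈ 1/(pool−1) (defaults give mean adjacent
  r² ≈ 0.35), between blocks founders start at linkage equilibrium, and LD
  decays further through recombination. Pool size is the single LD knob:
  larger pools mean weaker LD.
* **Gene dropping**: founder haplotype copies carry unique ancestry labels;
  meioses place crossovers as a Poisson process on the cM map (Haldane, no
  interference — consistent with the exponential segment-length model).
  Realized autozygosity = map-length-weighted fraction of SNP positions
  (Voronoi cells on the cM map) where the two labels coincide. Genotyping
  error defaults to 0 and missingness to 0.001, both configurable to exercise
  QC. An individual with one known parent is treated as a founder for
  transmission (fresh unrelated haplotypes), matching the pedigree
  convention.
* **Traits**: mean + β_ind·F(individual) + β_mat·F(dam) + sex effect +
  additive genetic + maternal genetic + maternal environment + year + residual.
  Genetic values descend the pedigree with Mendelian-sampling variance
  V(0.5 − 0.25(F_s + F_d)). Defaults use the emulated system's published
  means (birthweight 2.08 kg, August weight 13.18 kg, hindleg 159.48 mm) and
  pedigree-based slopes (e.g. August weight −8.36 individual, −7.89
  maternal); variance components split the phenotypic variance roughly as
  0.2 V_P additive, 0.1 maternal genetic, 0.1 maternal environment, 0.2 year,
  0.4 residual — the ordering reported for these juvenile traits.
  Birthweight's maternal slope uses the genomic estimate (−3.09), the
  pedigree one being null.
* **Fitness**: one first-year-survival record per individual and 3 annual
  records (survival, breeding success) per individual, with sex-specific
  intercepts and slopes on the link scale (male first-year survival slope
  −22.66, etc.), year effects (variance 0.15) and individual effects
  (variance 0.15) for repeated records. Intercepts give realistic baselines
  (lamb survival ~50–60%, adult survival ~75–85%, ~1 offspring/adult-year).

What the generator does **not** emulate: density dependence and weather-driven
cohort crashes, selection and purging during the simulation, sex chromosomes,
genotyping batch effects, non-random missingness, pedigree errors, and
realistic genome-wide LD decay curves. Passing tests therefore demonstrate
the estimators' and models' statistical behaviour under a faithful but
simplified generative process, not performance on any particular real
dataset.

## Problem sizes used in the test and acceptance runs

Validity and correlation-pattern checks use 20 replicate gene-drops of one
1,500-individual pedigree with 3,000 SNPs; calibration uses 500 null datasets
(n = 200, L = 500, 199 permutations) for g2, 250 null and 200 recovery
animal-model fits on a ~320-individual pedigree, and 400 null plus 200
recovery GLMM fits. These sizes give binomial/Monte-Carlo error bands that
the assertions state explicitly (2–3 SE). The acceptance script runs one
default-scale pipeline end to end.

## Known limitations

* Dense-matrix REML is O(n³) per iteration; beyond ~5,000 records a sparse or
  low-rank implementation would be needed.
* PQL slopes for binary traits are mildly attenuated when random-effect
  variances are large; a Laplace or adaptive-quadrature refinement is a
  natural extension.
* Wald intervals are asymptotic; variance components at the zero boundary are
  reported as 0 without profile intervals.
* The pairwise-complete g2 variant is O(nL²) and intended for small panels.
* ROH calls on a 2,434,125 kb genome constant assume the map covers the full
  assayed span; supplying a mismatched map and constant silently rescales
  F_ROH.
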