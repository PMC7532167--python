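# Methods

This note documents the models, the numerical choices, and the synthetic
data the test suite runs on, in enough detail to audit or extend them.

## Haplotype construction

Haplotypes are the allele strings fully homozygous lines carry in
nonoverlapping windows of ten consecutive SNPs (map order per chromosome).
Each observed string becomes a presence/absence marker scored 0/2, so a
line scores 2 for exactly one haplotype per window and downstream mixed
models treat SNP and haplotype columns identically. Haplotype ids are
assigned by lexicographic allele string within a window, which makes ids
deterministic and shared across panels — the basis of all landrace-versus-
breeding congruency computations. Trailing windows with fewer than ten
SNPs are kept but flagged `partial` and excluded by default from
cross-panel frequency comparisons, since their haplotypes are not
length-comparable; the flag is a per-call option.

## Mixed-model machinery

**Single-observation model.** The scan model is y = Wα + xβ + u + e with
u ~ N(0, K σ²_g), e ~ N(0, I σ²) and K the genomic relationship matrix
K = (1/m) Σ_i (x_i − 2p_i)(x_i − 2p_i)ᵀ / (2 p_i (1 − p_i)) from all
polymorphic SNPs (for DH lines the diagonal sits near 2; a flag switches
the denominator to 4p(1−p) for a unit diagonal). One eigendecomposition of
K per line set turns every REML/ML evaluation into O(n) work; the variance
ratio δ = σ²_g/σ² is profiled by a coarse 64-point log-grid followed by
bounded Brent refinement (xatol 1e-10), which is robust to the occasional
multimodality of the REML surface. Variance floors sit at 1e-8 of var(y)
on the log scale and boundary hits are flagged. The REML criterion is
−½[(n−p)log 2π + log|V| + log|XᵀV⁻¹X| + yᵀPy] (no |XᵀX| constant), and the
ML criterion the usual profile form; both are verified against dense
multivariate-normal computations in the tests.

**Scan tests.** Per scan (trait × environment), variance components are
estimated once under the null (covariates only: intercept plus landrace
indicators) and reused for every marker; each marker's GLS effect, SE and
ML-profile likelihood-ratio test then reduce to weighted least squares in
the rotated basis, vectorized across markers. This is the standard fast
approximation used by genome-scan software; an exact per-marker ML refit
is available (`exact=True`) and agrees closely on signal markers. The LRT
uses ML rather than REML because likelihoods under different fixed-effect
sets are not comparable under REML. Calibration (type-I error at α = 0.05
within [0.04, 0.06] at n = 300) is enforced by the acceptance suite.

**Multi-environment model.** Stacked observations y_ijk = μ + ω_i + δ_j +
Σ_q x_kq β_q^i + u_k + e_ijk carry one random line effect u_k and
environment-specific residual variances. The per-environment effects
β_q^i are parameterized directly (one column per haplotype × environment),
which is an exact reparameterization of a main effect plus interaction.
u_k is iid σ²_u by default — the model's historical software default for
this design — with a kinship-structured option (`K=` argument); both paths
are tested against dense oracles. The likelihood uses the Woodbury
identity and matrix determinant lemma: O(N) per evaluation for iid u
(grouped per-line sums), one n×n Cholesky solve per evaluation for the
kinship option (Cholesky form, no explicit K⁻¹). Optimization is L-BFGS-B
on log-variances (ftol 1e-9), which keeps components positive by
construction.

**Backward elimination.** Every step refits the model — variance
components included, since the reference workflow refits per model — and
tests each haplotype's E-dimensional effect block jointly (Wald,
chi-square with df = number of estimable environment effects) conditional
on all others ("as if last entering"). The least significant haplotype is
removed while its P ≥ 0.01. Candidates that are monomorphic among the
phenotyped lines, or exactly collinear with earlier-entering ones, are
dropped up front with a log. The elimination trace (step, set size,
removed haplotype, its P) is retained on the model object.

**Stability classification.** Per environment a haplotype is significant
iff its 95% CI (estimate ± 1.96 SE) excludes zero. Constant sign across
significant environments → favorable or unfavorable according to the
trait's direction convention (early-vigor and early-height traits:
positive favorable; lodging and tillering: negative favorable; final
height and flowering: no convention, label `unclassified_direction`);
mixed signs → interacting; no significant environment → none. Inverting a
trait's direction map swaps favorable and unfavorable exactly and leaves
interacting untouched (property-tested).

**Variance explained** is (σ²_u,null − σ²_u,full)/σ²_u,null from REML fits
differing only in the haplotype fixed effects, floored at 0. With a
planted haplotype constructed to carry a known share of the genetic
variance the estimator is accurate to ±0.05 at n = 1000 (tested).

**Landrace-nested effects.** For haplotypes with at least `min_count`
carriers in ≥ 2 landraces, the model replaces β_q^i with β_q^ij (one
effect per haplotype × environment × landrace, estimable cells only) and
reports, per landrace pair, how many environment effects are significant
in both/one/neither and their sign concordance.

**Bivariate model.** Two traits on the same lines follow u ~ N(0, G⊗K),
e ~ N(0, E⊗I) with per-trait environment and landrace fixed effects. The
residual covariance couples the two traits within a (line, environment)
observation; observations are independent — this is an explicit
interpretation of the residual structure, chosen because it is the only
one under which e ~ N(0, E⊗I) is well defined for per-environment data.
For balanced line × environment layouts the likelihood factorizes through
the eigenbasis of K and a Helmert rotation of the environment dimension
into independent 2×2 trait blocks (per-line blocks s_k·E·G + E_cov on the
environment-mean direction, a constant E_cov block elsewhere); REML runs
over Cholesky factors of G and E, enforcing positive semidefiniteness.
Unbalanced inputs are reduced to complete cases with a warning — a known
limitation, acceptable because the phenotype inputs are per-environment
BLUEs that are near-complete by construction. With off-diagonals forced
to zero the bivariate fit reproduces the two univariate fits to 1e-6
(acceptance-tested); a haplotype is "significant for both traits" iff
both 95% CIs exclude zero, and per-trait variance explained is the
relative reduction of that trait's diagonal of G.

**Window contrast.** The focus haplotype is the reference level of a
categorical window factor with per-environment effects for every
alternative haplotype; the retained trait haplotypes minus the focus stay
in the model as background. Alternatives with fewer than three carriers
pool into a `rare` level. With exactly two window haplotypes the contrast
equals the plain biallelic parameterization (tested to 1e-6). The window's
variance explained is reported against two nulls — no haplotype terms at
all, and background-only — because the reference description is ambiguous
about which null it used; both numbers are returned.

## Diversity and LD statistics

H = 1 − Σp², PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j². nR is the Hudson–Kaplan
bound: four-gamete-incompatible SNP pairs define intervals, and the
greedy sweep over right endpoints counts the maximum number of pairwise
disjoint ones (only the minimal interval per left endpoint is kept, which
provably does not change the optimum); an independent dynamic-programming
oracle over all incompatible pairs confirms it on 500 random windows.
Modified Rogers' distance for homozygous lines reduces to
√(proportion of differing markers); PCoA is classical double-centering
with negative eigenvalues dropped from the percent-variance denominator.
Pairwise r² is the squared Pearson correlation of 0/2 genotype columns
within 1 Mb — identical to the gametic D²/(p(1−p)q(1−q)) for fully
homozygous lines. LD decay fits the drift–recombination expectation of r²
with finite-sample correction,

E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],

C = ρ·d, by least squares over log ρ from four starts; the decay distance
is the first point of a 1-bp grid where the fitted curve drops below the
threshold (default 0.2), so it is deterministic and grid-limited only.
Curves that never cross within the data range report the maximum distance
with a flag.

## Panel comparison

Overlap statistics come from the merged frequency table with explicit
zero rows. Random haplotype draws (default 500, carrier count ≥ 3) are
uniform without replacement and seeded. The Mann–Whitney test uses the
exact null for both samples ≤ 20 without ties and the tie-corrected
normal approximation otherwise. The "common" flag is a strict comparison
against the upper quartile of the random frequencies, quartile by linear
interpolation (numpy's default type-7) — the flag's absolute value
depends on that convention, which is therefore fixed and documented. The
permutation mean test enumerates all assignments exactly whenever their
number is at most `n_perm` (e.g. all 35 assignments for 4-vs-3 groups)
and otherwise uses Monte Carlo with the add-one estimator
p = (1 + #{perm ≥ obs})/(n_perm + 1), which cannot report p = 0.
Phenotypic landrace-vs-checks comparisons are run per landrace.

## Synthetic data generator

No generative model exists for the real material; the generator is a
documented stand-in that emulates the *structure* the pipeline relies on,
not the biology of any particular landrace:

- An ancestral pool of 16 haplotypes (allele frequencies uniform on
  [0.1, 0.9] per SNP). Each of 3 landraces draws 8 founders from the pool
  and adds private mutations (rate 0.01 per allele), making the landraces
  self-contained but related. The breeding panel draws its founders from
  a 10-haplotype subset of the same pool, so part of the landrace
  haplotype space is absent from breeding material by construction.
- DH lines are one recombinant gamete from a random founder pair,
  doubled: crossovers per chromosome ~ Poisson(cM length/100), positions
  uniform on the genetic map, no interference. Default genome: 3
  chromosomes × 400 SNPs, 160 Mb / 160 cM each, bp positions uniform and
  cM linear in bp.
- Planted QTLs are (window, haplotype) pairs with per-environment effects
  on the 0/2-coded scale (carrier − non-carrier contrast = 2β): stable
  patterns keep a constant sign, interacting patterns flip sign between
  environment halves, null patterns are zero. Default effect size 0.4–0.5
  trait units against residual SD 1 and polygenic variance 0.5 — i.e.
  roughly a 0.4-SD allele, the regime where detection is expected but not
  trivial. Default 6 environments, 200 DH lines per landrace, 64 breeding
  lines.
- Phenotypes: y = env mean + landrace mean + Σ x·β + u + e with u drawn
  from N(0, σ²_poly·K̃) (K̃ the SNP kinship scaled to unit mean diagonal)
  and environment-specific residual noise; the across-environment BLUE
  stand-in is the plain mean over environments (the field-trial
  adjustment stage is deliberately not simulated).

What the generator does **not** emulate: genotyping error, missing data
(inputs are assumed imputed), selection or drift history, interference,
allele-frequency clines, and trait networks. Passing tests therefore
demonstrate the estimators' correctness and calibration under the stated
model, not robustness to artefacts real data may carry.

## Problem sizes in the shipped experiments

The validation experiments run at: LRT calibration n = 300 lines × 2000
replicates; CI coverage 150 lines × 4 environments × 1000 refits;
planted-QTL recovery 600 lines × 6 environments × 1200 SNPs × 25
independent studies; LD self-consistency 800 pairs × 50 seeds. These
sizes were chosen as the smallest at which the targeted operating
characteristics are stable and binomial bands are meaningful.

## Known limitations

- The bivariate model requires (or reduces to) balanced complete cases.
- FDR is applied within each scan; pooling across scans is a documented
  configuration choice, not the default.
- The fine-mapping re-scan (sliding ten-SNP windows, best window by
  minimum p) is this package's explicit definition of in-silico
  fine-mapping; other definitions exist.
- The EMMAX-style fixed-ratio approximation slightly miscalibrates for
  markers with very strong effects; the exact refit flag exists for those.
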