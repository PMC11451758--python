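# Methods

This note documents the statistical models implemented in `vqtlscan`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Phenotype preparation

Traits are rank-based inverse-normal transformed (RINT) with the Blom
offset: value with mid-rank $r$ among $n$ finite values maps to
$\Phi^{-1}((r - 3/8)/(n + 1/4))$. Blom is the standard GWAS convention;
mid-ranks handle ties, and non-finite inputs are excluded before ranking
and preserved as NaN so outputs stay aligned to individuals. RINT is
invariant to any strictly monotone transform of the input, which makes the
downstream scans robust to the trait's measurement scale.

Residualization is OLS with an intercept always included; missing handling
is listwise per phenotype. The variance phenotype is the element-wise
square of the covariate-adjusted residual of the RINT trait; its mean
equals the residual variance, and a genotype slope on it measures a
variance (scale) effect.

Two covariate sets are wired in because practice genuinely differs between
stages: the variance phenotype and the double GLM default to age, age²,
sex and the first 5 PCs, while association and interaction models default
to age, age², sex and the first 10 PCs. Both are configurable
(`n_pcs_variance`, `n_pcs_mean`); neither choice is treated as canonical.
Whether the variance-stage regression re-includes the covariates already
removed by residualization is likewise configurable
(`variance_covariates`); the default re-includes them, which is harmless
(the phenotype is orthogonal to them) and guards against covariate-genotype
correlation in real data.

Clinical-lab aggregation takes the median of an individual's repeated
measurements after dropping values above 3× the upper limit of normal —
hospital-cohort values during acute illness are not representative of an
individual's set point.

## Scale test and vQTL call

Each variant is tested twice by OLS with covariates: mean stage on the RINT
trait, variance stage on the squared residual. Wald p-values use the t
reference with $n-k$ degrees of freedom (indistinguishable from normal at
the sample sizes used, exact at small n for tests). The per-variant fit is
computed by Frisch–Waugh–Lovell residualization, vectorized across
variants; this is algebraically identical to the full multi-column OLS and
is asserted against a brute-force normal-equations solve in the tests.

A variant is called a vQTL iff variance-stage $P < 5\times10^{-8}$ **and**
mean-stage $P > 5\times10^{-8}$ (both thresholds configurable). Default
scan filters: MAF ≥ 0.001, missing-call rate ≤ 0.1; candidate-gene mode
uses MAF ≥ 0.10 with Bonferroni significance $0.05/m$ over the $m$ passing
variants in the gene.

Fixed-effects OLS stands in for mixed-model association machinery as a
deliberate simplification: the synthetic cohorts are unrelated by
construction, so there is no relatedness or population structure for a
random effect to absorb, and the scientific content — which phenotype is
regressed on what — is unchanged. On real related cohorts this
simplification would inflate test statistics.

The variance phenotype is a squared Gaussian, i.e. strongly right-skewed;
OLS Wald inference on it relies on large n. Null calibration (type-I rate
and genomic-control λ within [0.95, 1.05]) is verified at n = 50,000 in
the acceptance tests and should not be assumed far below that.

## Double GLM

The model: $y_i \sim N(x_i^\top\beta,\ \phi_i)$ with
$\log\phi_i = z_i^\top\gamma$. Fitting alternates

1. weighted least squares for $\beta$ with weights $1/\phi_i$;
2. a gamma GLM with log link for $\gamma$ on the dispersion design, with
   response $d_i = (y_i - x_i^\top\hat\beta)^2$ and prior weights
   $(1-h_i)/2$, where $h_i$ is the mean-model leverage under the current
   weights;

monitored on the extended quasi-likelihood
$-\tfrac12\sum_i[\log(2\pi\phi_i) + d_i/\phi_i]$, to relative tolerance
1e-8, max 50 iterations. Non-convergence is flagged, not raised. With
unadjusted weights (a flag), the alternation is exact coordinate ascent on
the EQL, so the fixed point is the joint Gaussian MLE — the tests verify
this against a direct `scipy.optimize` maximization. The leverage
adjustment is the REML-flavoured finite-sample correction; its objective is
monitored and is non-decreasing in practice (checked per iteration in
tests with a small tolerance).

**Wald covariance bookkeeping.** The prior weights only matter *relatively*
for the point estimate, but naively passing $(1-h)/2$ as variance weights
with the gamma dispersion fixed at 2 double-counts the factor 2 and
inflates dispersion SEs by $\sqrt2$ (empirically confirmed: reported
SE/empirical SD ≈ 1.47 under a homoscedastic null). The implementation
therefore passes the relative part $(1-h)$ as the GLM variance weights with
scale 2, giving the quasi-likelihood covariance
$2\,(Z^\top\mathrm{diag}(1-h)Z)^{-1}$ — for $\chi^2_1$-distributed squared
residuals this is the asymptotically correct Wald covariance. After the
correction the null dispersion p-values are KS-uniform.

The focal genotype appears in *both* designs, so $\beta_\text{dispersion}$
is a variance effect net of the variant's mean effect; omitting it from the
mean design would let mean effects masquerade as dispersion.

## Interaction models

Linear family: OLS of $y$ on $(1, g_1, g_2, g_1g_2, X)$, t-reference Wald
test on the product term. Logistic family: binomial GLM fitted by IRLS
(max 100 iterations, tolerance 1e-10); separation is detected as any
$|\hat\beta| > 20$ and flagged rather than raised, as is IRLS
non-convergence. All 95% CIs are Wald ($\pm1.96\,SE$); no
profile-likelihood intervals. Interaction log-odds for binary outcomes are
reported on the logistic (log-odds) scale.

The joint model adds a second product term ($g_f g_a$ and $g_f g_b$ fitted
simultaneously with all three main effects). When $g_a$ is merely an LD
proxy of the true interactor $g_b$, the joint fit retains $g_b$'s product
term and nulls $g_a$'s — this is the cis-epistasis disambiguation used for
nearby variants on the same chromosome.

Pathogenic allele counts sum dosages at two sites in one gene (a compound
heterozygote carries two pathogenic alleles); group labels pool counts ≥ 2
into "2" while the raw sum is retained.

Stratified trait means use $SE = sd/\sqrt n$ per genotype combination;
stratified odds ratios form a 2×2 table of each combination against a
reference combination, $OR = ad/bc$ with log-scale Wald CI, adding 0.5 to
all four cells (flagged) when any cell is zero. The reference combination
has OR = 1 exactly. Interaction scans report raw p-values plus a Bonferroni
column; no default filtering.

## LD statistics

From phased haplotype counts, plug-in $D$, $D'$ (sign-dependent
$D_{max}$), $r^2$. "A"/"B" are the alternate alleles of each variant, and
the sign of $D$ follows that orientation. From unphased dosages, haplotype
frequencies come from EM over the double-heterozygote ambiguity: start at
linkage-equilibrium frequencies (the two-locus likelihood is unimodal in
practice, so this avoids seed dependence), split the (1,1) cell by the
current odds $p_{AB}p_{ab} : p_{Ab}p_{aB}$, re-normalize expected counts,
iterate to 1e-10 max-frequency change (cap 1000 iterations, flagged if
hit). The multinomial log-likelihood path is recorded and is non-decreasing.

## Power analysis

$\lambda = n\,\beta_{int}^2\,\mathrm{Var}(G_1G_2)/\sigma^2$; power is the
upper-tail probability of $\chi^2_1(\lambda)$ beyond the central
upper-$\alpha$ quantile. Two interaction-term variance conventions are
reported side by side because the choice materially changes power at
common allele frequencies and published calculations rarely state it:

* **product** (default for reproducing published claims):
  $\mathrm{Var}(G_1G_2) = E[G_1^2]E[G_2^2] - (E[G_1]E[G_2])^2$ under HWE
  and independence, with $E[G]=2p$, $E[G^2]=2p(1-p)+4p^2$. At MAF
  0.10/0.10, effect 0.05 SD, n = 400,000, α = 5×10⁻⁸ this gives λ = 46.8
  and power ≈ 91.8%; at MAF 0.01/0.01, effect 0.5 SD, λ = 40.8 and power
  ≈ 82.5% — both above the 80% benchmark.
* **adjusted**: the main-effect-residualized variance
  $\mathrm{Var}(G_1)\mathrm{Var}(G_2) = 4p_1(1-p_1)p_2(1-p_2)$, which is
  the asymptotically correct NCP for the Wald test in the model that
  includes both main effects. This is the convention the simulation oracle
  matches (verified at interior power ≈ 0.5 with 1000 replicates); at the
  two operating points above it gives 59.5% and 79.1%.

Main effects (default 0.01 SD each) enter the simulation oracle but are
omitted from the analytic NCP — the fitted main-effect terms absorb them.

## Synthetic-data generator

What it emulates: hard-call genotypes in exact HWE at specified allele
frequencies; pairwise LD at a target $D'$ via the 4-class haplotype model
(haplotype sums give the dosages exactly, providing phased truth for EM
validation); covariates shaped like a biobank table (age ~ U(40,70), sex ~
Bernoulli(0.5), PCs ~ N(0,1) i.i.d.); quantitative traits
$y = \mu + \sum\beta_v g_v + \sum\beta_{uv} g_ug_v + X\delta + \varepsilon$
with $\varepsilon \sim N(0, \sigma^2 e^{\sum\gamma_v g_v})$; binary
outcomes from a logistic model. The log-linear variance effect makes the
double GLM's log-linked dispersion submodel correctly specified, so
parameter recovery is a clean end-to-end check; the logistic (rather than
liability-threshold) binary model matches the logistic interaction models
fitted downstream.

What it does not emulate: realistic multi-locus LD beyond pairwise target
pairs, relatedness and family structure, ancestry admixture or stratified
PCs, imputation dosage uncertainty, case-control ascertainment. Passing
tests therefore demonstrate correctness of the estimators under their
assumed models, not robustness to those real-data features.

All randomness flows through one explicit integer seed per call; identical
seeds give bit-identical outputs (genotype generation is blocked over
variants with a fixed block size, so results do not depend on cohort
width). The pipeline derives stage seeds as fixed small offsets of the
config seed.

### The planted-signal demonstration cohort

The end-to-end demo plants one vQTL whose variance effect is mediated
entirely by a GxG partner. A raw product interaction
$\beta_{int}g_1g_2$ induces a first-order marginal *mean* effect
$\beta_{int}E[g_2]$ at the focal variant — which would disqualify it under
the "no mean effect" half of the vQTL rule — so the demo adds the
compensating main effect $-\beta_{int}\cdot 2p_2$ at the focal variant,
equivalent to writing the interaction in the centered partner dosage. The
operating point ($p_1=0.3$, $p_2=0.5$, $\beta_{int}=0.5$, n = 20,000, 30–50
background null variants) was sized analytically: the variance-scan z-score
is ≈ 12 and the interaction z-score ≈ 29, so both clear genome-wide
significance with wide margin while a single replicate runs in seconds.

## Problem sizes used in the test suite

Closed-form checks run at the published operating points (n = 400,000 is
just a number in a formula). Simulation checks use: 2,000 null variants at
n = 50,000 for variance-scan calibration; n = 100,000 for dispersion
recovery and n = 1,000 × 500 replicates for dispersion null calibration;
n = 200,000 for interaction recovery and n = 1,000 × 500 replicates for its
size; 1,000 replicates at n = 2,000 for the power cross-validation; and 25
pipeline replicates at n = 20,000 for planted-signal recovery. These sizes
were chosen so each check's Monte-Carlo error is small relative to the
tolerance it asserts.

## Known limitations

* No mixed-model association; not valid for related individuals.
* The variance phenotype's OLS inference needs large n (skewed response).
* No Firth penalization: rare-outcome logistic fits near separation are
  flagged, not rescued.
* EM LD assumes random mating (HWE) at both loci; it is a two-locus
  method only.
* Power analysis covers quantitative traits at a single fixed α; no
  binary-outcome power, no LD between the interacting loci.
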