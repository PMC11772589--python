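# Methods

This note documents the statistical models implemented in `trimodalqtl`,
the assumptions behind the synthetic-cohort generator, the numerical choices
that matter, and the package's known limitations.

## Allele-aware count-QTL model

### Model

For one molecular feature (a promoter-contact read count or an ATAC peak
count) and one candidate variant, donor $i$ contributes a total count
$c_i$ and, when heterozygous, an alternative-allele count $n_{1i}$.
Genotypes are uncertain: imputation supplies class probabilities
$p(G_i=g)$, $g \in \{0,1,2\}$, which the likelihood marginalises over:

$$
L(\beta,\gamma,\phi,\theta) = \prod_i \Big[ p(G_i{=}1)\,
f_{NB}(c_i \mid \mu_i(1), \phi)\, f_{BB}(n_{1i};\pi,\theta,c_i)
 + \sum_{g\in\{0,2\}} p(G_i{=}g)\, f_{NB}(c_i \mid \mu_i(g), \phi) \Big]
$$

with genotype-dependent mean
$\mu_i(g) = \exp(X\gamma)\,\ell_i\,(2-g+g e^{\beta})/2$, so that
$\mu(2)/\mu(0) = e^{\beta}$: $\beta$ is the natural-log allelic fold
change, the ratio of expected signal between alternative and reference
homozygotes. Library size $\ell_i$ enters as a multiplicative offset.
The negative binomial is parameterised mean/overdispersion,
$\mathrm{Var} = \mu + \mu^2/\phi$; the beta-binomial by mean fraction and
concentration, $a = \pi\theta$, $b=(1-\pi)\theta$. Reference-mapping bias
enters through $\alpha_0 = \mathrm{logit}(AI_0)$: the heterozygote
alt-read fraction is $\pi = \mathrm{logistic}(\alpha_0+\beta)$, the
homozygote baseline $\mathrm{logistic}(\alpha_0)$.

### Priors and inference

$\beta$ carries a 50/50 two-component Gaussian mixture prior with
variances 0.001 and 0.121 (a spike of essentially-null effects and a slab
of real ones, reflecting a candidate set where about half the variants are
expected to be true QTLs). Nuisance priors are weakly informative:
$\gamma \sim N(0,5^2)$, $\log\phi,\log\theta \sim N(0,2^2)$.

Sampling is adaptive random-walk Metropolis over
$(\beta, \gamma, \log\phi, \log\theta)$: a componentwise warmup phase with
per-parameter Robbins–Monro scale adaptation (target acceptance 0.44),
then a joint Gaussian proposal built from the empirical warmup covariance
(target 0.3) — the covariance matters because $\beta$ and the intercept
are correlated through the genotype-dependent mean. Ten percent of
iterations propose $\beta$ fresh from its mixture prior; for that
independence move the acceptance ratio reduces to a likelihood ratio, and
it lets chains hop between the spike and slab modes. Defaults are 2
chains, 2000 warmup and 2000 kept draws; a `thin` parameter trades extra
iterations for less autocorrelated kept draws (the bundled studies use
600–1000 kept draws with thin 4). Convergence is monitored with split-
$\hat R$; the per-feature likelihood kernel is JIT-compiled when numba is
available and falls back to the identical numpy expression otherwise (the
two are asserted equal in the tests, and the likelihood itself is pinned
against scipy densities and a genotype-enumeration brute force).

### Decision rule

A variant is significant iff the equal-tailed 99% credible interval for
$\beta$ excludes zero, the baseline allelic imbalance shows no strong
reference-ward bias ($AI_0 \ge 0.4$; the filter is deliberately one-sided,
since only reference-ward bias mimics a spurious alt-depletion), and
$\hat R < 1.01$. Features with fewer than 3 donors of heterozygote
probability > 0.5 are skipped with a reason code. For ranking, the
approximate posterior probability of association is the largest credible
level at which a normal approximation to the marginal posterior excludes
zero, $2\Phi(|m|/s)-1$.

### Power at desk scale

Under the generator defaults below, at $n=50$ donors and 100–200 reads per
feature the marginal posterior sd of $\beta$ is ≈ 0.11–0.14 (verified
against an independent profile-grid posterior). A fold change of 1.5
($\beta = 0.405$) therefore sits near the 99%-credibility detection
boundary: calibration runs show a null false-positive rate well under 1%
but single-feature detection of aFC 1.5 in only ~25–35% of features, with
posterior means shrunk to ≈ 0.30 by the mixture prior. This is a property
of the data regime, not of the sampler, and is the quantitative motivation
for the joint multi-trait analysis; detection approaches 100% only with
milder donor-level overdispersion or larger cohorts.

## Evidence enrichment

Candidates carry the ranking statistic $1-\text{approx. pp}$ (smaller =
stronger evidence). For each of 10,000 null samples, every eQTL draws one
non-eQTL uniformly (with replacement across samples) from the same
quantile bin of the pooled read-count distribution — ten bins by default —
and the one-sided p-value is the add-one estimator
$(1+\#\{\text{null mean} \le \text{observed}\})/(1+N)$, which is never
zero and is invariant to monotone relabelings of read counts.

## Multi-trait Bayesian variable selection

### Windows

Windows intersect (bait fragment ± 5 kb) with (ATAC peak ± 5 kb), in
0-based half-open coordinates; a window is dropped when a contained
variant is flagged for restriction-site creation/disruption at the bait or
lies within 10 kb of the target gene's promoter.

### Marginal likelihood and priors

Given a variant subset $\gamma$ with effective rank $r$ (pivoted QR;
redundant collinear columns contribute neither fit nor penalty), each
trait contributes the conjugate g-prior marginal

$$
\log m(y\mid\gamma) = -\tfrac{r}{2}\log(1+g)
 - \tfrac{n-1}{2}\log\big(y^\top y - \tfrac{g}{1+g} y^\top H_\gamma y\big),
$$

and the three traits multiply (residual independence across traits given
the shared indicator — a deliberate simplification of a full multivariate
marginal; it preserves the selection behaviour that matters here and is
exactly enumerable for testing). $g = n$ (unit information) by default and
exposed as a parameter. Genotype columns are standardised and traits
mean-centred, making the prior scale meaningful and the intercept
non-informative. The model-size prior is independent Bernoulli inclusion
with $\omega = 1/k$: the expected number of selected variants is 1 with sd
$\sqrt{1-1/k}\approx 1$ for any window size.

### Search

Three Metropolis-coupled chains at a geometric temperature ladder
(1, 2, 4) run 20,000 iterations with 5,000 burn-in. Moves are a symmetric
flip of one uniformly chosen variant or a swap of one selected with one
unselected variant — the move type is drawn independently of the current
state, and a swap proposed at the empty or full model is a no-op, which
keeps the kernel symmetric (state-dependent move choice provably biases
inclusion; the tests pin the sampler against exhaustive $2^8$ enumeration
to within ±0.05, and in practice it agrees to ~0.02). One exchange between
a random adjacent temperature pair is attempted per iteration. Marginal
likelihoods are memoised per visited subset. mPPI is the cold-chain
inclusion frequency after burn-in; the best model is the
largest-marginal-likelihood subset visited by any chain.

### FDR, BMA and filters

If the best model is null, no associations are declared. Otherwise
variants are selected by the Bayesian-FDR rule on mPPI sorted
non-increasing (ties broken by variant index): the default keeps the
largest prefix $j$ with mean local fdr $\frac1j\sum_{i\le j}(1-mPPI_{(i)})
\le q$, $q=0.05$; an unnormalised cumulative-sum variant is available as
`rule="cumulative_sum"`. Effects are Bayesian-model-averaged over
cold-chain visits: per model the conditional posterior mean is the
g-prior-shrunk least-squares fit and the conditional variance its g-prior
posterior variance (zero when excluded); the posterior z-score is
$E(\beta_{jk}\mid Y)/\sqrt{E(\sigma^2(\beta_{jk})\mid Y)}$. Post-hoc
filters drop variants with baseline $AI_0 < 0.4$ or with any
model-averaged |effect| under 0.006 (contact), 0.001 (accessibility) or
0.004 (expression); surviving variants are concordant when the three
effects share a sign, and the concordant fraction is tested against the
25% null (2 of 8 equiprobable sign patterns) by a one-sided binomial test.

## Causal mediation

Treatments are principal components of the window's centred dosage matrix
(sign fixed by making each component's largest-magnitude loading
positive), keeping the leading components whose cumulative explained
variance is ≤ 0.99; each PC is analysed separately. The mediator and
outcome models are ordinary least squares:

$$
M_i = \alpha_0+\alpha_1 X_i + \alpha_2^\top C_i + \varepsilon_{im},\qquad
Y_i = \beta_0+\beta_1 M_i + \beta_2 X_i + \beta_3^\top C_i + \varepsilon_{iy},
$$

giving ACME $=\alpha_1\beta_1$, ADE $=\beta_2$ and TE $=$ ACME + ADE
(an identity in the linear no-interaction case, so a single ACME is
reported per PC). The contact → expression model runs both with and
without accessibility as an observed confounder, both labelled in the
output. Inference is a nonparametric donor bootstrap (default 1000
resamples; fewer than 100 raises a warning flag) with BCa intervals
(bias correction from the bootstrap CDF at the point estimate,
acceleration from leave-one-out jackknife skewness) and add-one smoothed
two-sided p-values. Mediation is declared when TE and ACME have p ≤ 0.05;
ADE p > 0.05 upgrades it from partial to full mediation.

### Sensitivity to unmeasured confounding

If an unmeasured variable drives both mediator and outcome, the errors
$\varepsilon_m,\varepsilon_y$ correlate with some $\rho$ and the OLS
$\beta_1$ is biased. Residualising $M$ and $Y$ on $[1, X, C]$ reduces the
system to two correlated errors with the closed-form consistent slope

$$
\beta_1(\rho) = \hat\beta_1^{OLS}
 - \rho\,\frac{s_{y\mid m}}{s_m\sqrt{1-\rho^2}},
$$

where $s_m$ is the mediator-residual sd and $s_{y\mid m}$ the residual sd
of the outcome residual regressed on it. The curve
$ACME(\rho)=\hat\alpha_1\beta_1(\rho)$ equals the point estimate at
$\rho=0$ and is monotone on each side of zero; $\rho^*$ is the grid value
(default −0.99…0.99, step 0.01) of smallest magnitude where it crosses
zero, and $|\rho^*| \ge 0.3$ is labelled robust. Correctness is defined
generatively: simulating zero true mediation with error correlation
$\rho_0$ must put the sign flip at $\rho_0$, which the tests verify.

## TF perturbation and motif disruption

For each (tool, TF, training dataset) with predicted ChIP signal for both
alleles, SAD $=$ alt − ref and SAR $= \log_2(\text{alt}+1) -
\log_2(\text{ref}+1)$; the per-TF perturbation score is
$\max_i(\text{SAD}_i \cdot \text{SAR}_i)$, which is invariant to swapping
alleles (both factors negate). Calls compare the signed score against the
nearest-rank 99th percentile of an empirical background panel per
(tool, TF); a consensus call requires exceedance under both tools, and a
missing background leaves consensus undefined rather than false.

Motif models are position frequency matrices (JASPAR format via
biopython) with a pseudocount of 0.8 distributed by the flat 0.25
background; scoring weights are column probabilities times column
information content, and match scores are min–max normalised to [0, 1].
Scanning takes the best window over both strands and all offsets,
skipping (and flagging) windows with ambiguous bases. Match p-values are
exact under the flat background: per-position score contributions are
discretised to integer bins at 1e-3 granularity on the normalised scale
and convolved; the observed score maps onto the same grid, clamped to the
attainable maximum so a perfect match keeps its exact enumeration
probability. The convolution is verified against full $4^w$ sequence
enumeration. A strong allelic disruption requires a match at p ≤ 1e-4 for
either allele and an absolute normalised score difference ≥ 0.7.

## ABC threshold calibration

Enhancer-level ABC scores are $A_e C_e / \sum_{e'} A_{e'} C_{e'}$ over
the enhancers within 5 Mb of the gene's promoter (distant pairs are
excluded from numerator and denominator; genes with all-zero products get
zero scores and a flag). Gene-level scores sum the raw products of
enhancers whose normalised score passes the inclusion threshold, so they
are non-increasing in the threshold. Calibration scans a threshold grid
(default 0–0.1 in steps of 0.002; the bundled toy locus, whose planted
threshold is 0.3, uses a wider grid), maximising Pearson correlation
between gene-level ABC and log1p(expression) — the log transform is a
configuration choice (`log_expression=False` uses raw CPM-like values).
Ties go to the smaller threshold. Significance permutes gene labels and
recomputes the correlation at the calibrated threshold, with the add-one
estimator (floor $1/(N_{perm}+1)$).

## Synthetic cohort generator

The generator emulates a ~34-donor single-population cohort (sizes are
overridable per study):

- **Genotypes**: alt-dosage Binomial(2, MAF) per donor (Hardy–Weinberg),
  default MAF 0.25 — a common regulatory variant. Imputation uncertainty
  is a Dirichlet draw centred on the one-hot true class with concentration
  `gp_noise` (default 50, i.e. ~0.95 probability on the true class,
  matching well-imputed common variants); infinite concentration gives
  exact one-hot probabilities.
- **Counts**: library sizes log-normal around 1 with σ = 0.3 (a realistic
  depth spread without extreme outliers); totals NB with mean
  `mean_depth`·lib·(2−g+ge^β)/2, default depth 100 and φ = 8 (donor-level
  CV ≈ 35%, typical for per-feature ATAC/contact counts across
  individuals); heterozygote alt counts beta-binomial with θ = 20
  (allele-level intraclass correlation ≈ 0.05) and baseline allelic
  fraction `baseline_ai` (0.5 = unbiased).
- **Trait windows**: Y = X_std·B + E with E rows drawn under the
  configured 3×3 residual correlation (identity by default), traits
  mean-centred — the generative counterpart of variance-stabilised,
  centred counts.
- **Mediation triplets**: M = α₁X + ε_m, Y = β₁M + β₂X + ε_y with
  controllable error correlation ρ and the true ACME = α₁β₁ recorded.
- **TF backgrounds**: a 95/5 mixture of near-zero noise and rare large
  signed effects per (tool, TF) — the long-tailed shape of genome-wide
  variant effect panels.
- **ABC toy locus**: log-normal activities and contacts, distances mostly
  within 5 Mb (some planted beyond), expression built from gene-level ABC
  at a planted threshold (default 0.3) times log-normal noise.

All generators are pure functions of (config, seed); RNG sub-streams are
derived by stable hashing of (stage, feature id), so results do not depend
on execution order. What the generator does **not** emulate: read-level
artefacts (mapping bias beyond the AI₀ offset, duplicate structure),
linkage disequilibrium between variants in a window (columns are
independent), donor covariates other than library size, batch structure,
or empirically calibrated Hi-C contact decay. Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to those real-data complications.

## Problem sizes in the bundled studies

The calibration and recovery studies run at sizes chosen to be
informative on a single CPU: 500 null and 100 effect features for
count-QTL calibration (50 donors, depth 100–200, 600 kept draws with
thin 4 per chain); 20 windows of $k=8$ variants for the
enumeration-agreement check and 50 replicates for planted-variant
recovery (full 20,000-iteration chains, feasible because marginal
likelihoods are memoised); 200 replicates at n=200 with 500 bootstrap
resamples for mediation coverage; and $4^8$ full enumeration for motif
p-values.

## Known limitations

- Single-feature count-QTL detection at 34–50 donors is power-limited for
  fold changes ≲ 1.5 (see above); results should be read jointly with the
  multi-trait selection.
- The multi-trait marginal likelihood treats traits as conditionally
  independent; a full matrix-variate treatment could share residual
  correlation across traits.
- Mediation assumes linear continuous outcomes, no treatment–mediator
  interaction and a single mediator; the sensitivity analysis addresses
  only mediator–outcome confounding.
- The motif p-value is exact for the flat background only; GC-weighted
  backgrounds would need re-derivation of the convolution weights.
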