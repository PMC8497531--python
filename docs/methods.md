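# Methods

`fcmega` implements a complete multi-site analysis of resting-state
functional connectomes in a case/control design (here: major depressive
disorder vs healthy controls), from parcel time series to corrected group
statistics, together with a synthetic cohort generator that reproduces the
statistical structure such an analysis assumes. This note documents the
models, the generator, the numerical choices, and what the validation
suite does and does not establish.

## From time series to features

Each subject contributes a T × P matrix of parcel-averaged BOLD signals
(P = 400 cortical parcels in the full-scale setting; the synthetic default
is P = 42 for tractability). Functional connectivity is the Pearson
correlation between parcel time courses, variance-stabilised by the Fisher
transform z = arctanh(r). Correlations are clipped at |r| ≤ 1 − 1e−7
before arctanh so degenerate perfect correlations stay finite without
special-casing. The diagonal is stored as NaN ("undefined") and excluded
from every summary; this prevents silent inflation of within-network
means. The canonical edge order is the row-major upper triangle of the
atlas parcel ordering, giving P(P−1)/2 edges (79,800 at P = 400).

Each of the seven canonical cortical networks (VN, SMN, DAN, SN, LN, FPN,
DMN) yields two subject-level features:

* **within-network mean FC** — the signed mean z over all unordered
  within-network pairs;
* **network segregation** — s = (Z̄n − Z̄a) / Z̄n, where Z̄n is the mean of
  the *positive* within-network z values and Z̄a the mean over edges from
  the network's parcels to the rest of the cortex. Whether Z̄a is also
  restricted to positive edges is genuinely ambiguous in the literature;
  the default applies the positive-only rule to both terms (symmetry of
  treatment), and `between_policy="signed"` switches to signed averaging
  so the ambiguity is explicit and testable. With no positive
  between-network edge Z̄a is 0 (s = 1); with no positive within-network
  edge the metric is undefined and reported as missing, never as zero.

Subject-level quality control precedes all statistics: subjects with mean
framewise displacement above 0.55 mm (strictly greater; the threshold
itself passes) or age outside 18–65 years are excluded, each with a
machine-readable reason; missing age or motion is its own reason code
rather than a silent drop.

## One-stage mega-analysis

Features from all sites are pooled in a linear mixed-effect model per
feature,

    y_ij = β0 + β_g MDD_ij + β_a age_ij + β_s male_ij + β_f meanFD_ij
           + u_j + ε_ij,      u_j ~ N(0, σ²_site),  ε_ij ~ N(0, σ²),

fitted by REML (statsmodels MixedLM). Dependent features are rank-based
inverse normal transformed first — Φ⁻¹((r_i − c)/(n − 2c + 1)) with the
Blom offset c = 3/8 and average ranks for ties — so scales are comparable
across features and sites. The group t statistic uses residual degrees of
freedom (N − number of fixed-effect coefficients). Finer df
approximations (Satterthwaite, Kenward–Roger) were considered and not
implemented: for a subject-level contrast such as diagnosis, with ~10³
subjects and ~10¹ sites, they coincide with the residual df to well below
the reporting precision, and statsmodels does not expose the
variance-parameter covariance they require. Effect sizes are Cohen's
d = 2t/√df. A singular fit (site variance estimated at zero) degenerates
to the fixed-effects-only model and is flagged in the output
(`model_type="ols"`). Covariate-adjusted group means are fixed-effect
predictions at the sample-mean covariate vector with the group indicator
set to 0/1.

Multiplicity: the seven within-network FC tests and the seven segregation
tests are corrected as two separate seven-member Bonferroni families.
Edge-level tests form a single Benjamini–Hochberg family of P(P−1)/2
tests. The edge-level screen absorbs site as fixed-effect dummies inside
one vectorised least-squares solve across all edges, rather than fitting
one mixed model per edge: a per-edge REML fit costs ~0.1 s and is
infeasible ×79,800, while the fixed site intercept targets the same
adjustment for a balanced-covariate screen. Network-level inference always
uses the true mixed model.

Secondary analyses reuse the same model skeleton: severity categories
(remitted → very severe) replace the group factor (controls as reference;
overall Wald test of the five severity coefficients plus per-level
contrasts, Bonferroni within the feature family); medicated vs unmedicated
cases are compared the same way after a severity-balance check (Pearson
chi-square with a seeded Monte-Carlo permutation p-value, B = 1000 by
default); and the age-by-group interaction model `y ~ group*age + sex +
mean_fd + (1|site)` yields per-group age slopes and their difference.

## Two-stage meta-analytic cross-check

Within each site with at least `min_per_group` (default 10) subjects per
arm, an OLS model of the globally transformed feature on group, age, sex
and mean FD gives a site estimate β_k with standard error se_k.
Fixed-effect inverse-variance pooling then gives

    β̂ = Σ(β_k/se_k²) / Σ(1/se_k²),    se(β̂) = (Σ 1/se_k²)^(−1/2),

with a two-sided normal p. Sites failing the size rule or with a
rank-deficient design are excluded with a logged reason. A
DerSimonian–Laird random-effects option exists for sensitivity only; the
fixed-effect pool is the default cross-check. Concordance between the two
routes is reported as the Pearson correlation and sign agreement of the
14 network-feature estimates and the overlap of the Bonferroni-significant
sets.

## Synthetic cohort generator

The generator draws each subject's time series from a multivariate normal
whose correlation matrix is a seven-block structure: `base_within_r`
(default 0.35) inside network blocks, `base_between_r` (default 0.08)
elsewhere. Perturbations are injected on this latent correlation scale:

* **group effects** — per-network additive changes of the within-network
  correlation for cases (hypoconnectivity when negative);
* **site offsets** — one N(0, site_sd²) additive offset per site on all
  correlations (default site_sd 0.05, chosen so that site-level feature
  variance is of the same order as subject-level variance, matching the
  large scanner/protocol effects seen in uncorrected multi-site FC data);
* **site case mix** — each site's case fraction is drawn around
  `case_fraction` with sd `case_fraction_sd` (default 0.15): consortium
  centres range from patient-heavy clinics to control-heavy cohorts.
  This matters statistically: with identical case fractions everywhere,
  site offsets are orthogonal to the group contrast and omitting the site
  intercept costs nothing; the confounding that the random intercept
  exists to absorb arises precisely from case-mix differences between
  sites;
* **severity** — categories assigned by thresholding a latent standard
  normal score at the quantiles of realistic consortium frequencies
  (remitted 23%, mild 17%, moderate 33%, severe 17%, very severe 6%,
  unknown 4%); `severity_effect` ramps linearly over the ordered
  categories (remitted 0 → very severe 1), "unknown" carries no effect;
* **medication** — yes/no/unknown (63%/36%/1%) among cases only, with an
  optional per-network additive effect for medicated cases;
* **age-by-group slope** — `age_group_slope` (per network, per year,
  centred at the mid age range) applies to cases only, producing a
  group-specific age trend in connectivity and segregation;
* **motion** — mean FD is drawn from a right-skewed shifted gamma
  truncated below the 0.55 mm QC threshold, with a configurable fraction
  (default 4%) drawn above it to exercise the filter; white noise of
  variance `motion_coupling × mean_fd` is added to the signals, which
  attenuates every observed correlation by 1/(1 + variance) — the
  motion-confound structure the mean-FD covariate is meant to absorb.

The perturbed matrix is clipped to (−1, 1) and, if indefinite, projected
to the nearest positive semi-definite correlation matrix (Higham
alternating projections, with an eigenvalue-clipping fallback when the
projection stalls). If the nearest valid matrix deviates from the request
by more than 0.15 in any entry, the configuration is rejected with an
error naming the subject context — the requested effect structure is not
realisable as a correlation matrix, and silently sampling from something
else would invalidate recovery checks. Every generated cohort carries a
`truth` table: the expected within-network Fisher z per subject implied by
its generating matrix after motion attenuation, which is what recovery
tests compare model estimates against. Controls never carry severity or
medication status. All randomness flows from a single `numpy` Generator
seeded by `CohortConfig.seed`; identical configurations are bit-identical.

What the generator does **not** emulate: BOLD autocorrelation and
hemodynamics, spatially structured artefacts, scanner-specific spectral
differences, non-Gaussian tails, heterogeneous per-site group effects
(exposed implicitly through site offsets only), or preprocessing choices.
Passing recovery tests therefore shows that the estimators are correct
under the model's own assumptions, not that those assumptions hold in any
given real dataset.

## Named study conditions and problem sizes

The validation suite runs four fixed scenarios (`fcmega.scenarios`), all
at 42 parcels and 150 timepoints:

* `null_calibration` — 12 sites × 40 subjects, no group-linked effects;
  500 replicates give the type-I error of the group test and of the
  deliberately misspecified no-site-intercept model.
* `smn_hypoconnectivity` — 16 sites × 68 subjects (~1,050 after QC);
  within-SMN correlation reduced by 0.012, sized so the transformed-scale
  group effect lands near d ≈ 0.26, plus a smaller within-SN reduction
  (−0.004). The SN effect is kept small deliberately: a within-only
  generator cannot reduce a network's between-network connectivity in
  proportion, which is what keeps SN segregation flat while its FC drops
  in the motivating setting, so a small within-SN effect is the faithful
  way to obtain "FC effect strongest in SMN; segregation flagged for SMN
  only".
* `smn_age_decline` — within-SMN correlation falls by 0.003 per year of
  age in cases only (≈ −0.14 across the adult range).
* `multisite_concordance` — 15 sites with effects spread over SMN, SN,
  DAN and VN, for the mega-vs-meta estimate comparison.

These sizes keep each simulation study in the minutes range on one CPU
while leaving Monte-Carlo error well below the effects being measured;
recovery checks aggregate over replicates and test majority behaviour or
mean bias (±2 Monte-Carlo SE) rather than single draws.

## Known limitations

* The residual-df t-test is mildly liberal in designs with very few sites
  and a site-level contrast; diagnosis is subject-level here, and the
  null calibration verifies the operating characteristics directly.
* The edge-level screen's site-fixed-effect OLS is not identical to a
  per-edge mixed model when sites are extremely unbalanced; it is a
  screening tool, and the network-level conclusions never depend on it.
* Global inverse normal transformation before per-site OLS (two-stage
  route) uses the pooled ranks; a strictly per-site transform would
  change site estimates slightly. The pooled transform keeps both routes
  on the same scale, which is what the concordance comparison requires.
* Segregation is undefined for a subject/network with no positive
  within-network edge; such entries propagate as missing and reduce the
  complete-case sample for that feature.
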