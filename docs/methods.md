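# Methods

This note documents the statistical procedures implemented in
`rbmscore`, the choices made where the design was genuinely open, and
what the synthetic-data studies do and do not demonstrate.

## Indicators

All indicators are risk-aligned (larger = riskier) before any modeling.

**Borderline Inclusion Index (BII).** Count of enrolled participants
whose eligibility lab value falls in the closed band [τ−δ, τ+δ] around
the protocol threshold τ, over enrolled assessed. The band is closed at
both ends so threshold-exact values count as borderline. δ is a
required clinical input; when unset it defaults to 5% of τ — a "narrow,
clinically meaningful band" has to be made concrete somehow, and ±5%
of the cutoff is a common assay-tolerance scale.

**Screen-failure rate and window violations.** Raw counts with their
denominators; no point division happens in the pipeline — the Beta
posterior carries the uncertainty, so small sites get wide posteriors
instead of extreme point rates. Window adherence is risk-aligned by
counting violations rather than adherent cases.

**Screening duration.** Median of log screening times per site. The
median resists the long right tail typical of screening logs; the log
scale makes multiplicative slowdowns additive.

**Eligibility Distribution Divergence (EDD).** Exact two-sample
Kolmogorov–Smirnov distance between the focal site's lab values and the
pooled values of all *other* sites (self-exclusion avoids biasing the
comparison toward agreement). The energy distance
2E|X−Y| − E|X−X′| − E|Y−Y′| is available as a tail/shape-sensitive
alternative (V-statistic convention, so it vanishes exactly when the
empirical distributions coincide). The distance itself is used, not a
test p-value: sampling variability is handled by the bootstrap in
Stage 1 and by robust cross-site standardization.

**Screen-Failure Pattern Shift (SFPS).** Deliberately simple two-window
detector: pool the per-period reason counts into an earlier and a later
half, form the 2×R contingency table, and flag when the Pearson
chi-square statistic exceeds the upper-α quantile (default α = 0.05)
with R−1 degrees of freedom. Zero-count reasons are dropped; with
fewer than two active reasons there is no composition to shift and the
flag is 0. Sequential detectors (CUSUM, multiple-break models) would
give a continuous drift probability and are intentionally out of scope.

**CMG (optional).** Exclusions for modernized criteria versus a
benchmark proportion ρ₀; Stage 1 centers the logit posterior at
logit(ρ₀), so above-benchmark exclusion is positive risk. The benchmark
is treated as a known constant.

## Stage 1 — posterior draws

Proportions get conjugate Beta(1+y, 1+n−y) posteriors reported as
logit(π): the flat prior is weak regularization that keeps 0/1 counts
off the boundary. The drift flag gets Beta(1+m, 2−m). Duration and EDD
get nonparametric bootstraps (resample size = original size); EDD
resamples *both* samples per draw and transforms as log(max(D, 10⁻⁶)),
the floor keeping the log finite when a resample pair coincides.

Each (site, indicator) pair draws from an RNG substream keyed by
(seed, site index, indicator index), so adding or removing a site never
perturbs another site's draws.

The KS bootstrap is computed exactly but without materializing
resamples: the bootstrap ECDF evaluated at the ~2n relevant cut points
is a Markov chain of conditional binomials (the cumulative count of a
uniform multinomial resample), and the supremum of |F_x − F_y| over the
line is attained at a site-support point evaluated from the right or
just to its left. This makes the per-site cost O(M·n) instead of
O(M·(n+N) log(n+N)) and is what keeps 500-replicate Monte-Carlo runs
at desk scale; equivalence with the naive resample-and-recompute
bootstrap is tested.

## Stage 2 — robust standardization

Anchors are site-level posterior means per indicator; the cross-site
median is the center and 1.4826×MAD the scale (≈ SD under normality),
falling back to the sample SD when the MAD is zero and to 1 (with a
warning) when both vanish.

One numerical subtlety matters: for conjugate indicators the anchors
are computed from the closed form E[logit π] = ψ(a) − ψ(b) (digamma),
not from Monte-Carlo draw means. The drift indicator's anchors take
only two values in exact arithmetic, so its cross-site MAD is exactly 0
and the SD fallback is the *designed* behavior; draw-mean anchors blur
the two points by MC noise of order 1/√M, the fallback never triggers,
and standardized scores then grow like √M with the draw count — an
artifact, not a property of the method. Bootstrap indicators (duration,
EDD) have no closed form and keep empirical draw means, whose cross-site
variation is genuinely continuous.

## Stage 3 — composite and weights

The default composite is the convex combination S = Σ w_k z_k on each
draw. The softmax form (1/λ)·log Σ exp(λ w_k z_k) is OR-leaning; note
its true bounds: it dominates max_k w_k z_k (not the linear composite
in general — with all z equal the linear sum exceeds it) and decreases
monotonically in λ toward max_k w_k z_k. The geometric form
Π(c+z_k)^{w_k} − c is AND-leaning and requires c + z > 0 on every draw,
checked at call time.

Weights are user policy, not data: defaults are equal. Alternatives:
dispersion-proportional weights (MAD of each indicator's anchors,
normalized — the implemented reading of "reward indicators with higher
cross-site dispersion"), or a Dirichlet prior over the simplex whose
concentrations encode criticality, in which case weight draw m
multiplies score draw m so weight uncertainty propagates into the score
posterior.

Summaries per site: posterior mean, equal-tailed 95% credible interval
(2.5/97.5 percentiles), Pr(S > τ), and Pr(Top-K) from per-draw
descending ranks with ties broken by site order (determinism for
regression tests).

## Flagging

Dual-key rule: flag site s iff Pr(S_s > τ | data) > p* (default 0.8)
and the corroborator's standardized posterior mean exceeds c (default:
screen-failure component > 0.5). Both inequalities are strict. The
Bayesian FDR of a flag set is the mean posterior non-exceedance
probability over flagged sites; because every flag satisfies key 1 it
is bounded by 1 − p*, an identity asserted at run time.
`calibrate_policy` scans a (τ, p*) grid and returns the point flagging
the most sites subject to estimated FDR ≤ q, breaking ties toward
larger p*. The corroborator cut is applied to the standardized
posterior *mean*; an exceedance-probability form of the second key
would be a straightforward variant but is not the default.

## Latent-factor model

The joint alternative to the two-stage pipeline links indicators
through a latent site risk R_s ~ N(0,1): binomial layers
logit(π_ks) = β_k0 + β_k R_s + ε_ks with ε_ks ~ N(0, σ_kπ²); normal
layers for site-level log-times/log-distances with means
γ_k0 + γ_k R_s and a separate observation scale; Bernoulli drift layers
logit(ψ_ks) = δ_k0 + δ_k R_s with no residual term. Priors: N(0,5²)
intercepts, half-N(0,1) nonnegative loadings (no sign-flip ambiguity;
R's N(0,1) prior fixes location and scale), Half-Cauchy(0,1) scales.

Sampling is adaptive Metropolis-within-Gibbs with conjugate blocks
wherever they exist: vectorized random-walk updates for R and the
binomial logits (sites are conditionally independent), Gibbs for
normal-layer means and intercepts, truncated-normal Gibbs for loadings,
and the inverse-gamma auxiliary representation for Half-Cauchy scales.
Two joint Metropolis "sweep" moves travel the soft identifiability
ridges — shifting all R_s against the intercepts, and rescaling R_s
against the loadings — without which those directions mix an order of
magnitude more slowly. Split-R̂ and Geyer-pairs effective sample sizes
are reported for every parameter; R̂ > 1.1 raises a prominent warning
but never silently discards a fit. With a single site-level observation
per normal layer, the observation and residual scales are separated
only by their priors; posteriors for those two parameters individually
should not be over-interpreted.

Simulation-based calibration (rank uniformity of the true latent risk
within thinned posterior draws under prior-predictive data) is part of
the test suite at reduced scale, alongside parameter recovery
(correlation of posterior-mean R̂ with truth > 0.8 at 50 sites) and
prior recovery on null data.

## Simulator

The generator mimics a multicenter trial monitored through one
lab-based eligibility criterion: 50 sites; DiscreteUniform(20, 100)
screened per site; candidate labs N(80, 15) against threshold 60 (units
of mL/min in the motivating setting); 10% of sites atypical with the
site lab mean shifted by −12 (more borderline inclusions, shifted
distribution, higher eligibility failure); screen failure combines the
eligibility channel (lab ≤ 60) with an independent non-lab channel
whose site probability is Beta with mean Uniform(0.10, 0.40) and
concentration 20 (the split between channels is this package's
modeling choice; the concentration sets realistic overdispersion);
durations log-normal with median 7 days and log-SD 0.4, atypical
medians ×1.30 (a log-location shift, since the spread is specified on
the log scale); window violations Binomial(n_enrolled, 1 − θ_s) with
θ_s ~ Uniform(0.80, 0.95); drift flags Bernoulli with probability 0.05
(typical) / 0.50 (atypical). The borderline half-width is δ = 5 lab
units, so the band is [55, 65]; n_bii = n_enrolled in simulation mode.

Site *profiles* (sizes, atypical labels, realized failure probability,
adherence, the realized drift flag, duration location) are drawn
separately from participant-level data, so ranking-stability studies
can hold the configuration fixed and redraw only participant data. The
realized drift flag is treated as a site trait: it describes how the
site operates, not sampling noise of one data cut.

What the generator does **not** emulate: time-varying accrual,
calendar-time epochs, multiple eligibility labs, region effects,
informative missingness, or correlation between window adherence /
non-lab failure rates and atypicality. Because window and failure-rate
heterogeneity are independent of the atypical label, those two
indicators contribute cross-site noise rather than signal under these
conditions — passing tests show the pipeline's operating
characteristics under this stylized world, not performance on any real
trial.

## Operating characteristics and problem sizes

The Monte-Carlo harness runs the full pipeline per replicate (equal
weights, 1000 posterior draws) and classifies a site as atypical when
E[S_s] > 1.5 (an exceedance-probability rule is available). Sensitivity,
specificity and FDR (FP/max(TP+FP,1); 0 for an empty flag set) are
averaged over replicates with MC standard errors; sensitivity is
reported as undefined under a null configuration. "Ranking accuracy" is
reported two ways: mean pairwise Spearman correlation of posterior-mean
rankings across fixed-configuration replicates, and the probability
that all truly atypical sites rank within the top 2× their count.

Default problem sizes — 500 replicates for operating characteristics,
50 for rank stability, reduced sizes in the test suite — keep every
study at desk scale (minutes on one CPU); the acceptance script exposes
`--replicates` to scale further.

Under these exact conditions the measured characteristics are
approximately: sensitivity 0.55–0.60, specificity ≥ 0.99, FDR ≤ 0.02,
rank stability ≈ 0.6 (the acceptance script recomputes them; the test
suite asserts the published targets at their stated tolerances). Two
structural facts cap these numbers: the E[S] > 1.5 rule is conservative
when two of six equally weighted indicators are uninformative noise
under the generator's independence assumptions, and pairwise rank
stability is bounded because robust standardization rescales
noise-only indicators (duration, EDD, BII across typical sites) to
unit spread by construction.

## Numerical conventions

Beta draws are clipped to (10⁻¹², 1−10⁻¹²) before the logit; the EDD
floor is 10⁻⁶ before the log; MAD uses the 1.4826 consistency factor
everywhere; SD fallbacks use ddof=1; rank ties break by site order;
equal-tailed credible intervals throughout. All randomness flows from
explicit seeds via `numpy` `SeedSequence` substreams; identical
(config, seed) pairs reproduce results bit for bit, including CSV
exports.
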